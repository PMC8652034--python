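"""2D placement of helices and sheets by minimizing 3D-to-2D projection error.

Each diagram element (a helix, or a whole sheet moving as one rigid template)
has a 3D anchor point.  The layout seeks 2D positions whose pairwise distances
reproduce the pairwise 3D anchor distances: the *stress*

    sum over unordered pairs (|p_i - p_j| - |a_i - a_j|)^2
        + lambda * sum over started labels |p_i - s_i|^2

where the second term restricts deviation from a starting layout reused from a
previously computed family member, keeping diagrams of related domains
intercomparable.  Minimization is deterministic gradient descent with
backtracking line search from a principal-plane projection of the anchors
(or from the starting layout where one covers the elements).

Placement runs in two stages mirroring the primary/secondary split: primary
elements are placed first among themselves, then frozen while secondary
elements are placed against them.  Angles are assigned afterwards by
projecting each element's 3D axis into the layout plane, with a small
deterministic sweep that reduces glyph overlap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.affinity import rotate as shp_rotate, translate as shp_translate
from shapely.geometry import box

from .errors import FlatfoldError
from .family_stats import FamilyStats, PRIMARY, SECONDARY
from .sheet_model import (
    PAIRING_CUTOFF,
    SHEET_SPACING,
    SheetModel,
    build_sheets,
    pair_strands,
    sheet_element_label,
)
from .sse_annotation import HELIX, SSE3D, STRAND, AnnotatedFamily, DetectionParams
from .structure_io import DomainStructure

HELIX_GLYPH_WIDTH = 3.0
STRAND_GLYPH_WIDTH = 2.2


@dataclass
class LayoutConfig:
    """Tunables of the layout stage (distances in Angstrom-equivalent units)."""

    lambda_dev: float = 0.05  # deviation-penalty weight
    primary_threshold: float = 0.5
    max_iter: int = 2000
    tol: float = 1e-8  # relative objective-change convergence
    seed: int = 0
    min_overlap: float = 0.5  # starting-layout label-overlap requirement
    pairing_cutoff: float = PAIRING_CUTOFF
    sheet_spacing: float = SHEET_SPACING
    detection: DetectionParams = field(default_factory=DetectionParams)

    def __post_init__(self):
        if self.lambda_dev < 0:
            raise ValueError("lambda_dev must be >= 0")
        if self.tol <= 0 or self.max_iter <= 0:
            raise ValueError("tol and max_iter must be positive")


@dataclass
class LayoutElement:
    label: str
    element_type: str  # "helix" | "sheet"
    center_2d: np.ndarray
    angle: float  # radians in [-pi, pi), N-to-C direction in the layout frame
    display_length: float
    members: list[dict] = field(default_factory=list)  # strand glyphs for sheets

    def __post_init__(self):
        self.center_2d = np.asarray(self.center_2d, dtype=float)
        if not np.all(np.isfinite(self.center_2d)) or not math.isfinite(self.angle):
            raise FlatfoldError(f"non-finite geometry for element {self.label}")
        if self.display_length <= 0:
            raise FlatfoldError(f"non-positive length for element {self.label}")


@dataclass
class DomainDiagram:
    domain_id: str
    elements: list[LayoutElement]
    sequence_order: list[str]  # SSE labels N-to-C (strands individually)
    stress: float  # final all-pairs projection error (lambda-free)
    normalized_stress: float  # stress / sum of squared 3D pair distances
    warnings: list[str] = field(default_factory=list)

    def element(self, label: str) -> LayoutElement:
        for e in self.elements:
            if e.label == label:
                return e
        raise KeyError(label)

    @property
    def labels(self) -> set[str]:
        return {e.label for e in self.elements}


@dataclass
class Frame2D:
    """Projection frame: 3D plane basis plus an in-plane alignment transform."""

    origin: np.ndarray
    ex: np.ndarray
    ey: np.ndarray
    m2: np.ndarray = field(default_factory=lambda: np.eye(2))
    t2: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def project_point(self, p: np.ndarray) -> np.ndarray:
        q = np.array([np.dot(p - self.origin, self.ex), np.dot(p - self.origin, self.ey)])
        return self.m2 @ q + self.t2

    def project_dir(self, d: np.ndarray) -> np.ndarray:
        return self.m2 @ np.array([np.dot(d, self.ex), np.dot(d, self.ey)])


def wrap_angle(a: float) -> float:
    """Wrap to [-pi, pi)."""
    return float(np.mod(a + np.pi, 2 * np.pi) - np.pi)


# -- anchors ----------------------------------------------------------------


def element_anchors_3d(
    sses: list[SSE3D], sheets: list[SheetModel]
) -> dict[str, np.ndarray]:
    """3D anchor per element: helix axis midpoint; sheet strand-midpoint centroid."""
    by_label = {s.label: s for s in sses}
    in_sheet = {lab for sh in sheets for lab in sh.strand_labels}
    anchors: dict[str, np.ndarray] = {}
    for s in sses:
        if s.sse_type == HELIX:
            anchors[s.label] = s.midpoint
    for sh in sheets:
        mids = np.array([by_label[lab].midpoint for lab in sh.strand_labels])
        anchors[sheet_element_label(sh)] = mids.mean(axis=0)
    # strands outside any sheet should not exist (singletons become sheets),
    # but guard against stray input
    for s in sses:
        if s.sse_type == STRAND and s.label not in in_sheet:
            anchors[s.label] = s.midpoint
    return anchors


# -- stress -----------------------------------------------------------------


def stress(
    positions_2d: dict[str, np.ndarray],
    anchors_3d: dict[str, np.ndarray],
    start_positions: dict[str, np.ndarray] | None = None,
    lam: float = 0.0,
) -> float:
    """Projection-error objective over all unordered element pairs.

    ``start_positions`` may cover a subset of the labels; the deviation term
    applies only to covered labels, weighted by ``lam``.
    """
    if set(positions_2d) != set(anchors_3d):
        raise ValueError("positions and anchors must cover the same labels")
    labels = sorted(positions_2d)
    p = np.array([positions_2d[l] for l in labels], dtype=float)
    a = np.array([anchors_3d[l] for l in labels], dtype=float)
    val = _pair_stress(p, _dist_matrix(a), np.triu(np.ones((len(labels),) * 2, bool), 1))
    if start_positions and lam > 0:
        for i, l in enumerate(labels):
            if l in start_positions:
                val += lam * float(np.sum((p[i] - np.asarray(start_positions[l])) ** 2))
    return float(val)


def _dist_matrix(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _pair_stress(p: np.ndarray, d3: np.ndarray, mask: np.ndarray) -> float:
    d2 = _dist_matrix(p)
    return float((((d2 - d3) ** 2)[mask]).sum())


def _stage_value_grad(p, d3, mask, var_idx, start_arr, start_mask, lam_eff):
    """Objective and gradient restricted to the variable rows.

    ``mask`` is a symmetric boolean matrix of active pair terms (zero diagonal).
    """
    n = p.shape[0]
    d2 = _dist_matrix(p)
    err = d2 - d3
    val = float(((err**2)[np.triu(mask, 1)]).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(d2 > 1e-12, 2.0 * err / d2, 0.0)
    coef = coef * mask
    diff = p[:, None, :] - p[None, :, :]
    grad = (coef[:, :, None] * diff).sum(axis=1)
    if lam_eff > 0:
        dev = (p - start_arr) * start_mask[:, None]
        val += lam_eff * float((dev**2).sum())
        grad = grad + 2.0 * lam_eff * dev
    g = np.zeros_like(p)
    g[var_idx] = grad[var_idx]
    return val, g


def _descend(p0, d3, mask, var_idx, start_arr, start_mask, lam_eff, config):
    """Monotone gradient descent with Armijo backtracking; returns (p, value, converged)."""
    p = p0.copy()
    val, g = _stage_value_grad(p, d3, mask, var_idx, start_arr, start_mask, lam_eff)
    step = 1.0
    for _ in range(config.max_iter):
        gnorm2 = float((g**2).sum())
        if gnorm2 < 1e-18:
            return p, val, True
        step *= 2.0
        accepted = False
        for _ in range(60):
            cand = p - step * g
            cand_val, cand_g = _stage_value_grad(
                cand, d3, mask, var_idx, start_arr, start_mask, lam_eff
            )
            if cand_val <= val - 1e-4 * step * gnorm2:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            return p, val, True  # no descent direction progress: at a stationary point
        rel = (val - cand_val) / max(val, 1e-30)
        p, val, g = cand, cand_val, cand_g
        if rel < config.tol:
            return p, val, True
    return p, val, False


# -- initialization ---------------------------------------------------------


def _principal_axes(anchors: np.ndarray) -> np.ndarray:
    centered = anchors - anchors.mean(axis=0)
    if np.allclose(centered, 0.0):
        return np.eye(3)
    _, _, vt = np.linalg.svd(centered, full_matrices=True)
    return vt


def _plane_frame(
    anchors: dict[str, np.ndarray], axes_pair: tuple[int, int], first_label: str | None
) -> Frame2D:
    labels = sorted(anchors)
    a = np.array([anchors[l] for l in labels])
    vt = _principal_axes(a)
    ex, ey = vt[axes_pair[0]].copy(), vt[axes_pair[1]].copy()
    origin = a.mean(axis=0)
    frame = Frame2D(origin=origin, ex=ex, ey=ey)
    if first_label is not None and first_label in anchors:
        q = frame.project_point(anchors[first_label])
        if q[0] < 0:
            frame.ex = -frame.ex
        # deterministic y-sign: first label in sorted order with |y| > tol points up
        for l in labels:
            y = np.dot(anchors[l] - origin, frame.ey)
            if abs(y) > 1e-9:
                if y < 0:
                    frame.ey = -frame.ey
                break
    return frame


def _align_2d(moving: np.ndarray, target: np.ndarray):
    """Orthogonal Procrustes (rotation, possibly reflection) + translation."""
    mc, tc = moving.mean(axis=0), target.mean(axis=0)
    h = (moving - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    m = vt.T @ u.T
    t = tc - m @ mc
    return m, t


def initial_positions(
    anchors_3d: dict[str, np.ndarray],
    start: dict[str, np.ndarray] | None = None,
    first_label: str | None = None,
    axes_pair: tuple[int, int] = (0, 1),
) -> tuple[dict[str, np.ndarray], Frame2D]:
    """Principal-plane projection of the anchors, aligned to a starting subset.

    Labels covered by ``start`` take the start coordinates exactly; remaining
    labels take their plane projection, rigidly aligned (2D Procrustes on the
    shared labels) into the start's coordinate frame when a start exists.
    """
    if not anchors_3d:
        raise ValueError("no elements to initialize")
    frame = _plane_frame(anchors_3d, axes_pair, first_label)
    proj = {l: frame.project_point(a) for l, a in anchors_3d.items()}
    if start:
        shared = sorted(set(start) & set(anchors_3d))
        if len(shared) >= 2:
            m, t = _align_2d(
                np.array([proj[l] for l in shared]),
                np.array([np.asarray(start[l], dtype=float) for l in shared]),
            )
            frame.m2, frame.t2 = m @ frame.m2, m @ frame.t2 + t
            proj = {l: frame.project_point(a) for l, a in anchors_3d.items()}
        elif len(shared) == 1:
            l0 = shared[0]
            shift = np.asarray(start[l0], dtype=float) - proj[l0]
            frame.t2 = frame.t2 + shift
            proj = {l: p + shift for l, p in proj.items()}
        out = dict(proj)
        for l in shared:
            out[l] = np.asarray(start[l], dtype=float).copy()
        return out, frame
    if len(anchors_3d) == 1:
        (l,) = anchors_3d
        return {l: np.zeros(2)}, frame
    return proj, frame


# -- starting-layout selection ----------------------------------------------


def select_starting_layout(
    domain_labels: set[str],
    computed: dict[str, DomainDiagram],
    min_overlap: float,
) -> tuple[DomainDiagram, set[str]] | None:
    """Previously computed diagram sharing the largest label fraction.

    Returns None when nothing reaches ``min_overlap`` (a valid outcome for the
    first member of a family).
    """
    if not domain_labels or not computed:
        return None
    best = None
    for dom_id in sorted(computed):
        shared = domain_labels & computed[dom_id].labels
        ratio = len(shared) / len(domain_labels)
        if best is None or ratio > best[0]:
            best = (ratio, dom_id, shared)
    if best is None or best[0] < min_overlap:
        return None
    return computed[best[1]], best[2]


# -- placement --------------------------------------------------------------


def place_elements(
    anchors_3d: dict[str, np.ndarray],
    classes: dict[str, str],
    start: dict[str, np.ndarray] | None,
    config: LayoutConfig,
    first_label: str | None = None,
) -> tuple[dict[str, np.ndarray], Frame2D, list[str]]:
    """Two-stage stress minimization: primaries first, then secondaries.

    Stage 1 minimizes stress over primary labels only; stage 2 freezes them and
    minimizes over secondary labels with every pair term touching a secondary
    label active.  Deterministic: without a starting layout the three principal
    planes are tried and the lowest final objective wins.
    """
    labels = sorted(anchors_3d)
    if set(classes) < set(labels):
        raise ValueError("classes must cover all labels")
    n = len(labels)
    idx = {l: i for i, l in enumerate(labels)}
    a3 = np.array([anchors_3d[l] for l in labels])
    d3 = _dist_matrix(a3)
    primary_idx = np.array([classes[l] == PRIMARY for l in labels], dtype=bool)
    if not primary_idx.any():
        primary_idx = np.ones(n, dtype=bool)  # degenerate split: place all at once
    secondary_idx = ~primary_idx

    start_arr = np.zeros((n, 2))
    start_mask = np.zeros(n, dtype=bool)
    if start:
        for l, s in start.items():
            if l in idx:
                start_arr[idx[l]] = np.asarray(s, dtype=float)
                start_mask[idx[l]] = True

    plane_choices = [(0, 1)] if start else [(0, 1), (0, 2), (1, 2)]
    best = None
    warnings: list[str] = []
    for axes_pair in plane_choices:
        init, frame = initial_positions(anchors_3d, start, first_label, axes_pair)
        p = np.array([init[l] for l in labels])

        mask1 = primary_idx[:, None] & primary_idx[None, :]
        np.fill_diagonal(mask1, False)
        n_pairs1 = int(np.triu(mask1, 1).sum())
        sm1 = start_mask & primary_idx
        lam1 = _lambda_eff(config.lambda_dev, n_pairs1, int(sm1.sum()))
        p, _, conv1 = _descend(
            p, d3, mask1, np.where(primary_idx)[0], start_arr, sm1, lam1, config
        )

        conv2 = True
        if secondary_idx.any():
            mask2 = secondary_idx[:, None] | secondary_idx[None, :]
            np.fill_diagonal(mask2, False)
            n_pairs2 = int(np.triu(mask2, 1).sum())
            sm2 = start_mask & secondary_idx
            lam2 = _lambda_eff(config.lambda_dev, n_pairs2, int(sm2.sum()))
            p, _, conv2 = _descend(
                p, d3, mask2, np.where(secondary_idx)[0], start_arr, sm2, lam2, config
            )

        full_mask = np.triu(np.ones((n, n), dtype=bool), 1)
        final = _pair_stress(p, d3, full_mask)
        if best is None or final < best[0] - 1e-12:
            best = (final, p.copy(), frame, conv1 and conv2)
    _, p, frame, converged = best
    if not converged:
        warnings.append("optimizer reached iteration cap before convergence")
    return {l: p[idx[l]] for l in labels}, frame, warnings


def _lambda_eff(lam: float, n_pairs: int, n_start: int) -> float:
    """Deviation weight scaled to be commensurate with the pair-term count."""
    if lam <= 0 or n_start == 0:
        return 0.0
    return lam * max(n_pairs, 1) / n_start


# -- angles -----------------------------------------------------------------


def _glyph_polygon(center: np.ndarray, angle: float, length: float, width: float):
    poly = box(-length / 2, -width / 2, length / 2, width / 2)
    poly = shp_rotate(poly, math.degrees(angle), origin=(0, 0))
    return shp_translate(poly, float(center[0]), float(center[1]))


def adjust_angles(
    element_axes: dict[str, np.ndarray],
    positions_2d: dict[str, np.ndarray],
    frame: Frame2D,
    dims: dict[str, tuple[float, float]],
    adjustable: set[str] | None = None,
    fixed_angles: dict[str, float] | None = None,
) -> tuple[dict[str, float], list[str]]:
    """Project 3D axis directions into the layout plane, then reduce glyph overlap.

    ``dims`` maps label -> (length, width) of the glyph rectangle.  When two
    rectangles overlap, each adjustable element may rotate by up to +-15 deg in
    5 deg steps, choosing the angle minimizing its total overlap area
    (deterministic sweep in sorted label order; ties keep the smaller change).
    """
    warnings: list[str] = []
    angles: dict[str, float] = {}
    fixed_angles = fixed_angles or {}
    for label in sorted(element_axes):
        if label in fixed_angles:
            angles[label] = fixed_angles[label]
            continue
        v = frame.project_dir(element_axes[label])
        if np.linalg.norm(v) < 1e-9:
            warnings.append(f"axis of {label} projects to zero length; angle set to 0")
            angles[label] = 0.0
        else:
            angles[label] = wrap_angle(math.atan2(float(v[1]), float(v[0])))

    adjustable = set(element_axes) if adjustable is None else adjustable
    labels = sorted(element_axes)
    deltas = [math.radians(d) for d in (0, -5, 5, -10, 10, -15, 15)]
    for label in labels:
        if label not in adjustable:
            continue
        others = [l for l in labels if l != label]
        other_polys = [
            _glyph_polygon(positions_2d[l], angles[l], *dims[l]) for l in others
        ]
        base_poly = _glyph_polygon(positions_2d[label], angles[label], *dims[label])
        base_overlap = sum(base_poly.intersection(o).area for o in other_polys)
        if base_overlap <= 1e-9:
            continue
        best_delta, best_area = 0.0, base_overlap
        for d in deltas[1:]:
            poly = _glyph_polygon(positions_2d[label], angles[label] + d, *dims[label])
            area = sum(poly.intersection(o).area for o in other_polys)
            if area < best_area - 1e-12:
                best_delta, best_area = d, area
        angles[label] = wrap_angle(angles[label] + best_delta)
    return angles, warnings


# -- orchestration ----------------------------------------------------------


def _sheet_axis_direction(sheet: SheetModel, by_label: dict[str, SSE3D]) -> np.ndarray:
    """Mean sign-corrected strand direction: the sheet's own N-to-C axis."""
    dirs = []
    for lab in sheet.strand_labels:
        _, sign = sheet.template_2d[lab]
        dirs.append(sign * by_label[lab].direction)
    v = np.mean(dirs, axis=0)
    norm = np.linalg.norm(v)
    return v / norm if norm > 1e-12 else np.array([1.0, 0.0, 0.0])


def layout_domain(
    domain: DomainStructure,
    sses: list[SSE3D],
    sheets: list[SheetModel],
    stats: FamilyStats,
    computed: dict[str, DomainDiagram] | None = None,
    config: LayoutConfig | None = None,
) -> DomainDiagram:
    """Full per-domain layout: starting-layout reuse, two-stage placement, angles."""
    config = config or LayoutConfig()
    computed = computed or {}
    by_label = {s.label: s for s in sses}
    sheet_of = {lab: sh for sh in sheets for lab in sh.strand_labels}

    anchors = element_anchors_3d(sses, sheets)
    if not anchors:
        raise FlatfoldError(f"domain {domain.domain_id} has no layout elements")

    elem_meta: dict[str, dict] = {}
    for s in sses:
        if s.sse_type == HELIX:
            elem_meta[s.label] = {
                "type": "helix",
                "axis": s.direction,
                "length": float(np.linalg.norm(s.axis_end - s.axis_start)),
                "width": HELIX_GLYPH_WIDTH,
            }
    for sh in sheets:
        lab = sheet_element_label(sh)
        lengths = [
            float(np.linalg.norm(by_label[l].axis_end - by_label[l].axis_start))
            for l in sh.strand_labels
        ]
        elem_meta[lab] = {
            "type": "sheet",
            "axis": _sheet_axis_direction(sh, by_label),
            "length": max(lengths),
            "width": max(len(sh.strand_labels), 1) * sh.spacing,
            "sheet": sh,
            "lengths": dict(zip(sh.strand_labels, lengths)),
        }
    for s in sses:  # stray strands outside any sheet (defensive)
        if s.label in anchors and s.label not in elem_meta:
            elem_meta[s.label] = {
                "type": "sheet",
                "axis": s.direction,
                "length": float(np.linalg.norm(s.axis_end - s.axis_start)),
                "width": STRAND_GLYPH_WIDTH,
                "sheet": None,
                "lengths": {s.label: float(np.linalg.norm(s.axis_end - s.axis_start))},
            }

    def element_class(label: str) -> str:
        meta = elem_meta[label]
        if meta["type"] == "helix":
            ls = stats.per_label.get(label)
            return ls.sse_class if ls else SECONDARY
        member_classes = [
            stats.per_label[l].sse_class
            for l in (meta["sheet"].strand_labels if meta["sheet"] else meta["lengths"])
            if l in stats.per_label
        ]
        return PRIMARY if PRIMARY in member_classes else SECONDARY

    classes = {l: element_class(l) for l in anchors}

    sequence_order = [s.label for s in sorted(sses, key=lambda s: s.start_index)]
    first_elem = None
    if sequence_order:
        s0 = sequence_order[0]
        first_elem = (
            sheet_element_label(sheet_of[s0]) if s0 in sheet_of else s0
        )

    selection = select_starting_layout(set(anchors), computed, config.min_overlap)
    start_positions = None
    if selection is not None:
        start_diag, shared = selection
        start_positions = {l: start_diag.element(l).center_2d for l in sorted(shared)}

    positions, frame, warnings = place_elements(
        anchors, classes, start_positions, config, first_elem
    )

    dims = {l: (elem_meta[l]["length"], elem_meta[l]["width"]) for l in anchors}
    axes = {l: elem_meta[l]["axis"] for l in anchors}
    primary_set = {l for l in anchors if classes[l] == PRIMARY} or set(anchors)
    angles, w1 = adjust_angles(
        {l: axes[l] for l in primary_set},
        positions,
        frame,
        dims,
    )
    secondary_set = set(anchors) - primary_set
    if secondary_set:
        angles, w2 = adjust_angles(
            axes, positions, frame, dims, adjustable=secondary_set, fixed_angles=angles
        )
        warnings += w2
    warnings += w1

    elements = []
    for label in sorted(anchors):
        meta = elem_meta[label]
        members = []
        if meta["type"] == "sheet" and meta.get("sheet") is not None:
            sh: SheetModel = meta["sheet"]
            for lab in sh.strand_labels:
                offset, sign = sh.template_2d[lab]
                members.append(
                    {
                        "label": lab,
                        "dx": float(offset[0]),
                        "dy": float(offset[1]),
                        "sign": int(sign),
                        "length": meta["lengths"][lab],
                    }
                )
        elif meta["type"] == "sheet":
            members.append(
                {"label": label, "dx": 0.0, "dy": 0.0, "sign": 1, "length": meta["length"]}
            )
        elements.append(
            LayoutElement(
                label=label,
                element_type=meta["type"],
                center_2d=positions[label],
                angle=angles[label],
                display_length=meta["length"],
                members=members,
            )
        )

    labels = sorted(anchors)
    p = np.array([positions[l] for l in labels])
    a3 = np.array([anchors[l] for l in labels])
    d3 = _dist_matrix(a3)
    full_mask = np.triu(np.ones((len(labels),) * 2, dtype=bool), 1)
    raw = _pair_stress(p, d3, full_mask)
    denom = float((d3[full_mask] ** 2).sum())
    return DomainDiagram(
        domain_id=domain.domain_id,
        elements=elements,
        sequence_order=sequence_order,
        stress=raw,
        normalized_stress=raw / denom if denom > 0 else 0.0,
        warnings=warnings,
    )


def layout_family(
    family: AnnotatedFamily,
    structures: dict[str, DomainStructure],
    stats: FamilyStats,
    config: LayoutConfig | None = None,
) -> dict[str, DomainDiagram]:
    """Lay out every member, reusing earlier members' diagrams as starting layouts.

    Members are processed by descending element count (ties by domain id) so the
    richest member anchors the family's common frame.
    """
    config = config or LayoutConfig()
    order = sorted(family.members, key=lambda d: (-len(family.members[d]), d))
    computed: dict[str, DomainDiagram] = {}
    for dom_id in order:
        domain = structures[dom_id]
        sses = family.members[dom_id]
        strands = [s for s in sses if s.sse_type == STRAND]
        adjacency = pair_strands(domain, strands, config.pairing_cutoff)
        sheets = build_sheets(strands, adjacency, config.sheet_spacing)
        computed[dom_id] = layout_domain(domain, sses, sheets, stats, computed, config)
    return computed


# -- glyph geometry (shared by rendering and the family overlay) -------------


def rot2(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s], [s, c]])


def sse_glyph_geometry(
    diagram: DomainDiagram,
) -> dict[str, tuple[np.ndarray, float, float, str]]:
    """Per-SSE glyph geometry: label -> (center, angle, length, sse_type).

    Helices map to their element directly; strands are placed by transforming
    their sheet-template offset by the sheet's center and angle, with the
    direction sign flipping antiparallel strands by pi.
    """
    out: dict[str, tuple[np.ndarray, float, float, str]] = {}
    for e in diagram.elements:
        if e.element_type == "helix":
            out[e.label] = (e.center_2d.copy(), e.angle, e.display_length, HELIX)
        else:
            r = rot2(e.angle)
            for m in e.members:
                center = e.center_2d + r @ np.array([m["dx"], m["dy"]])
                angle = e.angle if m["sign"] > 0 else wrap_angle(e.angle + math.pi)
                out[m["label"]] = (center, angle, m["length"], STRAND)
    return out


def sse_endpoints(
    diagram: DomainDiagram,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """N- and C-terminal 2D endpoints of each SSE glyph (for connectors)."""
    out = {}
    for label, (center, angle, length, _) in sse_glyph_geometry(diagram).items():
        d = np.array([math.cos(angle), math.sin(angle)]) * (length / 2.0)
        out[label] = (center - d, center + d)
    return out


# -- layout JSON -------------------------------------------------------------


def _round(v: float, nd: int = 6) -> float:
    return round(float(v), nd)


def diagram_to_json(diagram: DomainDiagram) -> dict:
    return {
        "domain": diagram.domain_id,
        "stress": _round(diagram.stress),
        "normalized_stress": _round(diagram.normalized_stress, 12),
        "sequence_order": list(diagram.sequence_order),
        "warnings": list(diagram.warnings),
        "elements": [
            {
                "label": e.label,
                "type": e.element_type,
                "x": _round(e.center_2d[0]),
                "y": _round(e.center_2d[1]),
                "angle_deg": _round(math.degrees(e.angle)),
                "length": _round(e.display_length),
                "members": [
                    {
                        "label": m["label"],
                        "dx": _round(m["dx"]),
                        "dy": _round(m["dy"]),
                        "sign": m["sign"],
                        "length": _round(m["length"]),
                    }
                    for m in e.members
                ],
            }
            for e in diagram.elements
        ],
    }


def diagram_from_json(doc: dict) -> DomainDiagram:
    elements = [
        LayoutElement(
            label=e["label"],
            element_type=e["type"],
            center_2d=np.array([e["x"], e["y"]]),
            angle=wrap_angle(math.radians(e["angle_deg"])),
            display_length=e["length"],
            members=[dict(m) for m in e.get("members", [])],
        )
        for e in doc["elements"]
    ]
    return DomainDiagram(
        domain_id=doc["domain"],
        elements=elements,
        sequence_order=list(doc.get("sequence_order", [])),
        stress=doc["stress"],
        normalized_stress=doc.get("normalized_stress", 0.0),
        warnings=list(doc.get("warnings", [])),
    )


def write_diagram(diagram: DomainDiagram, path: str | Path) -> None:
    Path(path).write_text(json.dumps(diagram_to_json(diagram), indent=2, sort_keys=True) + "\n")


def read_diagram(path: str | Path) -> DomainDiagram:
    return diagram_from_json(json.loads(Path(path).read_text()))
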