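"""Calpha-geometry secondary-structure detection and family-consistent labelling.

Detection uses P-SEA-style distance criteria on the Calpha trace: residue *i* is
helix-like when d(i,i+2) falls in [5.1, 6.4] A and d(i,i+3) in [4.6, 6.0] A, and
strand-like when d(i,i+2) falls in [6.4, 7.4] A.  Runs of at least 4 helix-like
(3 strand-like) residues become elements; the element span extends to the last
residue entering the defining distances; helices win where spans overlap.

Labelling picks the member with the most elements as the reference, names its
elements H1, H2, ... / E1, E2, ... in sequence order, and aligns every other
member to it by rigid superposition followed by an order-preserving,
type-constrained dynamic-programming match on element midpoints.  Topologically
equivalent elements thus share one family-wide name, the property the layout
and the family overlay depend on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FlatfoldError, GeometryError
from .structure_io import DomainStructure

HELIX = "helix"
STRAND = "strand"

#: Minimum residues for a valid element of each type.
MIN_LEN = {HELIX: 4, STRAND: 3}


@dataclass
class DetectionParams:
    """Thresholds of the Calpha distance criteria (Angstrom).

    ``window_slack`` widens every window on both sides, and ``bridge_gaps``
    closes single-residue holes inside flag runs; together they make detection
    robust to coordinate noise of a few tenths of an Angstrom while leaving
    ideal geometry classified identically.  Set slack to 0 and bridging off for
    the strict literal criteria.
    """

    helix_d13: tuple[float, float] = (5.1, 6.4)
    helix_d14: tuple[float, float] = (4.6, 6.0)
    strand_d13: tuple[float, float] = (6.4, 7.4)
    min_helix_run: int = 4
    min_strand_run: int = 3
    window_slack: float = 0.35
    bridge_gaps: bool = True

    def window(self, name: str) -> tuple[float, float]:
        lo, hi = getattr(self, name)
        return lo - self.window_slack, hi + self.window_slack


@dataclass
class SSE3D:
    """A helix or strand with its residue span and fitted 3D axis."""

    label: str | None
    sse_type: str  # "helix" | "strand"
    chain_id: str
    start_index: int  # 0-based indices into the domain residue list
    end_index: int
    axis_start: np.ndarray
    axis_end: np.ndarray

    def __post_init__(self):
        if self.sse_type not in (HELIX, STRAND):
            raise FlatfoldError(f"unknown sse_type {self.sse_type!r}")
        if self.start_index > self.end_index:
            raise FlatfoldError("start_index > end_index")
        if self.n_residues < MIN_LEN[self.sse_type]:
            raise FlatfoldError(
                f"{self.sse_type} of {self.n_residues} residues below minimum"
            )
        self.axis_start = np.asarray(self.axis_start, dtype=float)
        self.axis_end = np.asarray(self.axis_end, dtype=float)
        if np.allclose(self.axis_start, self.axis_end):
            raise FlatfoldError("degenerate axis (zero length)")

    @property
    def n_residues(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.axis_start + self.axis_end)

    @property
    def direction(self) -> np.ndarray:
        d = self.axis_end - self.axis_start
        return d / np.linalg.norm(d)


@dataclass
class AnnotatedFamily:
    """Per-member labelled elements of one protein family."""

    family_id: str
    members: dict[str, list[SSE3D]]

    def __post_init__(self):
        types: dict[str, str] = {}
        for domain_id, sses in self.members.items():
            labels = [s.label for s in sses]
            if len(set(labels)) != len(labels):
                raise FlatfoldError(f"duplicate labels in member {domain_id}")
            for s in sses:
                if s.label is None:
                    raise FlatfoldError(f"unlabelled element in member {domain_id}")
                prev = types.setdefault(s.label, s.sse_type)
                if prev != s.sse_type:
                    raise FlatfoldError(
                        f"label {s.label} carries both {prev} and {s.sse_type}"
                    )

    @property
    def label_types(self) -> dict[str, str]:
        return {s.label: s.sse_type for sses in self.members.values() for s in sses}


def fit_axis(domain: DomainStructure, sse: SSE3D) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares axis through the element's Calpha positions.

    The axis endpoints are the projections of the first and last Calpha onto
    the fitted line; the direction points N to C.
    """
    coords = domain.coords[sse.start_index : sse.end_index + 1]
    return _fit_axis_coords(coords)


def _fit_axis_coords(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    coords = np.asarray(coords, dtype=float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    if np.allclose(centered, 0.0):
        raise GeometryError("all Calpha coincident; no axis")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if np.dot(direction, coords[-1] - coords[0]) < 0:
        direction = -direction
    t0 = float(np.dot(coords[0] - centroid, direction))
    t1 = float(np.dot(coords[-1] - centroid, direction))
    return centroid + t0 * direction, centroid + t1 * direction


def detect_sses(
    domain: DomainStructure, params: DetectionParams | None = None
) -> list[SSE3D]:
    """Find maximal non-overlapping helix and strand runs in a Calpha trace.

    Elements never span a chain break; a coil-only domain yields an empty list.
    """
    params = params or DetectionParams()
    coords = domain.coords
    out: list[SSE3D] = []
    for seg_start, seg_end in domain.segments:
        out.extend(_detect_in_segment(domain, coords, seg_start, seg_end, params))
    out.sort(key=lambda s: s.start_index)
    return out


def _close_gaps(flags: np.ndarray) -> np.ndarray:
    """Set any single False flanked by True on both sides (morphological closing)."""
    out = flags.copy()
    out[1:-1] |= flags[:-2] & flags[2:]
    return out


def _runs(flags: np.ndarray, min_run: int) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_run, as inclusive index pairs."""
    runs = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _detect_in_segment(domain, coords, seg_start, seg_end, params) -> list[SSE3D]:
    n = seg_end - seg_start + 1
    if n < 5:
        return []
    seg = coords[seg_start : seg_end + 1]
    d13 = np.full(n, np.nan)
    d14 = np.full(n, np.nan)
    d13[: n - 2] = np.linalg.norm(seg[2:] - seg[:-2], axis=1)
    d14[: n - 3] = np.linalg.norm(seg[3:] - seg[:-3], axis=1)

    lo13, hi13 = params.window("helix_d13")
    lo14, hi14 = params.window("helix_d14")
    slo, shi = params.window("strand_d13")
    with np.errstate(invalid="ignore"):  # trailing NaN distances compare False
        helix_like = (d13 >= lo13) & (d13 <= hi13) & (d14 >= lo14) & (d14 <= hi14)
        strand_like = (d13 >= slo) & (d13 <= shi)
    if params.bridge_gaps:
        helix_like = _close_gaps(helix_like)
        strand_like = _close_gaps(strand_like)

    covered = np.zeros(n, dtype=bool)
    sses: list[tuple[str, int, int]] = []

    prev_end = -1
    for a, b in _runs(helix_like, params.min_helix_run):
        span_a = max(a, prev_end + 1)
        span_b = min(b + 3, n - 1)
        if span_b - span_a + 1 >= MIN_LEN[HELIX]:
            sses.append((HELIX, span_a, span_b))
            covered[span_a : span_b + 1] = True
            prev_end = span_b

    strand_like &= ~covered
    prev_end = -1
    for a, b in _runs(strand_like, params.min_strand_run):
        span_a = max(a, prev_end + 1)
        span_b = min(b + 2, n - 1)
        # shrink off residues already claimed by a helix
        while span_a <= span_b and covered[span_a]:
            span_a += 1
        while span_b >= span_a and covered[span_b]:
            span_b -= 1
        if span_b - span_a + 1 >= MIN_LEN[STRAND]:
            sses.append((STRAND, span_a, span_b))
            prev_end = span_b

    sses.sort(key=lambda t: t[1])
    out = []
    for sse_type, a, b in sses:
        start, end = seg_start + a, seg_start + b
        axis_start, axis_end = _fit_axis_coords(coords[start : end + 1])
        out.append(
            SSE3D(
                label=None,
                sse_type=sse_type,
                chain_id=domain.residues[start].chain_id,
                start_index=start,
                end_index=end,
                axis_start=axis_start,
                axis_end=axis_end,
            )
        )
    return out


def superpose(
    ref_coords: Sequence[np.ndarray], mov_coords: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of mov onto ref.

    Returns ``(R, t, rmsd)`` with a proper rotation (det = +1) such that
    ``R @ m + t`` approximates the reference points.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise GeometryError("superpose needs equal-length (n,3) point sets")
    n = ref.shape[0]
    if n < 3:
        raise GeometryError("superpose needs at least 3 points")
    ref_c = ref.mean(axis=0)
    mov_c = mov.mean(axis=0)
    p = mov - mov_c
    q = ref - ref_c
    if np.linalg.matrix_rank(p, tol=1e-8) < 2 or np.linalg.matrix_rank(q, tol=1e-8) < 2:
        raise GeometryError("rank-deficient point set (collinear or coincident)")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ref_c - rot @ mov_c
    resid = ref - (mov @ rot.T + t)
    rmsd = float(np.sqrt((resid**2).sum() / n))
    return rot, t, rmsd


# -- family annotation ------------------------------------------------------

#: DP match bonus; equal to the forbidden-distance cutoff so any allowed match
#: scores >= 0 and is preferred over leaving both elements unmatched (gap = 0).
MATCH_CUTOFF = 10.0


def _dp_match(
    ref_sses: list[SSE3D],
    mov_sses: list[SSE3D],
    rot: np.ndarray,
    t: np.ndarray,
) -> list[tuple[int, int]]:
    """Order-preserving, type-constrained match of element midpoints."""
    nr, nm = len(ref_sses), len(mov_sses)
    score = np.full((nr, nm), -np.inf)
    for i, r in enumerate(ref_sses):
        for j, m in enumerate(mov_sses):
            if r.sse_type != m.sse_type:
                continue
            dist = float(np.linalg.norm(r.midpoint - (rot @ m.midpoint + t)))
            if dist <= MATCH_CUTOFF:
                score[i, j] = MATCH_CUTOFF - dist
    f = np.zeros((nr + 1, nm + 1))
    for i in range(1, nr + 1):
        for j in range(1, nm + 1):
            best = max(f[i - 1, j], f[i, j - 1])
            if np.isfinite(score[i - 1, j - 1]):
                best = max(best, f[i - 1, j - 1] + score[i - 1, j - 1])
            f[i, j] = best
    pairs: list[tuple[int, int]] = []
    i, j = nr, nm
    while i > 0 and j > 0:
        if (
            np.isfinite(score[i - 1, j - 1])
            and f[i, j] == f[i - 1, j - 1] + score[i - 1, j - 1]
        ):
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif f[i, j] == f[i - 1, j]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def _initial_transform(ref: DomainStructure, mov: DomainStructure):
    """Whole-trace superposition, truncating the longer trace to equal length."""
    n = min(len(ref), len(mov))
    if n < 3:
        return np.eye(3), np.zeros(3)
    try:
        rot, t, _ = superpose(ref.coords[:n], mov.coords[:n])
    except GeometryError:
        return np.eye(3), np.zeros(3)
    return rot, t


def _refined_transform(ref, mov, ref_sses, mov_sses, pairs):
    """Re-superpose on the Calpha of matched element pairs."""
    ref_pts, mov_pts = [], []
    for i, j in pairs:
        r, m = ref_sses[i], mov_sses[j]
        k = min(r.n_residues, m.n_residues)
        ref_pts.append(ref.coords[r.start_index : r.start_index + k])
        mov_pts.append(mov.coords[m.start_index : m.start_index + k])
    if not ref_pts:
        return None
    ref_all = np.vstack(ref_pts)
    mov_all = np.vstack(mov_pts)
    if len(ref_all) < 3:
        return None
    try:
        rot, t, _ = superpose(ref_all, mov_all)
    except GeometryError:
        return None
    return rot, t


def _sequence_labels(sses: list[SSE3D]) -> list[str]:
    """H1.../E1... names in sequence order, numbered per type."""
    counters = {HELIX: 0, STRAND: 0}
    labels = []
    for s in sses:
        counters[s.sse_type] += 1
        labels.append(("H" if s.sse_type == HELIX else "E") + str(counters[s.sse_type]))
    return labels


def annotate_family(
    family_id: str,
    members: dict[str, tuple[DomainStructure, list[SSE3D]]],
) -> AnnotatedFamily:
    """Assign family-consistent labels so equivalent elements share one name.

    The member with the most elements (ties: lexicographically smallest domain
    id) is the reference; its elements are named in sequence order.  Every other
    member is rigidly superposed onto the reference and matched by DP; matched
    elements inherit the reference label, unmatched ones get fresh labels
    suffixed with their domain id to stay globally unique.
    """
    if not members:
        raise ValueError("annotate_family: empty member set")
    ref_id = sorted(members, key=lambda d: (-len(members[d][1]), d))[0]
    ref_dom, ref_sses = members[ref_id]
    ref_labels = _sequence_labels(ref_sses)

    out: dict[str, list[SSE3D]] = {}
    out[ref_id] = [replace(s, label=lab) for s, lab in zip(ref_sses, ref_labels)]

    for dom_id in sorted(members):
        if dom_id == ref_id:
            continue
        dom, sses = members[dom_id]
        rot, t = _initial_transform(ref_dom, dom)
        pairs = _dp_match(ref_sses, sses, rot, t)
        refined = _refined_transform(ref_dom, dom, ref_sses, sses, pairs)
        if refined is not None:
            pairs = _dp_match(ref_sses, sses, refined[0], refined[1])
        matched = {j: ref_labels[i] for i, j in pairs}
        fresh = {HELIX: 0, STRAND: 0}
        labelled = []
        for j, s in enumerate(sses):
            if j in matched:
                labelled.append(replace(s, label=matched[j]))
            else:
                fresh[s.sse_type] += 1
                prefix = "H" if s.sse_type == HELIX else "E"
                labelled.append(
                    replace(s, label=f"{prefix}{fresh[s.sse_type]}.{dom_id}")
                )
        out[dom_id] = labelled
    return AnnotatedFamily(family_id=family_id, members=out)


# -- annotation JSON interchange --------------------------------------------


def annotation_to_json(
    family: AnnotatedFamily,
    structures: dict[str, DomainStructure],
    sheets: dict[str, list] | None = None,
) -> dict:
    """Serialize an annotated family (author numbering) to the interchange schema.

    This schema is the substitution point for external annotations: any tool's
    output converted to it can drive the layout and rendering stages.
    """
    doc: dict = {"family": family.family_id, "members": {}}
    for dom_id in sorted(family.members):
        dom = structures[dom_id]
        entries = []
        for s in family.members[dom_id]:
            entries.append(
                {
                    "label": s.label,
                    "type": s.sse_type,
                    "chain": s.chain_id,
                    "start_auth": dom.residues[s.start_index].seq_number,
                    "end_auth": dom.residues[s.end_index].seq_number,
                    "axis_start": [round(float(v), 4) for v in s.axis_start],
                    "axis_end": [round(float(v), 4) for v in s.axis_end],
                }
            )
        doc["members"][dom_id] = entries
    if sheets is not None:
        doc["sheets"] = {
            dom_id: [
                {
                    "id": sh.sheet_id,
                    "strands": list(sh.strand_labels),
                    "orientations": list(sh.orientations),
                }
                for sh in dom_sheets
            ]
            for dom_id, dom_sheets in sorted(sheets.items())
        }
    return doc


def annotation_from_json(
    doc: dict, structures: dict[str, DomainStructure]
) -> AnnotatedFamily:
    """Rebuild an AnnotatedFamily from the interchange schema."""
    members: dict[str, list[SSE3D]] = {}
    for dom_id, entries in doc["members"].items():
        dom = structures[dom_id]
        index_of = {
            (r.chain_id, r.seq_number): i for i, r in enumerate(dom.residues)
        }
        sses = []
        for e in entries:
            start = index_of[(e["chain"], e["start_auth"])]
            end = index_of[(e["chain"], e["end_auth"])]
            sses.append(
                SSE3D(
                    label=e["label"],
                    sse_type=e["type"],
                    chain_id=e["chain"],
                    start_index=start,
                    end_index=end,
                    axis_start=np.array(e["axis_start"], dtype=float),
                    axis_end=np.array(e["axis_end"], dtype=float),
                )
            )
        members[dom_id] = sses
    return AnnotatedFamily(family_id=doc["family"], members=members)


def write_annotation(doc: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_annotation(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
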