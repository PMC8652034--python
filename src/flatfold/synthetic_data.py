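"""Synthetic Calpha structures: ideal helices/strands, composite domains, families.

Every pipeline stage is testable without downloading a single structure.  The
generators produce geometrically ideal traces — a canonical alpha-helix
(radius 2.3 A, rise 1.5 A/residue, 100 deg/residue) and an extended zigzag
strand (rise 3.3 A/residue, +-0.9 A lateral offset) — joined by short coil
linkers, and "families" of jittered/element-deleted copies with ground-truth
labels, emulating the structural variation among homologous domains.

What this does NOT emulate: real loop conformations, sequence effects,
beta-sheet twist, or crystallographic noise structure; Gaussian coordinate
jitter stands in for all of them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

from .errors import GenerationError
from .sse_annotation import HELIX, STRAND
from .structure_io import DomainStructure, ResidueRecord, write_minimal_pdb

HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TWIST_DEG = 100.0
STRAND_RISE = 3.3
STRAND_OFFSET = 0.9

#: Physically plausible consecutive-Calpha distance window for generated traces.
CA_STEP_RANGE = (2.8, 4.2)


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GenerationError("zero direction vector")
    return v / n


def _frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-handed orthonormal frame (u, v, w) with w = direction."""
    w = _unit(direction)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(w)))] = 1.0
    u = _unit(np.cross(w, helper))
    v = np.cross(w, u)
    return u, v, w


def make_ideal_helix(n_res: int, origin=(0.0, 0.0, 0.0), direction=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Canonical alpha-helix Calpha trace along ``direction`` through ``origin``."""
    if n_res < 4:
        raise ValueError("a helix needs at least 4 residues")
    u, v, w = _frame(direction)
    origin = np.asarray(origin, dtype=float)
    pts = []
    for i in range(n_res):
        theta = math.radians(HELIX_TWIST_DEG) * i
        pts.append(
            origin
            + HELIX_RISE * i * w
            + HELIX_RADIUS * (math.cos(theta) * u + math.sin(theta) * v)
        )
    return np.array(pts)


def make_ideal_strand(n_res: int, origin=(0.0, 0.0, 0.0), direction=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Extended zigzag strand trace: 3.3 A rise, alternating +-0.9 A offset."""
    if n_res < 3:
        raise ValueError("a strand needs at least 3 residues")
    u, _, w = _frame(direction)
    origin = np.asarray(origin, dtype=float)
    return np.array(
        [origin + STRAND_RISE * i * w + ((-1) ** i) * STRAND_OFFSET * u for i in range(n_res)]
    )


@dataclass(frozen=True)
class SSESpec:
    """One element of a domain recipe."""

    kind: str  # "helix" | "strand"
    n_res: int
    origin: tuple[float, float, float]
    direction: tuple[float, float, float]


@dataclass
class GroundTruth:
    """Generator-assigned labels and residue index ranges."""

    labels: list[str]
    kinds: list[str]
    ranges: list[tuple[int, int]]  # inclusive indices into the residue list


@dataclass
class FamilySpec:
    recipe: list[SSESpec]
    n_members: int = 10
    jitter_sigma: float = 0.3  # Angstrom, per coordinate
    deletion_prob: float = 0.0
    seed: int = 0
    family_id: str = "9.99.99.99"

    def __post_init__(self):
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")
        if not 0 <= self.deletion_prob < 1:
            raise ValueError("deletion_prob must be in [0, 1)")


N_LINKER = 3  # coil residues bridging consecutive elements


def _window_clearance(d13: float, d14: float | None) -> float:
    """Distance (A) of a coil triple's signature from the detection windows.

    Positive means safely outside both the strand and the helix criteria;
    negative means the triple would read as secondary structure.
    """
    from .sse_annotation import DetectionParams

    p = DetectionParams()

    def dist_outside(value, window):
        lo, hi = window
        if value < lo:
            return lo - value
        if value > hi:
            return value - hi
        return -min(value - lo, hi - value)  # inside: negative depth

    strand_clear = dist_outside(d13, p.window("strand_d13"))
    h13 = dist_outside(d13, p.window("helix_d13"))
    if d14 is None:
        helix_clear = h13
    else:
        # helix-like needs BOTH windows, so escaping either one suffices
        helix_clear = max(h13, dist_outside(d14, p.window("helix_d14")))
    return min(strand_clear, helix_clear)


def _linker(p_from: np.ndarray, p_to: np.ndarray) -> np.ndarray:
    """Three coil points between two anchors, with a coil-like distance signature.

    A vectorized grid search over per-point lateral offsets (zigzag in the
    plane plus an out-of-plane bow) picks the path whose Calpha steps are
    physically plausible and whose within-linker d(i,i+2)/d(i,i+3) values
    clear the secondary-structure detection windows by the widest margin, so
    moderate coordinate noise cannot make the coil read as helix or strand.
    Gaps longer than four plausible steps are a generation error.
    """
    gap = p_to - p_from
    gap_len = float(np.linalg.norm(gap))
    lo, hi = CA_STEP_RANGE
    if gap_len < 1e-6:
        raise GenerationError("coincident linker anchors")
    if gap_len > (N_LINKER + 1) * (hi - 0.1):
        # re-bridged deletion gaps exceed what 3 residues can span
        return _coil_linker(p_from, p_to)
    offsets = _linker_offsets(gap_len)
    u, v, w = _frame(gap)
    basis = np.stack([u, v, w])  # local -> world
    local = np.zeros((N_LINKER, 3))
    local[:, 0] = offsets[:, 0]
    local[:, 1] = offsets[:, 1]
    local[:, 2] = offsets[:, 2]
    return p_from + local @ basis



@lru_cache(maxsize=256)
def _linker_offsets(gap_len: float) -> np.ndarray:
    """Best-clearance linker point offsets in the local (u, v, gap) frame."""
    from .sse_annotation import DetectionParams

    p = DetectionParams()
    windows = {
        "s13": p.window("strand_d13"),
        "h13": p.window("helix_d13"),
        "h14": p.window("helix_d14"),
    }
    gap_len = float(gap_len)
    fracs = np.arange(1, N_LINKER + 1) / (N_LINKER + 1)
    a_grid = np.arange(-7.0, 7.01, 0.5)
    bow_grid = np.arange(0.0, 4.01, 0.5)
    a1, a2, a3, bw = np.meshgrid(a_grid, a_grid, a_grid, bow_grid, indexing="ij")
    n = a1.size
    pts = np.zeros((n, 5, 3))
    pts[:, 4, 2] = gap_len
    for k, (a, frac) in enumerate(zip((a1, a2, a3), fracs)):
        pts[:, k + 1, 0] = a.ravel()
        pts[:, k + 1, 1] = bw.ravel() * math.sin(math.pi * frac)
        pts[:, k + 1, 2] = frac * gap_len

    steps = np.linalg.norm(np.diff(pts, axis=1), axis=2)  # (n, 4)
    ok = np.all((steps >= CA_STEP_RANGE[0] + 0.05) & (steps <= CA_STEP_RANGE[1] - 0.05), axis=1)
    d13 = np.linalg.norm(pts[:, 2:] - pts[:, :-2], axis=2)  # (n, 3)
    d14 = np.linalg.norm(pts[:, 3:] - pts[:, :-3], axis=2)  # (n, 2)

    def outside(val, window):
        lo_w, hi_w = window
        below, above = lo_w - val, val - hi_w
        inside_depth = -np.minimum(val - lo_w, hi_w - val)
        return np.where(val < lo_w, below, np.where(val > hi_w, above, inside_depth))

    strand_clear = outside(d13, windows["s13"])  # (n, 3)
    h13 = outside(d13, windows["h13"])
    h14 = outside(d14, windows["h14"])
    # helix-like needs both windows; the last triple has no d14 inside the chain
    helix_clear = h13.copy()
    helix_clear[:, :2] = np.maximum(h13[:, :2], h14)
    clearance = np.minimum(strand_clear, helix_clear).min(axis=1)
    clearance[~ok] = -np.inf
    best = int(np.argmax(clearance))
    if not np.isfinite(clearance[best]):
        raise GenerationError(f"no feasible 3-residue linker for gap {gap_len:.1f} A")
    out = _polish_linker(pts[best, 1:4].copy(), gap_len, windows)
    out.setflags(write=False)
    return out


def _polish_linker(points: np.ndarray, gap_len: float, windows: dict) -> np.ndarray:
    """Refine the grid winner with Nelder-Mead on all nine point coordinates."""
    from scipy.optimize import minimize

    lo, hi = CA_STEP_RANGE

    def neg_min_clearance(x):
        chain = np.vstack([[0.0, 0.0, 0.0], x.reshape(3, 3), [0.0, 0.0, gap_len]])
        steps = np.linalg.norm(np.diff(chain, axis=0), axis=1)
        penalty = 0.0
        penalty += 100.0 * float(np.clip(lo + 0.05 - steps, 0, None).sum())
        penalty += 100.0 * float(np.clip(steps - (hi - 0.05), 0, None).sum())
        worst = np.inf
        for i in range(3):
            d13 = float(np.linalg.norm(chain[i + 2] - chain[i]))
            d14 = (
                float(np.linalg.norm(chain[i + 3] - chain[i])) if i + 3 < 5 else None
            )
            worst = min(worst, _window_clearance_scalar(d13, d14, windows))
        return -worst + penalty

    res = minimize(
        neg_min_clearance,
        points.ravel(),
        method="Nelder-Mead",
        options={"maxiter": 800, "xatol": 1e-3, "fatol": 1e-4},
    )
    cand = res.x.reshape(3, 3)
    if neg_min_clearance(res.x) < neg_min_clearance(points.ravel()):
        return cand
    return points


def _window_clearance_scalar(d13: float, d14: float | None, windows: dict) -> float:
    def outside(value, window):
        lo_w, hi_w = window
        if value < lo_w:
            return lo_w - value
        if value > hi_w:
            return value - hi_w
        return -min(value - lo_w, hi_w - value)

    strand_clear = outside(d13, windows["s13"])
    h13 = outside(d13, windows["h13"])
    helix_clear = h13 if d14 is None else max(h13, outside(d14, windows["h14"]))
    return min(strand_clear, helix_clear)


def _coil_linker(p_from: np.ndarray, p_to: np.ndarray) -> np.ndarray:
    """Arbitrary-length coil: points on a wide circular helix between anchors.

    Used when a deleted element leaves a gap too long for the standard
    3-residue linker.  The coil's step is ~3.4 A and its d(i,i+2) is ~4.3 A,
    below every detection window, so it always reads as coil.  The number of
    residues grows with the gap.
    """
    from scipy.optimize import brentq

    gap = p_to - p_from
    gap_len = float(np.linalg.norm(gap))
    step_t, d13_t = 3.4, 4.3

    def helix_points(n, dz):
        with np.errstate(invalid="ignore"):
            a = math.sqrt(max(d13_t**2 - 4 * dz * dz, 1e-9))  # 2 r sin(phi)
            b = math.sqrt(max(step_t**2 - dz * dz, 1e-9))  # 2 r sin(phi/2)
        cos_half = min(a / (2 * b), 0.999)
        phi = 2 * math.acos(cos_half)
        r = b / (2 * math.sin(phi / 2))
        i = np.arange(n + 2)
        return np.column_stack([r * np.cos(i * phi), r * np.sin(i * phi), i * dz])

    def chord(n, dz):
        pts = helix_points(n, dz)
        return float(np.linalg.norm(pts[-1] - pts[0]))

    for n in range(max(3, int(gap_len / 2.0)), max(3, int(gap_len / 2.0)) + 40):
        lo_dz, hi_dz = 0.05, min(2.1, step_t - 0.1)
        f_lo, f_hi = chord(n, lo_dz) - gap_len, chord(n, hi_dz) - gap_len
        if f_lo * f_hi > 0:
            continue
        dz = brentq(lambda z: chord(n, z) - gap_len, lo_dz, hi_dz, xtol=1e-10)
        pts = helix_points(n, dz)
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if not np.all((steps >= CA_STEP_RANGE[0]) & (steps <= CA_STEP_RANGE[1])):
            continue
        # rigidly map the coil chord onto the gap
        c = pts[-1] - pts[0]
        rot = _rotation_between(c / np.linalg.norm(c), gap / gap_len)
        placed = (pts - pts[0]) @ rot.T + p_from
        return placed[1:-1]
    raise GenerationError(f"no feasible coil linker for gap {gap_len:.1f} A")


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a onto unit vector b (Rodrigues)."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        helper = np.zeros(3)
        helper[int(np.argmin(np.abs(a)))] = 1.0
        axis = np.cross(a, helper)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _trace(spec: SSESpec) -> np.ndarray:
    if spec.kind == HELIX:
        return make_ideal_helix(spec.n_res, spec.origin, spec.direction)
    if spec.kind == STRAND:
        return make_ideal_strand(spec.n_res, spec.origin, spec.direction)
    raise ValueError(f"unknown SSE kind {spec.kind!r}")


def make_domain(
    recipe: list[SSESpec], domain_id: str = "synA01", chain_id: str = "A"
) -> tuple[DomainStructure, GroundTruth]:
    """Assemble a domain from a recipe: SSE traces joined by 3-residue linkers.

    Returns the structure and the ground-truth annotation (labels in sequence
    order, numbered per type: H1, H2, ... / E1, E2, ...).
    """
    if not recipe:
        raise GenerationError("empty recipe")
    coords: list[np.ndarray] = []
    labels, kinds, ranges = [], [], []
    counters = {HELIX: 0, STRAND: 0}
    for k, spec in enumerate(recipe):
        trace = _trace(spec)
        if k > 0:
            coords.extend(_linker(coords[-1], trace[0]))
        start = len(coords)
        coords.extend(trace)
        counters[spec.kind] += 1
        labels.append(("H" if spec.kind == HELIX else "E") + str(counters[spec.kind]))
        kinds.append(spec.kind)
        ranges.append((start, len(coords) - 1))
    residues = [
        ResidueRecord(chain_id=chain_id, seq_number=i + 1, insertion_code="", ca_coord=c)
        for i, c in enumerate(coords)
    ]
    domain = DomainStructure(domain_id=domain_id, source_id="syn", residues=residues)
    return domain, GroundTruth(labels=labels, kinds=kinds, ranges=ranges)


def make_family(spec: FamilySpec) -> dict[str, tuple[DomainStructure, GroundTruth]]:
    """Jittered / element-deleted copies of a base recipe, ground truth attached.

    One RNG substream per member (spawned from the family seed by member
    index), so deleting or skipping a member never shifts another member's
    noise; runs are fully reproducible from ``spec.seed``.
    """
    out: dict[str, tuple[DomainStructure, GroundTruth]] = {}
    for m in range(spec.n_members):
        rng = np.random.default_rng([spec.seed, m])
        keep = [i for i in range(len(spec.recipe)) if rng.random() >= spec.deletion_prob]
        if not keep:  # never delete every element
            keep = [0]
        member_recipe = [spec.recipe[i] for i in keep]
        dom_id = f"synA{m:02d}"
        domain, truth = make_domain(member_recipe, domain_id=dom_id)
        # labels must refer to the base recipe's numbering, not the survivor's
        base_truth = _base_labels(spec.recipe)
        truth = GroundTruth(
            labels=[base_truth[i] for i in keep],
            kinds=truth.kinds,
            ranges=truth.ranges,
        )
        if spec.jitter_sigma > 0:
            noise = rng.normal(0.0, spec.jitter_sigma, size=(len(domain), 3))
            residues = [
                ResidueRecord(
                    chain_id=r.chain_id,
                    seq_number=r.seq_number,
                    insertion_code=r.insertion_code,
                    ca_coord=r.ca_coord + noise[i],
                )
                for i, r in enumerate(domain.residues)
            ]
            domain = DomainStructure(
                domain_id=domain.domain_id, source_id=domain.source_id, residues=residues
            )
        out[dom_id] = (domain, truth)
    return out


def _base_labels(recipe: list[SSESpec]) -> list[str]:
    counters = {HELIX: 0, STRAND: 0}
    labels = []
    for spec in recipe:
        counters[spec.kind] += 1
        labels.append(("H" if spec.kind == HELIX else "E") + str(counters[spec.kind]))
    return labels


# -- standard recipes --------------------------------------------------------


def hairpin_recipe(n_res: int = 6, separation: float = 4.8) -> list[SSESpec]:
    """Two antiparallel strands side by side: the minimal beta-sheet."""
    height = (n_res - 1) * STRAND_RISE
    return [
        SSESpec(STRAND, n_res, (0.0, 0.0, 0.0), (0.0, 0.0, 1.0)),
        SSESpec(STRAND, n_res, (separation, 0.0, height), (0.0, 0.0, -1.0)),
    ]


def meander_recipe(n_strands: int = 3, n_res: int = 6, separation: float = 4.8) -> list[SSESpec]:
    """Up-down-up meander of antiparallel strands."""
    height = (n_res - 1) * STRAND_RISE
    specs = []
    for k in range(n_strands):
        if k % 2 == 0:
            specs.append(SSESpec(STRAND, n_res, (k * separation, 0.0, 0.0), (0.0, 0.0, 1.0)))
        else:
            specs.append(
                SSESpec(STRAND, n_res, (k * separation, 0.0, height), (0.0, 0.0, -1.0))
            )
    return specs


def barrel_recipe(n_strands: int = 6, n_res: int = 6) -> list[SSESpec]:
    """Strands on a closed ring: a (deliberately unsupported) beta-barrel."""
    radius = 4.8 / (2 * math.sin(math.pi / n_strands))
    height = (n_res - 1) * STRAND_RISE
    specs = []
    for k in range(n_strands):
        phi = 2 * math.pi * k / n_strands
        x, y = radius * math.cos(phi), radius * math.sin(phi)
        if k % 2 == 0:
            specs.append(SSESpec(STRAND, n_res, (x, y, 0.0), (0.0, 0.0, 1.0)))
        else:
            specs.append(SSESpec(STRAND, n_res, (x, y, height), (0.0, 0.0, -1.0)))
    return specs


def mixed_recipe() -> list[SSESpec]:
    """Two helices plus a hairpin: exercises every element type at once."""
    return [
        SSESpec(HELIX, 12, (0.0, 0.0, 0.0), (0.0, 0.0, 1.0)),
        SSESpec(STRAND, 6, (10.0, 0.0, 16.5), (0.0, 0.0, -1.0)),
        SSESpec(STRAND, 6, (14.8, 0.0, 0.0), (0.0, 0.0, 1.0)),
        SSESpec(HELIX, 10, (24.0, 0.0, 16.5), (0.0, 0.0, -1.0)),
    ]


def random_helix_recipe(rng: np.random.Generator, n_sse: int) -> list[SSESpec]:
    """Random layered all-helix domain, emulating helix-bundle packing.

    Helix axes point roughly up or down (tilted by up to ~30 deg) and origins
    follow a lateral random walk alternating between two layers, the way real
    alpha-domain architectures stack helices.  All-helix recipes keep the
    sheet topology trivially valid while exercising layout geometry over
    genuinely 3D arrangements.
    """
    specs: list[SSESpec] = []
    placed_points: list[np.ndarray] = []
    xy = np.zeros(2)
    layer_z = 11.0
    for k in range(n_sse):
        n_res = int(rng.integers(8, 15))
        layer = k % 2
        for _attempt in range(500):
            step = rng.uniform(7.0, 11.0)
            phi = rng.uniform(0, 2 * np.pi)
            cand_xy = xy + step * np.array([np.cos(phi), np.sin(phi)])
            z0 = layer * layer_z + rng.normal(scale=1.5)
            # axes alternate up/down with a random tilt
            tilt = rng.uniform(0, np.radians(30))
            azim = rng.uniform(0, 2 * np.pi)
            sign = 1.0 if k % 2 == 0 else -1.0
            direction = np.array(
                [
                    np.sin(tilt) * np.cos(azim),
                    np.sin(tilt) * np.sin(azim),
                    sign * np.cos(tilt),
                ]
            )
            origin = np.array([cand_xy[0], cand_xy[1], z0])
            trace = make_ideal_helix(n_res, origin, direction)
            if not placed_points:
                break
            d = np.linalg.norm(
                trace[:, None, :] - np.array(placed_points)[None, :, :], axis=-1
            )
            if d.min() > 3.5:
                break
        else:
            raise GenerationError("could not place a non-clashing helix")
        specs.append(SSESpec(HELIX, n_res, tuple(origin), tuple(direction)))
        placed_points.extend(trace)
        xy = cand_xy
    return specs


# -- fixture export ----------------------------------------------------------


def export_family(
    family: dict[str, tuple[DomainStructure, GroundTruth]],
    out_dir: str | Path,
    family_id: str = "9.99.99.99",
) -> Path:
    """Write each member as minimal PDB plus a domain-list/ground-truth JSON.

    The JSON doubles as the input manifest for the command-line pipeline.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"family": family_id, "domains": {}}
    for dom_id in sorted(family):
        domain, truth = family[dom_id]
        pdb_path = out / f"{dom_id}.pdb"
        write_minimal_pdb(domain.residues, pdb_path)
        manifest["domains"][dom_id] = {
            "path": pdb_path.name,
            "ranges": [
                [domain.residues[0].chain_id, domain.residues[0].seq_number,
                 domain.residues[-1].seq_number]
            ],
            "ground_truth": {
                "labels": truth.labels,
                "kinds": truth.kinds,
                "ranges": [list(r) for r in truth.ranges],
            },
        }
    manifest_path = out / "family.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path
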