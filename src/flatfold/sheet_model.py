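"""Group beta-strands into sheets and build each sheet's rigid 2D template.

Two strands are ladder-paired when their mean nearest-Calpha distance is at or
below a cutoff (default 5.5 A, typical ladder spacing plus slack); the pair is
parallel when the N-to-C axis directions agree (non-negative dot product).
Connected components of the pairing graph become sheets.  Only simple paths are
supported: beta-barrels (cycles) and bifurcated sheets (degree >= 3) raise an
UnsupportedTopologyError naming the strands, by design rather than being drawn
approximately.

A sheet's template places its strands as parallel segments in path order,
separated by a fixed spacing, with direction signs propagated from the first
strand through the ladder orientations.  The template is rigid: during layout
only the sheet's center and angle move.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .errors import UnsupportedTopologyError
from .sse_annotation import SSE3D, STRAND
from .structure_io import DomainStructure

PARALLEL = "parallel"
ANTIPARALLEL = "antiparallel"

#: Default mean nearest-Calpha pairing cutoff (Angstrom).
PAIRING_CUTOFF = 5.5
#: Default inter-strand spacing of the 2D template (layout units).
SHEET_SPACING = 4.8


@dataclass
class SheetModel:
    """Ordered, oriented 2D template of one beta-sheet."""

    sheet_id: str
    strand_labels: list[str]  # spatial (path) order across the sheet
    orientations: list[str]  # between adjacent pairs, parallel/antiparallel
    template_2d: dict[str, tuple[np.ndarray, int]]  # label -> (offset, sign)
    spacing: float = SHEET_SPACING

    def __post_init__(self):
        if len(set(self.strand_labels)) != len(self.strand_labels):
            raise ValueError("duplicate strand labels in sheet")
        if len(self.orientations) != max(len(self.strand_labels) - 1, 0):
            raise ValueError("orientations must cover adjacent pairs")


def mean_nearest_ca_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric mean of nearest-neighbour Calpha distances between two strands."""
    d = cdist(a, b)
    return float(np.concatenate([d.min(axis=1), d.min(axis=0)]).mean())


def pair_strands(
    domain: DomainStructure,
    strands: list[SSE3D],
    cutoff: float = PAIRING_CUTOFF,
) -> list[tuple[str, str, str]]:
    """Ladder adjacency between strands, as (label_a, label_b, orientation)."""
    coords = domain.coords
    pairs = []
    for i in range(len(strands)):
        for j in range(i + 1, len(strands)):
            a, b = strands[i], strands[j]
            if a.sse_type != STRAND or b.sse_type != STRAND:
                continue
            ca = coords[a.start_index : a.end_index + 1]
            cb = coords[b.start_index : b.end_index + 1]
            if mean_nearest_ca_distance(ca, cb) <= cutoff:
                orientation = (
                    PARALLEL if float(np.dot(a.direction, b.direction)) >= 0 else ANTIPARALLEL
                )
                pairs.append((a.label or f"#{i}", b.label or f"#{j}", orientation))
    return pairs


def build_sheets(
    strands: list[SSE3D],
    adjacency: list[tuple[str, str, str]],
    spacing: float = SHEET_SPACING,
) -> list[SheetModel]:
    """Turn pairing components into rigid sheet templates.

    Components must be simple paths; the path is traversed from the endpoint
    with the lexicographically smaller label, making the template independent
    of input order.  Sheets are returned ordered by their first strand's
    sequence position and named S1, S2, ...
    """
    by_label = {s.label: s for s in strands}
    graph = nx.Graph()
    graph.add_nodes_from(by_label)
    orient: dict[frozenset, str] = {}
    for a, b, o in adjacency:
        graph.add_edge(a, b)
        orient[frozenset((a, b))] = o

    components = []
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if sub.number_of_edges() >= len(comp):
            raise UnsupportedTopologyError(
                f"beta-barrel (cyclic sheet) not supported: {sorted(comp)}",
                strands=sorted(comp),
            )
        if any(d > 2 for _, d in sub.degree):
            raise UnsupportedTopologyError(
                f"bifurcated sheet (branch point) not supported: {sorted(comp)}",
                strands=sorted(comp),
            )
        if len(comp) == 1:
            order = list(comp)
        else:
            ends = sorted(n for n, d in sub.degree if d == 1)
            order = list(nx.shortest_path(sub, ends[0], ends[-1]))
        components.append(order)

    components.sort(key=lambda order: min(by_label[l].start_index for l in order))

    sheets = []
    for k, order in enumerate(components, start=1):
        orientations = [
            orient[frozenset((order[i], order[i + 1]))] for i in range(len(order) - 1)
        ]
        n = len(order)
        template: dict[str, tuple[np.ndarray, int]] = {}
        sign = 1
        for i, label in enumerate(order):
            y = i * spacing - (n - 1) * spacing / 2.0
            template[label] = (np.array([0.0, y]), sign)
            if i < n - 1:
                sign = sign if orientations[i] == PARALLEL else -sign
        sheets.append(
            SheetModel(
                sheet_id=f"S{k}",
                strand_labels=order,
                orientations=orientations,
                template_2d=template,
                spacing=spacing,
            )
        )
    return sheets


def sheet_element_label(sheet: SheetModel) -> str:
    """Cross-member stable element name for a sheet: its sorted strand labels."""
    return "S[" + "+".join(sorted(sheet.strand_labels)) + "]"
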