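import itertools
import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flatfold.family_stats import PRIMARY, SECONDARY
from flatfold.layout_engine import (
    DomainDiagram,
    LayoutConfig,
    diagram_from_json,
    diagram_to_json,
    element_anchors_3d,
    initial_positions,
    place_elements,
    select_starting_layout,
    sse_glyph_geometry,
    stress,
    wrap_angle,
    _dist_matrix,
)
from flatfold.sse_annotation import HELIX, STRAND, SSE3D
from flatfold.sheet_model import SheetModel


def _helix(label, start, end):
    return SSE3D(label, HELIX, "A", 0, 9, np.asarray(start, float), np.asarray(end, float))


class TestAnchors:
    def test_helix_anchor_is_axis_midpoint(self):
        sse = _helix("H1", (0, 0, 0), (0, 0, 10))
        anchors = element_anchors_3d([sse], [])
        np.testing.assert_allclose(anchors["H1"], [0, 0, 5])

    def test_sheet_anchor_is_strand_midpoint_centroid(self):
        s1 = SSE3D("E1", STRAND, "A", 0, 4, np.array([0.0, 0, 0]), np.array([0.0, 0, 0.1]))
        s2 = SSE3D("E2", STRAND, "A", 10, 14, np.array([4.0, 0, 0]), np.array([4.0, 0, 0.1]))
        sheet = SheetModel("S1", ["E1", "E2"], ["antiparallel"],
                           {"E1": (np.zeros(2), 1), "E2": (np.array([0.0, 4.8]), -1)})
        anchors = element_anchors_3d([s1, s2], [sheet])
        np.testing.assert_allclose(anchors["S[E1+E2]"], [2.0, 0.0, 0.05])

    def test_single_strand_sheet_anchor(self):
        s1 = SSE3D("E1", STRAND, "A", 0, 4, np.array([1.0, 2, 3]), np.array([1.0, 2, 9]))
        sheet = SheetModel("S1", ["E1"], [], {"E1": (np.zeros(2), 1)})
        anchors = element_anchors_3d([s1], [sheet])
        np.testing.assert_allclose(anchors["S[E1]"], [1, 2, 6])


class TestStress:
    def test_exact_planar_embedding_is_zero(self):
        anchors = {l: np.array([x, y, 0.0]) for l, (x, y) in
                   {"A": (0, 0), "B": (5, 1), "C": (2, 7)}.items()}
        positions = {l: a[:2] for l, a in anchors.items()}
        assert stress(positions, anchors) == pytest.approx(0.0, abs=1e-12)

    def test_two_elements_squared_error(self):
        anchors = {"A": np.zeros(3), "B": np.array([10.0, 0, 0])}
        positions = {"A": np.zeros(2), "B": np.array([7.0, 0.0])}
        assert stress(positions, anchors) == pytest.approx(9.0)

    def test_deviation_penalty_term(self):
        anchors = {"A": np.zeros(3), "B": np.array([10.0, 0, 0])}
        positions = {"A": np.zeros(2), "B": np.array([10.0, 0.0])}
        start = {"B": np.array([10.0, 2.0])}
        assert stress(positions, anchors, start, lam=0.5) == pytest.approx(0.5 * 4.0)

    def test_mismatched_labels_rejected(self):
        with pytest.raises(ValueError):
            stress({"A": np.zeros(2)}, {"B": np.zeros(3)})

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_rigid_invariance_without_penalty(self, seed):
        """Stress depends only on pairwise 2D distances: rotating and
        translating every position leaves it unchanged when lambda = 0."""
        rng = np.random.default_rng(seed)
        labels = list("ABCDE")
        anchors = {l: rng.normal(scale=10, size=3) for l in labels}
        positions = {l: rng.normal(scale=10, size=2) for l in labels}
        theta = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = rng.normal(scale=5, size=2)
        moved = {l: rot @ p + shift for l, p in positions.items()}
        assert stress(moved, anchors) == pytest.approx(stress(positions, anchors), rel=1e-9)


class TestInitialPositions:
    def test_coplanar_anchors_project_exactly(self):
        rng = np.random.default_rng(4)
        labels = list("ABCDEF")
        raw = {l: np.array([*rng.normal(scale=8, size=2), 0.0]) for l in labels}
        # rotate the plane arbitrarily in 3D
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        anchors = {l: q @ v for l, v in raw.items()}
        positions, _ = initial_positions(anchors)
        for a, b in itertools.combinations(labels, 2):
            d3 = np.linalg.norm(anchors[a] - anchors[b])
            d2 = np.linalg.norm(positions[a] - positions[b])
            assert d2 == pytest.approx(d3, abs=1e-9)

    def test_start_covering_all_labels_returned_exactly(self):
        anchors = {"A": np.zeros(3), "B": np.array([5.0, 0, 0]), "C": np.array([0, 5.0, 0])}
        start = {"A": np.array([1.0, 1.0]), "B": np.array([6.0, 1.0]), "C": np.array([1.0, 6.0])}
        positions, _ = initial_positions(anchors, start)
        for l in start:
            np.testing.assert_allclose(positions[l], start[l])

    def test_partial_start_kept_exactly(self):
        anchors = {"A": np.zeros(3), "B": np.array([5.0, 0, 0]), "C": np.array([0, 5.0, 0])}
        start = {"A": np.array([10.0, 0.0]), "B": np.array([15.0, 0.0])}
        positions, _ = initial_positions(anchors, start)
        np.testing.assert_allclose(positions["A"], [10.0, 0.0])
        np.testing.assert_allclose(positions["B"], [15.0, 0.0])
        assert np.all(np.isfinite(positions["C"]))


class TestSelectStartingLayout:
    def _diagram(self, domain_id, labels):
        from flatfold.layout_engine import LayoutElement

        elements = [
            LayoutElement(l, "helix", np.zeros(2), 0.0, 10.0) for l in labels
        ]
        return DomainDiagram(domain_id, elements, list(labels), 0.0, 0.0)

    def test_empty_computed_set(self):
        assert select_starting_layout({"H1"}, {}, 0.5) is None

    def test_identical_label_set_selected(self):
        diag = self._diagram("synA00", ["H1", "H2"])
        got = select_starting_layout({"H1", "H2"}, {"synA00": diag}, 0.5)
        assert got is not None
        assert got[0].domain_id == "synA00"
        assert got[1] == {"H1", "H2"}

    def test_insufficient_overlap_returns_none(self):
        diag = self._diagram("synA00", ["X1"])
        labels = {"H1", "H2", "H3", "H4", "X1"}
        assert select_starting_layout(labels, {"synA00": diag}, 0.5) is None

    def test_tie_broken_by_smaller_domain_id(self):
        d1 = self._diagram("synA01", ["H1", "H2"])
        d2 = self._diagram("synA02", ["H1", "H2"])
        got = select_starting_layout({"H1", "H2"}, {"synA02": d2, "synA01": d1}, 0.5)
        assert got[0].domain_id == "synA01"


class TestPlaceElements:
    def test_single_element_at_origin(self):
        anchors = {"H1": np.array([3.0, 4.0, 5.0])}
        positions, _, _ = place_elements(anchors, {"H1": PRIMARY}, None, LayoutConfig())
        np.testing.assert_allclose(positions["H1"], [0.0, 0.0], atol=1e-12)

    def test_coplanar_primaries_reach_machine_zero(self):
        rng = np.random.default_rng(9)
        labels = list("ABCDE")
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        anchors = {l: q @ np.array([*rng.normal(scale=10, size=2), 0.0]) for l in labels}
        classes = {l: PRIMARY for l in labels}
        positions, _, _ = place_elements(anchors, classes, None, LayoutConfig())
        scale = np.mean([np.linalg.norm(anchors[a] - anchors[b])
                         for a, b in itertools.combinations(labels, 2)])
        assert stress(positions, anchors) < 1e-6 * scale**2

    def test_three_elements_beat_grid_oracle(self):
        """The continuous optimum is at most the best of all 5x5-grid
        placements of three elements (exhaustively enumerated)."""
        anchors = {"A": np.array([0.0, 0, 0]), "B": np.array([6.0, 1, 2]),
                   "C": np.array([2.0, 5, 4])}
        labels = sorted(anchors)
        d3 = _dist_matrix(np.array([anchors[l] for l in labels]))
        grid = [np.array([x, y]) for x in np.linspace(0, 10, 5) for y in np.linspace(0, 10, 5)]
        oracle = min(
            sum((np.linalg.norm(p[i] - p[j]) - d3[i, j]) ** 2
                for i in range(3) for j in range(i + 1, 3))
            for p in itertools.product(grid, repeat=3)
        )
        positions, _, _ = place_elements(anchors, {l: PRIMARY for l in labels}, None, LayoutConfig())
        assert stress(positions, anchors) <= oracle + 1e-6

    def test_final_objective_not_worse_than_initial(self):
        rng = np.random.default_rng(12)
        anchors = {f"H{i}": rng.normal(scale=12, size=3) for i in range(7)}
        classes = {l: PRIMARY for l in anchors}
        init, _ = initial_positions(anchors)
        positions, _, _ = place_elements(anchors, classes, None, LayoutConfig())
        assert stress(positions, anchors) <= stress(init, anchors) + 1e-9

    def test_secondary_stage_freezes_primaries(self):
        """Primary positions are untouched by the secondary stage: they remain
        a stationary point of the primary-only objective."""
        from flatfold.layout_engine import _stage_value_grad

        rng = np.random.default_rng(13)
        anchors = {f"H{i}": rng.normal(scale=12, size=3) for i in range(6)}
        labels = sorted(anchors)
        classes = {l: (PRIMARY if i < 4 else SECONDARY) for i, l in enumerate(labels)}
        positions, _, _ = place_elements(anchors, classes, None, LayoutConfig())
        p = np.array([positions[l] for l in labels])
        d3 = _dist_matrix(np.array([anchors[l] for l in labels]))
        primary = np.array([classes[l] == PRIMARY for l in labels])
        mask = primary[:, None] & primary[None, :]
        np.fill_diagonal(mask, False)
        _, grad = _stage_value_grad(
            p, d3, mask, np.where(primary)[0], np.zeros_like(p),
            np.zeros(len(labels), dtype=bool), 0.0,
        )
        assert np.abs(grad).max() < 1e-2

    def test_deviation_penalty_reduces_displacement(self):
        rng = np.random.default_rng(14)
        anchors = {f"H{i}": rng.normal(scale=12, size=3) for i in range(6)}
        classes = {l: PRIMARY for l in anchors}
        start_full, _, _ = place_elements(anchors, classes, None, LayoutConfig())
        # perturb the anchors (a "second member") and restart from the layout
        anchors2 = {l: a + rng.normal(scale=0.5, size=3) for l, a in anchors.items()}
        disp = {}
        for lam in (0.0, 0.05):
            p, _, _ = place_elements(anchors2, classes, start_full,
                                     LayoutConfig(lambda_dev=lam))
            disp[lam] = sum(np.linalg.norm(p[l] - start_full[l]) for l in p)
        assert disp[0.05] < disp[0.0]


class TestLayoutFamily:
    def test_family_diagrams_are_deterministic(self, jittered_family, annotated_family, family_stats):
        from flatfold.layout_engine import layout_family

        structures = {d: dom for d, (dom, _) in jittered_family.items()}
        one = layout_family(annotated_family, structures, family_stats, LayoutConfig())
        two = layout_family(annotated_family, structures, family_stats, LayoutConfig())
        for dom_id in one:
            assert json.dumps(diagram_to_json(one[dom_id])) == json.dumps(
                diagram_to_json(two[dom_id])
            )

    def test_every_sse_represented(self, annotated_family, family_diagrams):
        for dom_id, sses in annotated_family.members.items():
            glyphs = sse_glyph_geometry(family_diagrams[dom_id])
            assert set(glyphs) == {s.label for s in sses}

    def test_shared_labels_coherent_across_members(self, family_diagrams):
        """Diagrams of jittered copies are intercomparable: every shared
        element stays within 20% of the mean inter-element distance."""
        shared = set.intersection(*[d.labels for d in family_diagrams.values()])
        centers = {l: np.array([d.element(l).center_2d for d in family_diagrams.values()])
                   for l in shared}
        means = [c.mean(axis=0) for c in centers.values()]
        mean_dist = np.mean([np.linalg.norm(a - b)
                             for a, b in itertools.combinations(means, 2)])
        for l, c in centers.items():
            assert np.linalg.norm(c.std(axis=0)) <= 0.2 * mean_dist

    def test_final_stress_recorded_nonnegative(self, family_diagrams):
        for d in family_diagrams.values():
            assert d.stress >= 0.0
            assert d.normalized_stress >= 0.0


class TestAngles:
    def test_wrap_angle_range(self):
        for a in (-10.0, -np.pi, 0.0, np.pi, 10.0):
            w = wrap_angle(a)
            assert -np.pi <= w < np.pi

    def test_in_plane_axes_get_projected_angles(self):
        from flatfold.layout_engine import Frame2D, adjust_angles

        frame = Frame2D(np.zeros(3), np.array([1.0, 0, 0]), np.array([0.0, 1, 0]))
        axes = {"A": np.array([1.0, 0, 0]), "B": np.array([0.0, 1, 0])}
        positions = {"A": np.zeros(2), "B": np.array([50.0, 50.0])}
        dims = {"A": (10.0, 3.0), "B": (10.0, 3.0)}
        angles, warnings = adjust_angles(axes, positions, frame, dims)
        assert angles["A"] == pytest.approx(0.0)
        assert angles["B"] == pytest.approx(np.pi / 2)
        assert warnings == []

    def test_out_of_plane_axis_warns_and_zeroes(self):
        from flatfold.layout_engine import Frame2D, adjust_angles

        frame = Frame2D(np.zeros(3), np.array([1.0, 0, 0]), np.array([0.0, 1, 0]))
        axes = {"A": np.array([0.0, 0, 1.0])}
        angles, warnings = adjust_angles(axes, {"A": np.zeros(2)}, frame, {"A": (10.0, 3.0)})
        assert angles["A"] == 0.0
        assert len(warnings) == 1

    def test_parallel_3d_helices_stay_parallel_in_2d(self, family_diagrams):
        # H1 and H2 of the mixed recipe are antiparallel in 3D (same line
        # direction): their unsigned 2D directions should agree within 10 deg.
        for diagram in family_diagrams.values():
            try:
                a1 = diagram.element("H1").angle
                a2 = diagram.element("H2").angle
            except KeyError:
                continue
            diff = abs(wrap_angle(a1 - a2))
            assert min(diff, abs(np.pi - diff)) < np.radians(10)


def test_layout_json_round_trip(family_diagrams):
    for diagram in family_diagrams.values():
        doc = diagram_to_json(diagram)
        again = diagram_from_json(doc)
        assert diagram_to_json(again) == doc
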