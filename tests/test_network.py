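"""Skeletonization, vectorization and branch metrics."""

import numpy as np
import pytest

from mitomorph.network import (
    branch_metrics,
    distance_map,
    skeletonize,
    vectorize,
)
from mitomorph.segment import label_objects


def line_mask(n=11):
    mask = np.zeros((5, n + 4), bool)
    mask[2, 2 : 2 + n] = True
    return mask


class TestSkeletonize:
    def test_empty_mask(self):
        assert not skeletonize(np.zeros((8, 8), bool)).any()

    def test_rod_skeleton_is_centerline_row(self):
        mask = np.zeros((9, 27), bool)
        mask[3:6, 3:24] = True  # 21x3 rod, centre row 4
        sk = skeletonize(mask)
        ys, xs = np.nonzero(sk)
        assert set(ys) == {4}
        assert len(xs) == xs.max() - xs.min() + 1  # contiguous

    def test_bump_spur_pruned_to_clean_rod_skeleton(self):
        clean = np.zeros((11, 27), bool)
        clean[4:7, 3:24] = True
        bumped = clean.copy()
        bumped[3, 12:14] = True  # 2-px bump on the edge
        assert np.array_equal(skeletonize(bumped), skeletonize(clean))

    def test_pruning_never_erases_a_component(self):
        mask = np.zeros((7, 7), bool)
        mask[3, 2:5] = True  # tiny 3-px rod
        sk = skeletonize(mask, prune_iterations=5)
        assert sk.sum() >= 1

    def test_prune_zero_keeps_spur(self):
        clean = np.zeros((11, 27), bool)
        clean[4:7, 3:24] = True
        bumped = clean.copy()
        bumped[3, 12:14] = True
        assert skeletonize(bumped, 0).sum() >= skeletonize(bumped, 2).sum()


class TestVectorize:
    def test_straight_line(self):
        g = vectorize(line_mask(11))
        assert g.n_br == 1 and g.n_bp == 0 and g.n_ep == 2
        assert g.branches[0].length == pytest.approx(10.0)

    def test_y_shape_three_arms(self):
        sk = np.zeros((25, 25), bool)
        sk[12, 2:13] = True  # west arm
        sk[2:12, 12] = True  # north arm
        sk[13:23, 12] = True  # south arm
        sk[12, 12] = True
        g = vectorize(sk)
        assert g.n_br == 3 and g.n_bp == 1 and g.n_ep == 3
        # under 8-connectivity the pixels flanking the crossing are also
        # junction pixels, so the merged branch point absorbs up to one
        # step of each arm: total in [27, 30]
        total = sum(b.length for b in g.branches)
        assert 27.0 <= total <= 30.0

    def test_two_disjoint_lines_are_additive(self):
        a = line_mask(11)
        b = np.zeros_like(a)
        combined = np.zeros((12, 15), bool)
        combined[2, 2:13] = True
        combined[8, 2:13] = True
        g = vectorize(combined)
        single = vectorize(line_mask(11))
        assert g.n_br == 2 * single.n_br
        assert g.n_ep == 2 * single.n_ep
        assert g.l_br_roi == pytest.approx(2 * single.l_br_roi)

    def test_anisotropic_spacing_lengths(self):
        sk = np.zeros((5, 3, 3), bool)
        sk[0:5, 1, 1] = True  # axial line of 5 voxels
        g = vectorize(sk, spacing=(0.364, 0.0845, 0.0845))
        assert g.branches[0].length == pytest.approx(4 * 0.364)

    def test_isolated_pixel_is_unrepresented_not_a_branch(self):
        sk = np.zeros((5, 5), bool)
        sk[2, 2] = True
        g = vectorize(sk)
        assert g.n_br == 0
        assert len(g.isolated_pixels) == 1

    def test_closed_ring_is_single_closed_branch(self):
        # diamond ring: pure diagonal steps, every pixel degree 2 under
        # 8-connectivity (an axis-aligned square ring has degree-3 pixels
        # next to its corners and is not a junction-free cycle)
        yy, xx = np.mgrid[0:9, 0:9]
        sk = np.abs(yy - 4) + np.abs(xx - 4) == 3
        g = vectorize(sk)
        assert g.n_br == 1
        assert g.branches[0].closed
        assert g.n_ep == 0 and g.n_bp == 0
        assert g.branches[0].length == pytest.approx(12 * np.sqrt(2))

    def test_non_thin_input_rejected(self):
        with pytest.raises(ValueError, match="unit-width"):
            vectorize(np.ones((6, 6), bool))

    def test_object_attribution(self, test_panel):
        image, gt = test_panel
        lab = label_objects(image > 0, spacing=(1, 1))
        g = vectorize(skeletonize(image > 0), spacing=(1, 1), labeled=lab)
        assert g.represented_objects() <= set(range(1, lab.object_count + 1))

    def test_tree_components_satisfy_euler_relation(self):
        """For each acyclic component: branches = nodes - 1 in the
        contracted graph (checked via the exported topology view)."""
        sk = np.zeros((25, 25), bool)
        sk[12, 2:23] = True
        sk[2:12, 12] = True  # T-shape: one junction, 3 arms
        g = vectorize(sk)
        nxg = g.to_networkx()
        import networkx as nx

        for comp in nx.connected_components(nxg):
            sub = nxg.subgraph(comp)
            if nx.is_forest(nx.Graph(sub)):
                assert sub.number_of_edges() == len(comp) - 1

    def test_min_length_filter(self):
        g = vectorize(line_mask(11))
        assert g.filter_min_length(20.0).n_br == 0
        assert g.filter_min_length(5.0).n_br == 1


class TestDistanceMap:
    def test_single_pixel_value_one(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        d = distance_map(mask)
        assert d[2, 2] == pytest.approx(1.0)
        assert d[0, 0] == 0.0

    def test_rod_centerline_half_width(self):
        mask = np.zeros((9, 27), bool)
        mask[3:6, 3:24] = True  # width 3, centre row 4
        d = distance_map(mask)
        centre = d[4, 8:19]
        # centre-to-background-centre convention: width/2 + 0.5
        assert np.allclose(centre, 2.0)

    def test_doubling_z_step_doubles_axial_distances(self):
        # slab spanning the full xy plane: nearest background is axial
        mask = np.zeros((7, 3, 3), bool)
        mask[1:6] = True
        d1 = distance_map(mask, (1, 1, 1))
        d2 = distance_map(mask, (2, 1, 1))
        assert d1[3, 1, 1] == pytest.approx(3.0)
        assert d2[3, 1, 1] == pytest.approx(6.0)


class TestBranchMetrics:
    def test_direct_formula(self):
        # constant distance 1 µm along a 10 µm branch: D=2, V=10π
        sk = np.zeros((3, 15), bool)
        sk[1, 2:13] = True
        g = vectorize(sk)
        dmap = np.ones_like(sk, float)
        g = branch_metrics(g, dmap)
        b = g.branches[0]
        assert b.d_br == pytest.approx(2.0)
        assert b.v_br == pytest.approx(np.pi * 1.0 * b.length)
        assert g.v_br_roi == pytest.approx(b.v_br)

    def test_rod_diameter_within_documented_tolerance(self):
        mask = np.zeros((9, 27), bool)
        mask[3:6, 3:24] = True  # true width 3
        sk = skeletonize(mask)
        g = branch_metrics(vectorize(sk), distance_map(mask))
        # centre-to-background convention biases D upward by <= 1 px
        assert 3.0 <= g.branches[0].d_br <= 4.0

    def test_calibration_scaling(self):
        mask = np.zeros((9, 27), bool)
        mask[3:6, 3:24] = True
        sk = skeletonize(mask)
        c = 0.25
        g1 = branch_metrics(vectorize(sk, (1, 1)), distance_map(mask, (1, 1)))
        gc = branch_metrics(vectorize(sk, (c, c)), distance_map(mask, (c, c)))
        assert gc.branches[0].length == pytest.approx(c * g1.branches[0].length)
        assert gc.branches[0].d_br == pytest.approx(c * g1.branches[0].d_br)
        assert gc.branches[0].v_br == pytest.approx(c**3 * g1.branches[0].v_br)


class TestGraphExports:
    def test_tables_and_json(self, tmp_path):
        sk = np.zeros((25, 25), bool)
        sk[12, 2:23] = True
        sk[2:12, 12] = True
        mask = sk.copy()
        g = branch_metrics(vectorize(sk), distance_map(mask))
        bt = g.branch_table()
        assert set(bt.columns) >= {"branch_id", "object_id", "L_BR", "D_BR", "V_BR"}
        assert len(bt) == g.n_br
        nt = g.node_table()
        assert len(nt) == g.n_bp + g.n_ep
        g.to_json(tmp_path / "graph.json")
        import json

        payload = json.loads((tmp_path / "graph.json").read_text())
        assert len(payload["branches"]) == g.n_br
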