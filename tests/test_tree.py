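"""Cumulative embedding, binning, branching detection, assembly, export."""

import numpy as np
import pytest

from hodgeflow import tree as tm
from hodgeflow.simplicial_complex import SimplicialComplex


def line_sc(n=6):
    pts = np.c_[np.arange(float(n)), np.zeros(n)]
    edges = np.array([(i, i + 1) for i in range(n - 1)])
    return SimplicialComplex(
        n_vertices=n, edges=edges, triangles=np.zeros((0, 3), int), layout=pts
    )


def synthetic_binned(
    p=6, h=2, diverge_after=3, spread=0.05, m=12, seed=0, exact_shared=True
):
    """Two groups sharing a backbone through bin `diverge_after`, then apart.

    With ``exact_shared`` the trunk bins are bit-identical between groups
    (distance exactly 0 there); otherwise each group gets independent noise.
    """
    rng = np.random.default_rng(seed)
    coords, backbone, compact = {}, {}, {}
    last = {}
    shared = {
        k: np.array([k * 0.2, 0.0])[:h] + rng.normal(0, spread, (m, h))
        for k in range(diverge_after + 1)
    }
    for g in (0, 1):
        for k in range(p):
            if k <= diverge_after and exact_shared:
                pts = shared[k]  # groups identical through the shared bins
            elif k <= diverge_after:
                pts = np.array([k * 0.2, 0.0])[:h] + rng.normal(0, spread, (m, h))
            else:
                centre = np.zeros(h)
                centre[0] = k * 0.2
                centre[1] = (1 if g == 0 else -1) * 2.0 * (k - diverge_after)
                pts = centre + rng.normal(0, spread, (m, h))
            coords[(g, k)] = pts
            backbone[(g, k)] = pts.mean(axis=0)
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            compact[(g, k)] = float(d.sum() / (m * m))
        last[g] = p - 1
    return tm.BinnedGroups(
        p=p,
        boundaries=np.linspace(0, 1, p + 1),
        groups=[0, 1],
        coords=coords,
        backbone=backbone,
        compactness=compact,
        last_bin=last,
    )


class TestCumulativeEmbedding:
    def test_final_point_equals_trajectory_embedding(self, bifurcation_fit):
        fit = bifurcation_fit
        cum = fit.cumulative
        for i in range(fit.ensemble.n_paths):
            assert np.allclose(
                cum.curves[i][-1], fit.ensemble.embedding[i], atol=1e-12
            )

    def test_steps_telescope(self):
        sc = line_sc()
        rng = np.random.default_rng(1)
        H = rng.standard_normal((sc.n_edges, 2))
        path = np.array([0, 1, 2, 3])
        cum = tm.cumulative_embedding([path], sc, H)
        curve = cum.curves[0]
        # v_{s+1} - v_s is the harmonic image of the single step indicator
        for s in range(len(curve) - 1):
            step = H[cum.step_edges[0][s + 1]] * cum.step_signs[0][s + 1]
            assert np.allclose(curve[s + 1] - curve[s], step, atol=1e-12)
        # first point is the first step itself (v_0 = origin)
        assert np.allclose(curve[0], H[cum.step_edges[0][0]] * cum.step_signs[0][0])


class TestBinning:
    def test_uniform_split_single_group(self):
        sc = line_sc(9)
        eids = np.arange(sc.n_edges)
        coords = {0: (eids, np.linspace(0, 1, sc.n_edges)[:, None])}
        edge_pt = np.linspace(0, 1, sc.n_edges)
        binned = tm.bin_by_pseudotime(coords, edge_pt, p=4)
        sizes = [len(binned.coords[(0, k)]) for k in range(4)]
        assert sum(sizes) == sc.n_edges
        assert max(sizes) - min(sizes) <= 1

    def test_bin_index_monotone_in_pseudotime(self):
        rng = np.random.default_rng(2)
        edge_pt = rng.random(30)
        coords = {0: (np.arange(30), rng.standard_normal((30, 2)))}
        binned = tm.bin_by_pseudotime(coords, edge_pt, p=5)
        for k in range(5):
            if (0, k) not in binned.coords:
                continue
        order = np.argsort(edge_pt)
        ks = np.searchsorted(binned.boundaries, edge_pt[order], side="right") - 1
        assert np.all(np.diff(np.clip(ks, 0, 4)) >= 0)

    def test_p_validation(self):
        with pytest.raises(ValueError):
            tm.bin_by_pseudotime({0: (np.array([0]), np.zeros((1, 1)))}, np.zeros(1), p=1)


class TestGroupDistance:
    def test_identical_groups_distance_zero(self):
        b = synthetic_binned()
        b.coords[(1, 0)] = b.coords[(0, 0)]
        b.backbone[(1, 0)] = b.backbone[(0, 0)]
        b.compactness[(1, 0)] = b.compactness[(0, 0)]
        assert tm.group_distance(b, 0, 1, 0) == 0.0

    def test_hand_computed_two_bin_embedding(self):
        # frozen arithmetic oracle for the backbone/compactness distance
        coords = {
            (0, 0): np.array([[0.0, 0], [2, 0]]),
            (1, 0): np.array([[0.0, 2], [0, 4]]),
        }
        backbone = {k: v.mean(axis=0) for k, v in coords.items()}
        compact = {}
        for k, v in coords.items():
            d = np.sqrt(((v[:, None] - v[None]) ** 2).sum(-1))
            compact[k] = float(d.sum() / 4)
        b = tm.BinnedGroups(
            p=1,
            boundaries=np.array([0.0, 1.0]),
            groups=[0, 1],
            coords=coords,
            backbone=backbone,
            compactness=compact,
            last_bin={0: 0, 1: 0},
        )
        # backbones (1,0) and (0,3); compactness = 1 for both (mean pairwise
        # over ordered pairs: (0+2+2+0)/4 = 1)
        assert np.isclose(compact[(0, 0)], 1.0)
        expect = np.linalg.norm(np.array([1.0, 0.0]) - np.array([0.0, 3.0]))
        assert np.isclose(tm.group_distance(b, 0, 1, 0), expect)

    def test_symmetry(self):
        b = synthetic_binned(seed=3)
        for k in range(b.p):
            assert tm.group_distance(b, 0, 1, k) == tm.group_distance(b, 1, 0, k)

    def test_singleton_bin_substitutes_median(self):
        b = synthetic_binned()
        b.coords[(0, 2)] = b.coords[(0, 2)][:1]
        b.backbone[(0, 2)] = b.coords[(0, 2)][0]
        b.compactness[(0, 2)] = 0.0
        with pytest.warns(UserWarning, match="singleton"):
            d = tm.group_distance(b, 0, 1, 2)
        assert np.isfinite(d)


class TestBranchingDetection:
    def test_known_divergence_bin(self):
        b = synthetic_binned(p=6, diverge_after=3)
        bins = tm.detect_branching_points(b, sigma=1.0)
        assert bins[(0, 1)] == 3

    def test_sigma_limits(self):
        # independent noise so every bin distance is strictly positive
        b = synthetic_binned(p=6, diverge_after=3, exact_shared=False)
        assert tm.detect_branching_points(b, sigma=1e-12)[(0, 1)] == 0
        assert tm.detect_branching_points(b, sigma=1e9)[(0, 1)] == b.p - 1


class TestAssembleTree:
    def test_two_groups_one_branching_point(self):
        b = synthetic_binned()
        bins = tm.detect_branching_points(b)
        tree = tm.assemble_tree(bins, b)
        assert tree.n_leaves == 2
        kinds = [m.kind for m in tree.milestones]
        assert kinds.count("branching") == 1
        assert len(tree.branches) == 3  # trunk + two arms

    def test_three_group_caterpillar(self):
        # groups 0,1 split late (bin 5); group 2 splits early (bin 2)
        b = synthetic_binned(p=8, diverge_after=5)
        rng = np.random.default_rng(4)
        for k in range(8):
            if k <= 2:
                pts = b.coords[(0, k)]  # group 2 shares the trunk bins
            else:
                centre = np.array([k * 0.2, 6.0 * (k - 2)])
                pts = centre + rng.normal(0, 0.05, (12, 2))
            b.coords[(2, k)] = pts
            b.backbone[(2, k)] = pts.mean(axis=0)
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            b.compactness[(2, k)] = float(d.sum() / 144)
        b.groups = [0, 1, 2]
        b.last_bin[2] = 7
        bins = tm.detect_branching_points(b)
        assert bins[(0, 1)] == 5 and bins[(0, 2)] == 2 and bins[(1, 2)] == 2
        tree = tm.assemble_tree(bins, b)
        assert tree.n_leaves == 3
        # caterpillar: 0 and 1 merge first (highest bin), then 2 joins
        assert tree.merge_order[0][:2] == ((0,), (1,))
        assert tree.merge_order[1][2] == 2
        # milestone network is a connected tree
        net = {(br.from_milestone, br.to_milestone) for br in tree.branches}
        assert len(net) == len(tree.milestones) - 1

    def test_newick_topology(self):
        b = synthetic_binned()
        tree = tm.assemble_tree(tm.detect_branching_points(b), b)
        nwk = tree.newick()
        assert nwk.endswith(";")
        assert nwk.count("leaf_") == 2 and "branching_0" in nwk


class TestAllocationAndExport:
    def test_bifurcation_cells_follow_ground_truth(
        self, bifurcation_fit, bifurcation_cloud
    ):
        df = bifurcation_fit.assignment
        gt = bifurcation_cloud.branch_id[[int(c[1:]) for c in df["cell"]]]
        # map each recovered branch to its dominant arm and measure purity
        import pandas as pd

        gt = pd.Series(gt, index=df.index)
        agree = (
            df.groupby("branch")
            .apply(lambda s: (gt[s.index] == gt[s.index].mode()[0]).sum())
            .sum()
            / len(df)
        )
        assert agree >= 0.90

    def test_assignment_total_over_cells(self, bifurcation_fit):
        df = bifurcation_fit.assignment
        assert len(df) == bifurcation_fit.embedding.n_cells
        assert (df["branch"] != "unassigned").all()
        assert df["position"].between(0, 1).all()

    def test_export_roundtrip(self, bifurcation_fit, tmp_path):
        tree = bifurcation_fit.tree
        tm.export_tree(tree, tmp_path)
        back = tm.read_tree_json(tmp_path)
        assert [m.id for m in back.milestones] == [m.id for m in tree.milestones]
        assert [b.id for b in back.branches] == [b.id for b in tree.branches]
        import pandas as pd

        pct = pd.read_csv(tmp_path / "milestone_percentages.tsv", sep="\t")
        sums = pct.groupby("cell")["percentage"].sum()
        assert np.allclose(sums, 1.0)
        nwk = (tmp_path / "tree.newick").read_text()
        assert nwk.count("leaf_") == tree.n_leaves
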