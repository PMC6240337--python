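import numpy as np
import pandas as pd
import pytest

from molshape import (ancestral_states_bm, cull_to_genus, phenogram,
                      phylomorphospace, prune_to_taxa, read_newick,
                      simulate_bm, simulate_ou, write_newick)
from molshape.errors import (BadParameter, EmptyIntersection, ParseError)
from molshape.synthetic_data import make_yule_tree


def gls_oracle(tree, y):
    """Independent ancestral-state oracle: minimize the BM quadratic form
    sum_edges (x_child - x_parent)^2 / length over all unobserved states
    (root included), as a linear least-squares problem."""
    unknowns = [v for v in range(tree.n_nodes) if v >= tree.n_tips]
    idx = {v: k for k, v in enumerate(unknowns)}
    rows, rhs = [], []
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        u = tree.parent[v]
        w = 1.0 / np.sqrt(tree.edge_length[v])
        row = np.zeros(len(unknowns))
        b = 0.0
        if v in idx:
            row[idx[v]] += w
        else:
            b -= w * y[v]
        row[idx[u]] -= w
        rows.append(row)
        rhs.append(b)
    sol = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)[0]
    full = np.empty(tree.n_nodes)
    full[: tree.n_tips] = y
    for v, k in idx.items():
        full[v] = sol[k]
    return full


class TestNewickIO:
    def test_three_tip_parse(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        assert sorted(t.tip_labels) == ["A", "B", "C"]
        assert t.is_ultrametric()
        assert t.height == pytest.approx(2.0)

    def test_roundtrip_preserves_topology_and_lengths(self):
        t1 = make_yule_tree(12, seed=5)
        t2 = read_newick(write_newick(t1))
        d1 = t1.patristic_distance_matrix()
        d2 = t2.patristic_distance_matrix().loc[d1.index, d1.columns]
        np.testing.assert_allclose(d2.to_numpy(), d1.to_numpy(), atol=1e-9)

    def test_unbalanced_input_rejected(self):
        with pytest.raises(ParseError):
            read_newick("((A:1,B:1):1,C:2")


class TestPrune:
    def test_keep_all_is_identity(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        assert prune_to_taxa(t, {"A", "B", "C"}) is t

    def test_two_tip_distance_preserved(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        p = prune_to_taxa(t, {"A", "C"})
        assert p.n_tips == 2
        assert p.patristic_distance_matrix().loc["A", "C"] == pytest.approx(4.0)

    def test_patristic_submatrix_preserved(self):
        tree = make_yule_tree(30, seed=2)
        rng = np.random.default_rng(0)
        keep = sorted(rng.choice(tree.tip_labels, 12, replace=False))
        sub = prune_to_taxa(tree, keep)
        full = tree.patristic_distance_matrix().loc[keep, keep]
        red = sub.patristic_distance_matrix().loc[keep, keep]
        np.testing.assert_allclose(red.to_numpy(), full.to_numpy(),
                                   atol=1e-9)
        assert sub.is_ultrametric()

    def test_empty_intersection(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(EmptyIntersection):
            prune_to_taxa(t, {"Z"})

    def test_genus_culling_deterministic(self):
        t = read_newick("(((Uro_a:1,Uro_b:1):1,(Tit_x:1.5,Tit_a:1.5):0.5):1,"
                        "Cha_z:3);")
        culled = cull_to_genus(t)
        assert sorted(culled.tip_labels) == ["Cha_z", "Tit_a", "Uro_a"]


class TestSimulateBM:
    def test_zero_rate_constant(self):
        tree = make_yule_tree(8, seed=1)
        out = simulate_bm(tree, 0.0, root_state=1.5, seed=0)
        np.testing.assert_allclose(out.to_numpy(), 1.5)

    def test_tip_variance_matches_closed_form(self):
        tree = read_newick("(A:3,B:3);")
        out = simulate_bm(tree, sigma2=2.0, seed=4, n_cols=10_000)
        var = out.loc["A"].to_numpy().var()
        assert var == pytest.approx(2.0 * 3.0, rel=0.05)

    def test_seed_reproducibility(self):
        tree = make_yule_tree(10, seed=3)
        a = simulate_bm(tree, 1.0, seed=9, n_cols=3)
        b = simulate_bm(tree, 1.0, seed=9, n_cols=3)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_rate_rejected(self):
        with pytest.raises(BadParameter):
            simulate_bm(make_yule_tree(4, seed=0), -1.0)


class TestSimulateOU:
    def test_zero_noise_collapses_to_optimum(self):
        tree = make_yule_tree(6, seed=2)
        out = simulate_ou(tree, alpha=0.5, sigma2=0.0, theta_by_regime=[2.0],
                          seed=0)
        np.testing.assert_allclose(out.to_numpy(), 2.0)

    def test_stationary_variance(self):
        # deep single-regime tree: tip variance -> sigma2 / (2 alpha)
        tree = read_newick("(A:200,B:200);")
        alpha, sigma2 = 0.05, 3.0
        out = simulate_ou(tree, alpha, sigma2, seed=8, n_cols=10_000)
        assert out.loc["A"].to_numpy().var() == pytest.approx(
            sigma2 / (2 * alpha), rel=0.05)

    def test_alpha_to_zero_limit_matches_bm(self):
        tree = read_newick("(A:5,B:5);")
        ou = simulate_ou(tree, 1e-8, 1.0, seed=3, n_cols=20_000)
        bm_var = 1.0 * 5.0
        assert ou.loc["A"].to_numpy().var() == pytest.approx(bm_var,
                                                             rel=0.05)

    def test_shift_only_affects_descendants(self):
        tree = make_yule_tree(16, seed=6, age=100.0)
        # shift on a mid-depth internal edge
        cands = [e for e, v in enumerate(tree.edge_nodes)
                 if 3 <= len(tree.descendant_tips(v)) <= 8]
        e = cands[0]
        below = {tree.tip_labels[t]
                 for t in tree.descendant_tips(tree.edge_nodes[e])}
        base = simulate_ou(tree, 0.05, 1.0, theta_by_regime=[0.0, 0.0],
                           shift_edges=[e], seed=5, n_cols=200)
        shifted = simulate_ou(tree, 0.05, 1.0, theta_by_regime=[0.0, 40.0],
                              shift_edges=[e], seed=5, n_cols=200)
        outside = [t for t in tree.tip_labels if t not in below]
        pd.testing.assert_frame_equal(base.loc[outside], shifted.loc[outside])
        assert (shifted.loc[sorted(below)].mean(axis=1)
                > base.loc[sorted(below)].mean(axis=1) + 5).all()


class TestAncestralStates:
    def test_equal_branches_symmetric_mean(self):
        tree = read_newick("(A:1,B:1);")
        states = ancestral_states_bm(tree, pd.Series({"A": 0.0, "B": 2.0}))
        assert states[tree.root] == pytest.approx(1.0)

    def test_inverse_branch_length_weighting(self):
        tree = read_newick("(A:1,B:3);")
        states = ancestral_states_bm(tree, pd.Series({"A": 0.0, "B": 4.0}))
        # (0/1 + 4/3) / (1/1 + 1/3) = 1.0
        assert states[tree.root] == pytest.approx(1.0)

    def test_matches_explicit_gls_oracle(self):
        tree = make_yule_tree(8, seed=7)
        rng = np.random.default_rng(1)
        y = rng.standard_normal(tree.n_tips)
        states = ancestral_states_bm(tree, y)
        np.testing.assert_allclose(states, gls_oracle(tree, y), atol=1e-8)

    def test_shift_equivariance(self):
        tree = make_yule_tree(10, seed=4)
        rng = np.random.default_rng(2)
        y = rng.standard_normal(tree.n_tips)
        s1 = ancestral_states_bm(tree, y)
        s2 = ancestral_states_bm(tree, y + 7.5)
        np.testing.assert_allclose(s2, s1 + 7.5, atol=1e-8)


class TestProjections:
    def test_star_tree_root_at_gls_mean(self):
        tree = read_newick("(A:1,B:1,C:1,D:1);")
        y = pd.Series({"A": 1.0, "B": 2.0, "C": 3.0, "D": 6.0})
        place = phylomorphospace(tree, y, y)
        assert place.coords[tree.root, 0] == pytest.approx(3.0)

    def test_constant_trait_everywhere(self):
        tree = make_yule_tree(6, seed=9)
        y = pd.Series(2.5, index=tree.tip_labels)
        place = phylomorphospace(tree, y, y)
        np.testing.assert_allclose(place.coords, 2.5, atol=1e-8)

    def test_internal_nodes_equal_ancestral_estimates(self):
        tree = make_yule_tree(9, seed=11)
        rng = np.random.default_rng(3)
        y1 = pd.Series(rng.standard_normal(9), index=tree.tip_labels)
        y2 = pd.Series(rng.standard_normal(9), index=tree.tip_labels)
        place = phylomorphospace(tree, y1, y2)
        np.testing.assert_allclose(place.coords[:, 0],
                                   ancestral_states_bm(tree, y1), atol=1e-12)
        np.testing.assert_allclose(place.coords[:, 1],
                                   ancestral_states_bm(tree, y2), atol=1e-12)

    def test_phenogram_tips_at_tree_depth(self):
        tree = make_yule_tree(7, seed=13)
        y = pd.Series(np.arange(7.0), index=tree.tip_labels)
        place = phenogram(tree, y)
        np.testing.assert_allclose(place.coords[: tree.n_tips, 0],
                                   tree.height, atol=1e-9)
        np.testing.assert_allclose(place.coords[: tree.n_tips, 1],
                                   y.to_numpy())
        # x-coordinates are root-to-node path sums
        np.testing.assert_allclose(place.coords[:, 0], tree.node_depths())
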