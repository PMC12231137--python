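import io

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode

from microtraits import phylo
from microtraits.synthetic_data import brownian_tips, yule_tree

from conftest import random_count_table


def _random_additive_matrix(rng, n_tips):
    tree = yule_tree(n_tips, rng)
    for node in tree.traverse(include_self=False):
        node.length = rng.uniform(0.2, 1.5)
    tree.unroot()
    dm = tree.tip_tip_distances()
    return DistanceMatrix(dm.data, dm.ids), tree


class TestNeighborJoining:
    def test_additive_matrix_reproduced_exactly(self, rng):
        dm, _ = _random_additive_matrix(rng, 5)
        tree = phylo.neighbor_joining(dm)
        back = tree.tip_tip_distances(list(dm.ids))
        assert np.abs(back.data - dm.data).max() < 1e-9

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(
            np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float), ids=list("abc")
        )
        tree = phylo.neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(4.0)

    def test_ultrametric_quartet_pairs_correctly(self):
        # two tight pairs (a,b) and (c,d): the quartet ab|cd must be chosen
        d = np.array(
            [
                [0.0, 0.2, 1.0, 1.0],
                [0.2, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.2],
                [1.0, 1.0, 0.2, 0.0],
            ]
        )
        tree = phylo.neighbor_joining(DistanceMatrix(d, ids=list("abcd")))
        # brute force: of the three quartets, ab|cd has minimal path length sum
        tip_sets = [
            frozenset(t.name for t in n.tips())
            for n in tree.non_tips(include_self=False)
        ]
        assert frozenset("ab") in tip_sets or frozenset("cd") in tip_sets

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(np.array([[0, 1], [1, 0]], float), ids=list("ab"))
        with pytest.raises(ValueError):
            phylo.neighbor_joining(dm)

    def test_output_unrooted(self, rng):
        dm, _ = _random_additive_matrix(rng, 6)
        assert len(phylo.neighbor_joining(dm).children) == 3


class TestIlrBalance:
    def test_symmetric_groups_zero(self):
        counts = pd.DataFrame({"s1": [10, 10], "s2": [3, 3]}, index=["a", "b"])
        y = phylo.ilr_balance(counts, ["a"], ["b"], pseudocount=0)
        np.testing.assert_allclose(y, 0.0, atol=1e-12)

    def test_e_fold_ratio(self):
        a = 1000.0
        counts = pd.DataFrame({"s": [np.e * a, a]}, index=["r", "s"])
        y = phylo.ilr_balance(counts, ["r"], ["s"], pseudocount=0)
        assert y["s"] == pytest.approx(np.sqrt(0.5), abs=1e-4)

    def test_swapping_groups_negates(self, rng):
        counts = random_count_table(rng, 6, 4, low=1, high=40)
        r, s = ["t000", "t001"], ["t002", "t003", "t004"]
        y1 = phylo.ilr_balance(counts, r, s)
        y2 = phylo.ilr_balance(counts, s, r)
        np.testing.assert_allclose(y1, -y2, atol=1e-12)

    def test_overlapping_groups_rejected(self, rng):
        counts = random_count_table(rng, 4, 3)
        with pytest.raises(ValueError, match="overlap"):
            phylo.ilr_balance(counts, ["t000"], ["t000", "t001"])


def _planted_case(seed, n_tips=32, shift=0.3, noise=0.05):
    rng = np.random.default_rng(seed)
    tree = yule_tree(n_tips, rng)
    tree.unroot()
    cands = [n for n in tree.non_tips() if 4 <= len(list(n.tips())) <= 12]
    clade = frozenset(t.name for t in cands[0].tips())
    tips = [t.name for t in tree.tips()]
    cov = pd.Series(0.5 + rng.normal(0, noise, len(tips)), index=tips)
    cov[list(clade)] += shift
    counts = pd.DataFrame(
        rng.integers(1, 100, (len(tips), 6)),
        index=tips,
        columns=[f"s{j}" for j in range(6)],
    )
    return tree, clade, cov, counts, tips


class TestPhylofactor:
    def test_planted_clade_is_first_factor(self):
        tree, clade, cov, counts, tips = _planted_case(seed=11)
        res = phylo.phylofactor(counts, tree, cov, mode="taxon", n_factors=3)
        groups = {res.factors[0].group_r, res.factors[0].group_s}
        assert clade in groups

    def test_first_factor_matches_exhaustive_search(self):
        tree, clade, cov, counts, tips = _planted_case(seed=12)
        res = phylo.phylofactor(counts, tree, cov, mode="taxon", n_factors=1)
        best = None
        for _, _, below in phylo._edge_table(tree):
            g1, g2 = below, frozenset(tips) - below
            if not g1 or not g2:
                continue
            score, _ = phylo._edge_objective(counts, cov, g1, g2, "taxon", 1.0)
            if score is not None and (best is None or score > best[0]):
                best = (score, g1)
        assert res.factors[0].objective == pytest.approx(best[0])
        assert {res.factors[0].group_r, res.factors[0].group_s} == {
            best[1], frozenset(tips) - best[1]
        }

    def test_constant_covariate_never_significant(self):
        tree, _, cov, counts, tips = _planted_case(seed=13)
        flat = pd.Series(0.5, index=tips)
        res = phylo.phylofactor(counts, tree, flat, mode="taxon", n_factors=5)
        assert res.n_significant == 0

    def test_factors_partition_within_bins(self):
        tree, _, cov, counts, tips = _planted_case(seed=14)
        res = phylo.phylofactor(counts, tree, cov, mode="taxon", n_factors=6)
        seen_bins = [frozenset(tips)]
        for f in res.factors:
            merged = f.group_r | f.group_s
            assert merged in seen_bins
            assert not (f.group_r & f.group_s)
            assert f.group_r and f.group_s
            seen_bins.remove(merged)
            seen_bins.extend([f.group_r, f.group_s])

    def test_sample_mode_finds_ph_linked_clade(self):
        rng = np.random.default_rng(21)
        tree = yule_tree(24, rng)
        tree.unroot()
        cands = [n for n in tree.non_tips() if 5 <= len(list(n.tips())) <= 10]
        clade = frozenset(t.name for t in cands[0].tips())
        tips = [t.name for t in tree.tips()]
        ph = pd.Series(rng.uniform(5, 9, 20), index=[f"s{j}" for j in range(20)])
        base = rng.uniform(20, 60, (len(tips), 20))
        boost = np.exp(0.8 * (ph.to_numpy() - 7.0))
        for i, t in enumerate(tips):
            if t in clade:
                base[i] *= boost
        counts = pd.DataFrame(
            np.round(base).astype(int) + 1, index=tips, columns=ph.index
        )
        res = phylo.phylofactor(counts, tree, ph, mode="sample", n_factors=1)
        groups = {res.factors[0].group_r, res.factors[0].group_s}
        assert clade in groups

    def test_excess_factors_truncated(self):
        tree, _, cov, counts, tips = _planted_case(seed=15, n_tips=8)
        res = phylo.phylofactor(counts, tree, cov, mode="taxon", n_factors=100)
        assert len(res.factors) <= 7  # at most n_tips - 1 splits


class TestBlombergK:
    def test_star_tree_k_is_one(self, rng):
        star = TreeNode.read(io.StringIO("(A:1,B:1,C:1,D:1,E:1,F:1);"))
        y = pd.Series(rng.normal(size=6), index=list("ABCDEF"))
        k, _ = phylo.blomberg_k(star, y, n_perm=19, seed=0)
        assert k == pytest.approx(1.0, abs=1e-9)

    def test_shuffled_deep_tree_k_below_one(self):
        rng = np.random.default_rng(30)
        tree = yule_tree(64, rng)
        below = 0
        reps = 30
        for i in range(reps):
            y = brownian_tips(tree, np.random.default_rng(100 + i))
            shuffled = pd.Series(
                np.random.default_rng(200 + i).permutation(y.to_numpy()),
                index=y.index,
            )
            k, _ = phylo.blomberg_k(tree, shuffled, n_perm=0)
            below += k < 1
        assert below >= 0.9 * reps

    def test_constant_values_rejected(self):
        star = TreeNode.read(io.StringIO("(A:1,B:1,C:1);"))
        with pytest.raises(ValueError):
            phylo.blomberg_k(star, pd.Series(1.0, index=list("ABC")))

    def test_permutation_p_detects_brownian_signal(self):
        rng = np.random.default_rng(31)
        tree = yule_tree(64, rng)
        y = brownian_tips(tree, rng)
        _, p = phylo.blomberg_k(tree, y, n_perm=199, seed=1)
        assert p < 0.05


class TestPagelLambda:
    def test_brownian_truth_recovers_high_lambda(self):
        rng = np.random.default_rng(40)
        tree = yule_tree(120, rng)
        lam, _ = phylo.pagel_lambda(tree, brownian_tips(tree, rng))
        assert lam >= 0.9

    def test_iid_truth_recovers_low_lambda(self):
        rng = np.random.default_rng(41)
        tree = yule_tree(120, rng)
        y = pd.Series(
            rng.normal(size=120), index=[t.name for t in tree.tips()]
        )
        lam, _ = phylo.pagel_lambda(tree, y)
        assert lam <= 0.1

    def test_loglik_maximal_at_estimate(self):
        rng = np.random.default_rng(42)
        tree = yule_tree(40, rng)
        y = brownian_tips(tree, rng)
        lam, ll = phylo.pagel_lambda(tree, y)
        c, yv, _ = phylo._align(tree, y)
        assert ll >= phylo._lambda_loglik(0.0, c, yv) - 1e-6
        assert ll >= phylo._lambda_loglik(1.0, c, yv) - 1e-6


class TestPgls:
    def test_star_tree_equals_ols(self, rng):
        star = TreeNode.read(io.StringIO("(A:1,B:1,C:1,D:1,E:1,F:1,G:1);"))
        idx = list("ABCDEFG")
        x = pd.Series(rng.normal(size=7), index=idx)
        y = pd.Series(rng.normal(size=7), index=idx)
        res = phylo.pgls(star, y, x.to_frame("x"), lam=1.0)
        from scipy import stats as st

        ols = st.linregress(x, y)
        assert res.loc["x", "coef"] == pytest.approx(ols.slope, abs=1e-9)
        assert res.loc["intercept", "coef"] == pytest.approx(
            ols.intercept, abs=1e-9
        )

    def test_noiseless_fit_exact(self, rng):
        tree = yule_tree(20, np.random.default_rng(50))
        tips = [t.name for t in tree.tips()]
        x = pd.Series(rng.normal(size=20), index=tips)
        y = 2.0 * x
        res = phylo.pgls(tree, y, x.to_frame("x"), lam=1.0)
        assert res.loc["x", "coef"] == pytest.approx(2.0, abs=1e-9)

    def test_slope_recovery_under_brownian_noise(self):
        rng = np.random.default_rng(51)
        tree = yule_tree(150, rng)
        tips = [t.name for t in tree.tips()]
        x = pd.Series(rng.normal(size=150), index=tips)
        y = x + brownian_tips(tree, rng, sigma2=0.5)
        res = phylo.pgls(tree, y, x.to_frame("x"))
        assert abs(res.loc["x", "coef"] - 1.0) <= 3 * res.loc["x", "se"]

    def test_rank_deficient_design_rejected(self, rng):
        tree = yule_tree(10, np.random.default_rng(52))
        tips = [t.name for t in tree.tips()]
        x = pd.Series(rng.normal(size=10), index=tips)
        frame = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="rank"):
            phylo.pgls(tree, x, frame)


class TestCovariance:
    def test_matches_path_length_identity(self, rng):
        tree = yule_tree(12, np.random.default_rng(60))
        tree.unroot()
        c = phylo.phylo_covariance(tree)
        rooted = tree.copy().root_at_midpoint()
        dm = rooted.tip_tip_distances(list(c.index))
        # C_ii + C_jj - 2 C_ij equals the tip-to-tip path length
        for i, a in enumerate(c.index):
            for b in list(c.index)[i + 1:]:
                lhs = c.loc[a, a] + c.loc[b, b] - 2 * c.loc[a, b]
                assert lhs == pytest.approx(dm[a, b], abs=1e-9)
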