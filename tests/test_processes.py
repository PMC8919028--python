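"""betaMNTD/betaNTI, RC-Bray, process partitioning, chi-square, odds ratios."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from skbio import TreeNode

from microstates import processes as pr
from microstates.synth import simulate_tree

from conftest import toy_table


def brute_force_bmntd(counts_k, counts_m, D, weighted=True):
    """Exhaustive double-loop betaMNTD oracle."""
    k = np.where(counts_k > 0)[0]
    m = np.where(counts_m > 0)[0]
    fk = counts_k[k] / counts_k.sum() if weighted else np.full(len(k), 1 / len(k))
    fm = counts_m[m] / counts_m.sum() if weighted else np.full(len(m), 1 / len(m))
    term1 = sum(
        f * min(D[i, j] for j in m) for f, i in zip(fk, k)
    )
    term2 = sum(
        f * min(D[i, j] for i in k) for f, j in zip(fm, m)
    )
    return 0.5 * (term1 + term2)


def _random_instance(rng, n_taxa):
    newick = simulate_tree(n_taxa, seed=int(rng.integers(1e6)))
    asvs = [f"ASV_{i + 1}" for i in range(n_taxa)]
    counts = rng.integers(0, 20, size=(2, n_taxa))
    for row in counts:
        if row.sum() == 0:
            row[rng.integers(n_taxa)] = 1
    return newick, asvs, counts


class TestBetaMNTD:
    def test_identical_communities_zero(self):
        newick = simulate_tree(5, seed=0)
        t = toy_table([[3, 1, 0, 2, 0], [3, 1, 0, 2, 0]])
        value = pr.beta_mntd(t, newick, [("S1", "S2")]).iloc[0]
        assert value == pytest.approx(0.0, abs=1e-12)

    def test_singleton_communities_give_patristic_distance(self):
        newick = simulate_tree(4, seed=1)
        D = pr.patristic_matrix(newick, ["ASV_1", "ASV_2", "ASV_3", "ASV_4"])
        t = toy_table([[9, 0, 0, 0], [0, 0, 5, 0]])
        value = pr.beta_mntd(t, newick, [("S1", "S2")]).iloc[0]
        assert value == pytest.approx(D[0, 2])

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_oracle(self, weighted):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n_taxa = int(rng.integers(3, 11))
            newick, asvs, counts = _random_instance(rng, n_taxa)
            D = pr.patristic_matrix(newick, asvs)
            ours = pr.beta_mntd(
                toy_table(counts, asv_ids=asvs), newick, [("S1", "S2")],
                weighted=weighted,
            ).iloc[0]
            oracle = brute_force_bmntd(counts[0], counts[1], D, weighted)
            assert ours == pytest.approx(oracle, abs=1e-12)

    def test_missing_asv_raises(self):
        newick = simulate_tree(3, seed=2)
        t = toy_table([[1, 1, 1, 1], [1, 1, 1, 1]])
        with pytest.raises(ValueError, match="missing from tree"):
            pr.beta_mntd(t, newick, [("S1", "S2")])


class TestBetaNTI:
    def test_star_tree_shuffle_is_noop(self):
        star = "(" + ",".join(f"ASV_{i + 1}:1.0" for i in range(6)) + ");"
        t = toy_table([[5, 3, 0, 0, 1, 0], [0, 0, 4, 2, 0, 6]])
        res = pr.beta_nti(t, star, [("S1", "S2")], n_null=99, seed=0)
        assert res["beta_nti"].iloc[0] == 0.0

    def test_branch_length_rescaling_invariance(self):
        rng = np.random.default_rng(5)
        newick, asvs, counts = _random_instance(rng, 12)
        t = toy_table(counts, asv_ids=asvs)
        pairs = [("S1", "S2")]
        base = pr.beta_nti(t, newick, pairs, n_null=199, seed=7)
        tree = TreeNode.read(io.StringIO(newick))
        for node in tree.traverse():
            if node.length is not None:
                node.length *= 7.3
        scaled_newick = str(tree)
        scaled = pr.beta_nti(t, scaled_newick, pairs, n_null=199, seed=7)
        assert scaled["beta_nti"].iloc[0] == pytest.approx(
            base["beta_nti"].iloc[0], rel=1e-9
        )
        # betaMNTD itself scales linearly
        assert scaled["beta_mntd_obs"].iloc[0] == pytest.approx(
            7.3 * base["beta_mntd_obs"].iloc[0], rel=1e-9
        )

    def test_tip_order_permutation_invariance(self):
        rng = np.random.default_rng(8)
        newick, asvs, counts = _random_instance(rng, 8)
        t = toy_table(counts, asv_ids=asvs)
        tree = TreeNode.read(io.StringIO(newick))
        for node in tree.non_tips():
            node.children = node.children[::-1]
        flipped = str(tree)
        a = pr.beta_nti(t, newick, [("S1", "S2")], n_null=199, seed=3)
        b = pr.beta_nti(t, flipped, [("S1", "S2")], n_null=199, seed=3)
        assert a["beta_mntd_obs"].iloc[0] == pytest.approx(
            b["beta_mntd_obs"].iloc[0], abs=1e-12
        )


class TestRaupCrick:
    def test_identical_abundant_pair_is_strongly_negative(self):
        rng = np.random.default_rng(0)
        pool = rng.multinomial(600, np.full(50, 0.02), size=10)
        pool[pool.sum(axis=1) == 0, 0] = 1
        twin = np.tile(rng.multinomial(600, [0.5, 0.5] + [0.0] * 48), (2, 1))
        counts = np.vstack([twin, pool])
        t = toy_table(counts)
        res = pr.raup_crick_bray(t, [("S1", "S2")], n_null=199, seed=1)
        assert res["rc_bray"].iloc[0] <= -0.95

    def test_rc_always_in_unit_interval(self):
        rng = np.random.default_rng(2)
        counts = rng.multinomial(600, np.full(30, 1 / 30), size=12)
        t = toy_table(counts)
        pairs = [(f"S{i + 1}", f"S{j + 1}") for i in range(12) for j in range(i + 1, 12)]
        res = pr.raup_crick_bray(t, pairs, n_null=149, seed=2)
        assert res["rc_bray"].between(-1, 1).all()

    def test_empty_sample_rejected(self):
        t = toy_table([[0, 0], [1, 2]])
        with pytest.raises(ValueError, match="empty"):
            pr.raup_crick_bray(t, [("S1", "S2")], n_null=99)


class TestPartition:
    def test_threshold_arithmetic(self):
        df = pd.DataFrame(
            {"beta_nti": [3.0, -3.0, 0.0], "rc_bray": [0.0, 0.0, 0.2]}
        )
        p = pr.partition_processes(df, group_col=None)
        f = p.fractions.loc["all"]
        assert f["variable_selection"] == pytest.approx(1 / 3)
        assert f["homogeneous_selection"] == pytest.approx(1 / 3)
        assert f["drift"] == pytest.approx(1 / 3)
        assert f["dispersal_limitation"] == 0.0

    def test_all_drift(self):
        df = pd.DataFrame({"beta_nti": np.zeros(10), "rc_bray": np.zeros(10)})
        p = pr.partition_processes(df, group_col=None)
        assert p.fractions.loc["all", "drift"] == 1.0

    def test_selection_examples_from_thresholds(self):
        labels = pr.classify_processes([2.5, -2.5, 1.9, 0.0], [0, 0, 0.96, -0.96])
        assert labels.tolist() == [
            "variable_selection", "homogeneous_selection",
            "dispersal_limitation", "homogenizing_dispersal",
        ]

    def test_recount_oracle_on_random_grid(self):
        rng = np.random.default_rng(3)
        b = rng.normal(0, 2.5, 10_000)
        r = rng.uniform(-1, 1, 10_000)
        ours = pr.classify_processes(b, r)
        for bi, ri, cat in zip(b, r, ours):
            if bi > 2:
                expected = "variable_selection"
            elif bi < -2:
                expected = "homogeneous_selection"
            elif ri > 0.95:
                expected = "dispersal_limitation"
            elif ri < -0.95:
                expected = "homogenizing_dispersal"
            else:
                expected = "drift"
            assert cat == expected

    def test_fractions_sum_to_one_and_counts_reconcile(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "beta_nti": rng.normal(0, 2, 500),
                "rc_bray": rng.uniform(-1, 1, 500),
                "site": rng.choice(["gut", "oral", "skin"], 500),
            }
        )
        p = pr.partition_processes(df)
        np.testing.assert_allclose(p.fractions.sum(axis=1), 1.0, atol=1e-12)
        assert p.counts.sum().sum() + p.n_missing.sum() == 500

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        hst.floats(min_value=-10, max_value=10, allow_nan=False),
        hst.floats(min_value=-1, max_value=1, allow_nan=False),
    )
    def test_every_defined_pair_gets_exactly_one_category(self, b, r):
        (label,) = pr.classify_processes([b], [r])
        assert label in pr.PROCESS_CATEGORIES


class TestChiSquare:
    def _partition(self, counts):
        df = pd.DataFrame(counts, columns=list(pr.PROCESS_CATEGORIES))
        df.index.name = "site"
        return pr.ProcessPartition(
            counts=df, fractions=df.div(df.sum(axis=1), axis=0),
            n_missing=pd.Series(0, index=df.index),
        )

    def test_identical_distributions_give_zero(self):
        p = self._partition([[10, 10, 10, 10, 60], [10, 10, 10, 10, 60]])
        res = pr.process_chisq(p)
        assert res.loc["overall", "chi2"] == pytest.approx(0.0)
        assert res.loc["overall", "p_value"] == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # one process vs rest: [[30, 70], [70, 30]] -> chi2 = 32 exactly
        p = self._partition([[30, 0, 0, 0, 70], [70, 0, 0, 0, 30]])
        res = pr.process_chisq(p)
        assert res.loc["variable_selection", "chi2"] == pytest.approx(32.0)


class TestOddsRatio:
    def _turnover(self, bnti, si, sj):
        idx = pd.MultiIndex.from_tuples(
            [(f"a{i}", f"b{i}") for i in range(len(bnti))],
            names=["sample_i", "sample_j"],
        )
        df = pd.DataFrame({"beta_nti": bnti, "site": "gut"}, index=idx)
        labels = {}
        for i, (x, y) in enumerate(zip(si, sj)):
            labels[f"a{i}"] = x
            labels[f"b{i}"] = y
        return df, pd.Series(labels)

    def test_hand_built_2x2(self):
        # involving X: 20 deterministic / 30 not; others: 10 / 50
        bnti = [3.0] * 20 + [0.0] * 30 + [3.0] * 10 + [0.0] * 50
        si = ["X"] * 50 + ["Y"] * 60
        sj = ["Z"] * 50 + ["Y"] * 60
        df, labels = self._turnover(bnti, si, sj)
        res = pr.deterministic_odds_ratio(df, labels, site="gut")
        assert res.loc["X", "odds_ratio"] == pytest.approx(20 * 50 / (30 * 10))
        assert not res.loc["X", "haldane_corrected"]

    def test_zero_cell_gets_haldane_correction(self):
        bnti = [3.0] * 5 + [0.0] * 5
        si = ["X"] * 5 + ["Y"] * 5
        sj = ["X"] * 5 + ["Y"] * 5
        df, labels = self._turnover(bnti, si, sj)
        res = pr.deterministic_odds_ratio(df, labels, site="gut")
        assert np.isfinite(res.loc["X", "odds_ratio"])
        assert res.loc["X", "haldane_corrected"]

    def test_ci_covers_one_under_independence(self):
        rng = np.random.default_rng(6)
        covered = 0
        n_rep = 300
        for _ in range(n_rep):
            deterministic = rng.random(120) < 0.3
            involves = rng.random(120) < 0.4
            bnti = np.where(deterministic, 3.0, 0.0)
            si = np.where(involves, "X", "Y")
            df, labels = self._turnover(bnti, si, si)
            res = pr.deterministic_odds_ratio(df, labels, site="gut")
            if "X" in res.index and res.loc["X", "ci_low"] <= 1 <= res.loc["X", "ci_high"]:
                covered += 1
        assert covered / n_rep >= 0.90
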