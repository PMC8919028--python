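"""Diversity measures, ordination, and permutation association tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from microstates import diversity as div

from conftest import toy_table


class TestAlphaDiversity:
    def test_uniform_four_asvs(self):
        a = div.alpha_diversity(toy_table([[10, 10, 10, 10]]))
        assert a["richness"].iloc[0] == 4
        assert a["shannon"].iloc[0] == pytest.approx(np.log(4))
        assert a["evenness"].iloc[0] == pytest.approx(1.0)

    def test_single_asv_has_no_evenness(self):
        a = div.alpha_diversity(toy_table([[42, 0]]))
        assert a["richness"].iloc[0] == 1
        assert a["shannon"].iloc[0] == 0.0
        assert np.isnan(a["evenness"].iloc[0])

    def test_shannon_formula(self):
        # p = (0.5, 0.25, 0.25) -> H = 1.0397 nats
        a = div.alpha_diversity(toy_table([[2, 1, 1]]))
        assert a["shannon"].iloc[0] == pytest.approx(1.0397, abs=1e-4)

    def test_asv_order_invariance(self):
        a = div.alpha_diversity(toy_table([[5, 3, 2, 9]]))
        b = div.alpha_diversity(toy_table([[9, 2, 3, 5]]))
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_base_two_option(self):
        a = div.alpha_diversity(toy_table([[10, 10]]), base=2)
        assert a["shannon"].iloc[0] == pytest.approx(1.0)


class TestBrayCurtis:
    def test_identical_samples(self):
        d = div.bray_curtis(toy_table([[3, 4], [3, 4]]))
        assert d[0, 1] == 0.0

    def test_disjoint_supports(self):
        d = div.bray_curtis(toy_table([[5, 0], [0, 7]]))
        assert d[0, 1] == 1.0

    def test_closed_form(self):
        d = div.bray_curtis(toy_table([[6, 2], [2, 2]]))
        assert d[0, 1] == pytest.approx(1 / 3)

    def test_matrix_properties(self, rarefied_cohort):
        rarefied, _, _ = rarefied_cohort
        d = div.bray_curtis(rarefied)
        m = np.asarray(d.data)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0)
        assert m.min() >= 0 and m.max() <= 1

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            div.bray_curtis(toy_table([[0, 0], [1, 2]]))


class TestPCoA:
    def test_three_equidistant_samples(self):
        d = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
                           ids=["a", "b", "c"])
        res = div.pcoa(d)
        assert len(res.eigenvalues) == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(20, 3))
        d = DistanceMatrix(squareform(pdist(points)), ids=[str(i) for i in range(20)])
        res = div.pcoa(d)
        rebuilt = squareform(pdist(res.coordinates.to_numpy()))
        assert np.abs(rebuilt - np.asarray(d.data)).max() < 1e-6

    def test_collinear_points_have_one_dominant_axis(self):
        xs = np.arange(6, dtype=float)[:, None]
        d = DistanceMatrix(squareform(pdist(xs)), ids=[str(i) for i in range(6)])
        res = div.pcoa(d)
        assert res.proportion_explained[0] > 0.999


class TestPermanova:
    def _clouds(self, sep, n=10, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(0, 1, (n, 4)), rng.normal(sep, 1, (n, 4))])
        ids = [f"s{i}" for i in range(2 * n)]
        d = DistanceMatrix(squareform(pdist(pts)), ids=ids)
        groups = np.array(["x"] * n + ["y"] * n)
        return d, groups

    def test_complete_separation_minimum_p(self):
        # n large enough that partition-preserving permutations (which tie
        # with the observed F) are vanishingly rare
        rng = np.random.default_rng(0)
        counts = np.zeros((20, 6), dtype=int)
        counts[:10, :3] = rng.integers(80, 120, (10, 3))  # disjoint ASV support
        counts[10:, 3:] = rng.integers(80, 120, (10, 3))
        d = div.bray_curtis(toy_table(counts))
        groups = np.array(["a"] * 10 + ["b"] * 10)
        res = div.permanova(d, groups, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.r2 > 0.95

    def test_statistic_matches_skbio(self):
        # independent implementation check of the pseudo-F and its scale
        from skbio.stats.distance import permanova as skbio_permanova

        d, groups = self._clouds(2.0, seed=1)
        ours = div.permanova(d, groups, n_perm=99, seed=0)
        theirs = skbio_permanova(
            d, pd.Series(groups, index=d.ids, name="group"), permutations=99
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_deterministic_given_seed(self):
        d, groups = self._clouds(1.0)
        a = div.permanova(d, groups, n_perm=199, seed=5)
        b = div.permanova(d, groups, n_perm=199, seed=5)
        assert (a.p_value, a.pseudo_f) == (b.p_value, b.pseudo_f)

    def test_single_group_rejected(self):
        d, _ = self._clouds(1.0)
        with pytest.raises(ValueError, match="2 groups"):
            div.permanova(d, np.array(["x"] * 20))

    def test_block_restriction_never_crosses_blocks(self):
        rng = np.random.default_rng(0)
        blocks = np.repeat(np.arange(5), 4)
        for _ in range(200):
            perm = div.permuted_indices(20, blocks, rng)
            assert (blocks[perm] == blocks).all()
            assert sorted(perm) == list(range(20))


class TestEnvfit:
    def _ordination(self, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(30, 5))
        d = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(30)])
        return div.pcoa(d)

    def test_axis_aligned_variable_r2_one(self):
        ordination = self._ordination()
        variable = ordination.coordinates["PC1"].to_numpy()
        res = div.envfit(ordination, variable, n_perm=99, seed=0)
        assert res.r2 == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_planted_factor_clusters(self):
        rng = np.random.default_rng(2)
        centers = np.array([[0, 0], [8, 0], [0, 8], [8, 8]])
        pts = np.vstack([c + rng.normal(0, 0.3, (10, 2)) for c in centers])
        d = DistanceMatrix(squareform(pdist(pts)), ids=[f"s{i}" for i in range(40)])
        ordination = div.pcoa(d)
        factor = np.repeat(list("abcd"), 10)
        res = div.envfit(ordination, factor, n_perm=199, seed=0)
        assert res.r2 > 0.8
        assert res.p_value == pytest.approx(1 / 200)

    def test_constant_variable_rejected(self):
        ordination = self._ordination()
        with pytest.raises(ValueError, match="constant"):
            div.envfit(ordination, np.ones(30))


class TestCohensD:
    def test_identical_groups(self):
        assert div.cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_one_pooled_sd_apart(self):
        x = np.array([0.0, 1.0, 2.0])
        y = x + 1.0  # pooled SD = 1
        assert div.cohens_d(y, x) == pytest.approx(1.0)

    def test_hand_computed(self):
        assert div.cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            div.cohens_d([2, 2, 2], [2, 2, 2])


class TestDissimilarityContrasts:
    def test_pair_partition_counts(self, rarefied_cohort):
        rarefied, meta, _ = rarefied_cohort
        d = div.bray_curtis(rarefied)
        pairs, founders = div.dissimilarity_contrasts(d, meta)
        one = pairs[pairs["patient_id"] == "P01"]
        # 12 samples -> C(12,2)=66 pairs; 3 sites x C(4,2)=18 within-site
        assert len(one) == 66
        assert (one["contrast"] == "within_site").sum() == 18
        assert (one["contrast"] == "between_site").sum() == 48

    def test_founder_distance_of_founder_is_zero(self, rarefied_cohort):
        rarefied, meta, _ = rarefied_cohort
        d = div.bray_curtis(rarefied)
        _, founders = div.dissimilarity_contrasts(d, meta)
        first = founders[founders["elapsed_occasions"] == 0]
        assert (first["distance_to_founder"] == 0).all()

    def test_extremes_for_planted_patient(self):
        # within-site identical, between-site disjoint
        counts = [[100, 0], [100, 0], [0, 100], [0, 100]]
        t = toy_table(counts, sample_ids=["g1", "g2", "o1", "o2"])
        meta = pd.DataFrame(
            {
                "sample_id": ["g1", "g2", "o1", "o2"],
                "patient_id": ["P1"] * 4,
                "body_site": ["gut", "gut", "oral", "oral"],
                "time_index": [1, 2, 1, 2],
            }
        )
        pairs, _ = div.dissimilarity_contrasts(div.bray_curtis(t), meta)
        within = pairs[pairs["contrast"] == "within_site"]["distance"]
        between = pairs[pairs["contrast"] == "between_site"]["distance"]
        assert (within == 0).all() and (between == 1).all()
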