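import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import preyview as pv
from preyview.multivariate import (
    DistanceMatrix,
    DistanceMatrixError,
    Permanova,
    dispersion_homogeneity,
    p_adjust,
    pairwise_permanova,
)


class TestDistanceMatrix:
    def test_rejects_asymmetry(self):
        d = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(DistanceMatrixError):
            DistanceMatrix(d)

    def test_rejects_nonzero_diagonal(self):
        d = np.array([[0.1, 1.0], [1.0, 0]])
        with pytest.raises(DistanceMatrixError):
            DistanceMatrix(d)

    def test_from_points_euclidean(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0]])
        dm = DistanceMatrix.from_points(pts)
        assert dm.values[0, 1] == pytest.approx(5.0)


class TestPermanova:
    def test_identical_points_everywhere_gives_null(self):
        d = np.zeros((8, 8))
        groups = ["a"] * 4 + ["b"] * 4
        res = Permanova(DistanceMatrix(d, groups=groups)).fit(99, seed=0)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_pseudo_f_equals_anova_f_univariate(self):
        # on univariate Euclidean data the pseudo-F is classical one-way ANOVA F
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 1, 8), rng.normal(1.2, 1, 10),
                            rng.normal(0.4, 1, 6)])
        groups = ["a"] * 8 + ["b"] * 10 + ["c"] * 6
        dm = DistanceMatrix.from_points(x[:, None], groups=groups)
        res = Permanova(dm).fit(9, seed=0)
        f_oracle = sps.f_oneway(x[:8], x[8:18], x[18:]).statistic
        assert res.statistic == pytest.approx(f_oracle, abs=1e-10)

    def test_matches_scikit_bio_statistic(self):
        # independent implementation cross-check on a multivariate example
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(15, 4))
        pts[8:] += 0.8
        groups = ["a"] * 8 + ["b"] * 7
        dm = DistanceMatrix.from_points(pts, groups=groups)
        res = Permanova(dm).fit(99, seed=1)
        sk = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(dm.values), grouping=groups, permutations=0
        )
        assert res.statistic == pytest.approx(sk["test statistic"], rel=1e-10)

    def test_r2_plus_unexplained_is_one(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        groups = ["a"] * 6 + ["b"] * 6
        dm = DistanceMatrix.from_points(pts, groups=groups)
        model = Permanova(dm)
        f, r2 = model._f_and_r2(model.groups)
        d2 = dm.values**2
        from preyview.multivariate import _permanova_ss

        ss_total, ss_within = _permanova_ss(d2, model.groups, model.levels)
        assert r2 + ss_within / ss_total == pytest.approx(1.0, abs=1e-12)

    def test_seed_determinism_and_p_resolution(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(14, 2))
        groups = ["a"] * 7 + ["b"] * 7
        dm = DistanceMatrix.from_points(pts, groups=groups)
        r1 = Permanova(dm).fit(199, seed=5)
        r2 = Permanova(dm).fit(199, seed=5)
        assert r1.pvalue == r2.pvalue
        assert (r1.pvalue * 200) == pytest.approx(round(r1.pvalue * 200))

    def test_single_group_rejected(self):
        d = np.zeros((4, 4))
        with pytest.raises(DistanceMatrixError):
            Permanova(DistanceMatrix(d, groups=["a"] * 4))

    def test_null_pvalues_uniform(self, null_permanova_pvalues):
        # Kolmogorov-Smirnov distance to U(0,1) under a simulated null
        ks = sps.kstest(null_permanova_pvalues, "uniform").statistic
        assert ks < 0.05

    def test_summary_mentions_key_quantities(self):
        rng = np.random.default_rng(0)
        dm = DistanceMatrix.from_points(
            rng.normal(size=(10, 2)), groups=["a"] * 5 + ["b"] * 5
        )
        text = Permanova(dm).fit(99, seed=0).summary()
        assert "pseudo-F" in text and "R^2" in text


class TestPairwisePermanova:
    def _three_group_dm(self, shift=0.0, seed=0, n=6):
        rng = np.random.default_rng(seed)
        pts = np.concatenate(
            [rng.normal(i * shift, 1, (n, 2)) for i in range(3)], axis=0
        )
        groups = np.repeat(["a", "b", "c"], n)
        return DistanceMatrix.from_points(pts, groups=groups)

    def test_two_groups_adjusted_equals_raw(self):
        rng = np.random.default_rng(1)
        dm = DistanceMatrix.from_points(
            rng.normal(size=(12, 2)), groups=["a"] * 6 + ["b"] * 6
        )
        out = pairwise_permanova(dm, n_permutations=99, seed=0)
        assert len(out) == 1
        assert out["p_adjusted"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_adjusted_at_least_raw(self):
        out = pairwise_permanova(self._three_group_dm(seed=2), n_permutations=99, seed=0)
        assert (out["p_adjusted"] >= out["p"] - 1e-12).all()

    def test_bonferroni_closed_form(self):
        p = np.linspace(0.001, 0.09, 10)
        adj = p_adjust(p, "bonferroni")
        assert np.allclose(adj, np.minimum(1.0, 10 * p))

    def test_small_pair_flagged_not_computed(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(9, 2))
        groups = ["a"] * 4 + ["b"] * 4 + ["c"]
        dm = DistanceMatrix.from_points(pts, groups=groups)
        out = pairwise_permanova(dm, n_permutations=49, seed=0)
        bad = out[(out["group_a"] == "a") & (out["group_b"] == "c")]
        assert not bad["computed"].iloc[0]
        assert np.isnan(bad["F"].iloc[0])

    def test_relabeling_permutes_rows_not_values(self):
        dm = self._three_group_dm(shift=1.0, seed=4)
        out1 = pairwise_permanova(dm, n_permutations=99, seed=7)
        relabel = {"a": "z", "b": "y", "c": "x"}
        dm2 = DistanceMatrix(
            dm.values, groups=[relabel[g] for g in dm.groups]
        )
        out2 = pairwise_permanova(dm2, n_permutations=99, seed=7)
        assert sorted(out1["F"].round(10)) == sorted(out2["F"].round(10))


class TestPAdjust:
    def test_holm_stepdown_closed_form(self):
        adj = p_adjust([0.01, 0.04], "holm")
        assert np.allclose(adj, [0.02, 0.04])

    def test_single_p_unchanged(self):
        for method in ("bonferroni", "holm", "bh"):
            assert p_adjust([0.03], method)[0] == pytest.approx(0.03)

    def test_bh_matches_definition_on_sorted_grid(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        m = p.size
        # textbook step-up: min over tail of p_(j) * m / j
        expected = np.array(
            [min((p[j] * m / (j + 1) for j in range(i, m))) for i in range(m)]
        )
        assert np.allclose(p_adjust(p, "bh"), np.minimum(expected, 1.0))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            p_adjust([0.5, 1.2], "holm")


class TestDispersionHomogeneity:
    def test_euclidean_embedding_matches_direct_geometry(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(16, 3))
        groups = np.array(["a"] * 8 + ["b"] * 8, dtype=object)
        dm = DistanceMatrix.from_points(pts, groups=groups)
        from preyview.multivariate import DispersionHomogeneity

        model = DispersionHomogeneity(dm)
        direct = np.empty(16)
        for g in ("a", "b"):
            mask = groups == g
            centroid = pts[mask].mean(axis=0)
            direct[mask] = np.linalg.norm(pts[mask] - centroid, axis=1)
        assert np.allclose(model.distances_to_centroid, direct, atol=1e-8)

    def test_equal_dispersion_calibration(self):
        # mirrored point sets: dispersion equal by construction
        rng = np.random.default_rng(10)
        keep = 0
        runs = 100
        for _ in range(runs):
            base = rng.normal(size=(20, 2))
            pts = np.concatenate([base, -base], axis=0)
            groups = ["a"] * 20 + ["b"] * 20
            dm = DistanceMatrix.from_points(pts, groups=groups)
            res = dispersion_homogeneity(dm, n_permutations=199, seed=rng)
            if res.pvalue > 0.05:
                keep += 1
        assert keep >= 0.9 * runs

    def test_detects_five_fold_dispersion_difference(self):
        rng = np.random.default_rng(11)
        hits = 0
        runs = 100
        for _ in range(runs):
            tight = rng.normal(0, 1, (20, 2))
            wide = rng.normal(0, 5, (20, 2))
            dm = DistanceMatrix.from_points(
                np.concatenate([tight, wide]), groups=["a"] * 20 + ["b"] * 20
            )
            res = dispersion_homogeneity(dm, n_permutations=199, seed=rng)
            if res.pvalue < 0.05:
                hits += 1
        assert hits >= 0.9 * runs

    def test_all_zero_distances_rejected(self):
        from preyview.multivariate import DispersionHomogeneity

        d = np.zeros((6, 6))
        with pytest.raises(DistanceMatrixError):
            DispersionHomogeneity(DistanceMatrix(d, groups=["a"] * 3 + ["b"] * 3))

    def test_pairwise_output_adjusted(self):
        rng = np.random.default_rng(12)
        pts = np.concatenate(
            [rng.normal(0, s, (8, 2)) for s in (1.0, 1.0, 4.0)], axis=0
        )
        dm = DistanceMatrix.from_points(pts, groups=np.repeat(["a", "b", "c"], 8))
        res = dispersion_homogeneity(dm, n_permutations=199, seed=1)
        assert len(res.pairwise) == 3
        assert (res.pairwise["p_adjusted"] >= res.pairwise["p"] - 1e-12).all()
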