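"""Normalizations, ROUT, group tests, exact Spearman, ddCt, stage correlation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from fibromech import stats as fs
from fibromech import synth


class TestNormalizations:
    def test_median_center_example(self):
        np.testing.assert_allclose(fs.median_center([2.0, 4.0, 8.0]), [0.5, 1.0, 2.0])

    def test_median_center_defining_property(self, rng):
        v = rng.lognormal(0, 1, 101)
        assert np.median(fs.median_center(v)) == pytest.approx(1.0)
        assert np.median(fs.median_center(v, mode="subtract")) == pytest.approx(0.0)

    def test_median_center_scale_invariance(self, rng):
        v = rng.lognormal(0, 0.5, 50)
        np.testing.assert_allclose(fs.median_center(v), fs.median_center(7.3 * v))

    def test_median_center_zero_median_fails(self):
        with pytest.raises(ValueError):
            fs.median_center([-1.0, 0.0, 1.0])

    def test_zscore_self_reference(self, rng):
        v = rng.normal(5, 2, 500)
        z = fs.zscore(v, v.mean(), v.std())
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_control_normalized_control_mean_one(self, rng):
        v = rng.lognormal(1, 0.2, 64)
        assert fs.normalize_to_control(v, v.mean()).mean() == pytest.approx(1.0)

    def test_normalizations_invertible(self, rng):
        v = rng.lognormal(0, 0.4, 32)
        med = np.median(v)
        np.testing.assert_allclose(fs.median_center(v) * med, v, rtol=1e-12)
        z = fs.zscore(v, 2.0, 3.0)
        np.testing.assert_allclose(z * 3.0 + 2.0, v, rtol=1e-12)

    def test_degenerate_references_fail(self):
        with pytest.raises(ValueError):
            fs.normalize_to_control([1.0], 0.0)
        with pytest.raises(ValueError):
            fs.zscore([1.0], 0.0, 0.0)

    def test_zscore_aligns_fibrotic_stages_across_species(self):
        """After z-scoring, a chronic-stage murine sample is closer (smaller
        Kolmogorov distance) to a human-fibrotic-like sample than a
        transition-stage one, under generator settings encoding that ordering."""
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(0)
        human_fibrotic = synth.TissueMechanicsModel(2.5, 0.2, 35.0, 0.22, 0.45)
        h = np.log10(human_fibrotic.sample_moduli(4000, rng))
        d21 = np.log10(synth.STAGE_MECHANICS["chronic_d21"].sample_moduli(4000, rng))
        d14 = np.log10(synth.STAGE_MECHANICS["transition_d14"].sample_moduli(4000, rng))
        zh = fs.zscore(h, h.mean(), h.std())
        z21 = fs.zscore(d21, d21.mean(), d21.std())
        z14 = fs.zscore(d14, d14.mean(), d14.std())
        assert ks_2samp(z21, zh).statistic < ks_2samp(z14, zh).statistic


class TestRout:
    def test_gross_outlier_flagged(self):
        v = np.r_[np.zeros(19), 100.0]
        res = fs.rout_outliers(v, q=0.01)
        assert list(res.outlier_indices) == [19]

    def test_small_n_skipped_with_warning(self):
        res = fs.rout_outliers(np.arange(5, dtype=float))
        assert res.n_outliers == 0
        assert res.warning is not None

    def test_null_calibration(self):
        """False-flag fraction on clean normal data <= 2% at Q=1% (30 seeds)."""
        fracs = [
            fs.rout_outliers(np.random.default_rng(s).standard_normal(500)).n_outliers / 500
            for s in range(30)
        ]
        assert np.mean(fracs) <= 0.02

    def test_affine_invariance(self, rng):
        """Flag set unchanged under affine transforms of the data."""
        v = rng.standard_normal(200)
        v[:3] += 8.0
        base = fs.rout_outliers(v)
        for a, b in ((3.5, -2.0), (-0.7, 10.0)):
            res = fs.rout_outliers(a * v + b)
            np.testing.assert_array_equal(res.outlier_indices, base.outlier_indices)

    def test_contaminated_sample_cleaned(self, rng):
        v = np.r_[rng.standard_normal(200), [15.0, -12.0, 20.0]]
        res = fs.rout_outliers(v)
        assert set(res.outlier_indices) >= {200, 201, 202}


class TestGroupTests:
    def test_identical_groups_not_significant(self, rng):
        v = rng.normal(0, 1, 30)
        rep = fs.group_tests({"a": v, "b": v.copy()})
        assert rep.iloc[0]["p"] > 0.9
        assert rep.iloc[0]["stars"] == "ns"

    def test_large_shift_max_stars(self):
        """3-sd shift at n=30/group reaches **** in >=95% of seeds."""
        hits = 0
        for s in range(40):
            rng = np.random.default_rng(s)
            a = rng.normal(0, 1, 30)
            b = rng.normal(3, 1, 30)
            rep = fs.group_tests({"a": a, "b": b})
            hits += rep.iloc[0]["stars"] == "****"
        assert hits >= 38

    @pytest.mark.parametrize("p, stars", [
        (0.04, "*"), (0.004, "**"), (0.0004, "***"), (0.00004, "****"),
        (0.2, "ns"), (0.05, "ns"),
    ])
    def test_star_mapping(self, p, stars):
        assert fs.significance_stars(p) == stars

    def test_small_group_skipped_with_reason(self, rng):
        rep = fs.group_tests({"a": rng.normal(0, 1, 20), "b": np.array([1.0, 2.0])})
        skipped = rep[rep["stars"] == "skipped"]
        assert len(skipped) == 1
        assert "n < 3" in skipped.iloc[0]["method"]

    def test_multigroup_nonparametric_runs_dunn(self, rng):
        groups = {
            "a": rng.lognormal(0, 0.5, 25),
            "b": rng.lognormal(0.8, 0.5, 25),
            "c": rng.lognormal(1.6, 0.5, 25),
        }
        rep = fs.group_tests(groups, parametric=False)
        assert rep.iloc[0]["method"] == "kruskal-wallis"
        assert sum(rep["method"].str.startswith("dunn")) == 3

    def test_multigroup_parametric_bonferroni(self, rng):
        groups = {k: rng.normal(m, 1, 20) for k, m in
                  zip("abc", (0.0, 0.1, 3.0))}
        rep = fs.group_tests(groups, parametric=True)
        assert rep.iloc[0]["method"] == "one-way anova"
        pairwise = rep[rep["method"] == "t-test (bonferroni)"]
        assert len(pairwise) == 3
        assert (pairwise["p"] <= 1.0).all()


def _brute_force_spearman_p(rx, ry):
    """Independent enumeration oracle for the exact two-sided p."""
    n = len(rx)
    d2_obs = sum((a - b) ** 2 for a, b in zip(rx, ry))
    mean_d2 = n * (n**2 - 1) / 6
    count = 0
    for perm in itertools.permutations(range(1, n + 1)):
        d2 = sum((a - b) ** 2 for a, b in zip(rx, perm))
        if (d2 <= d2_obs) if d2_obs <= mean_d2 else (d2 >= d2_obs):
            count += 1
    return min(1.0, 2 * count / math.factorial(n))


class TestSpearmanExact:
    def test_printed_worked_example(self):
        """n=6 ranks with two disjoint adjacent swaps: rho=0.886, p=0.0333."""
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 3, 5, 4, 6]
        res = fs.spearman_exact(x, y)
        assert res.method == "exact-permutation"
        assert round(res.rho, 3) == 0.886
        assert round(res.p_two_sided, 4) == 0.0333

    def test_perfect_concordance(self):
        res = fs.spearman_exact([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert res.rho == 1.0
        assert res.p_two_sided == pytest.approx(2 / math.factorial(5))

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            x = rng.permutation(n) + 1.0
            y = rng.permutation(n) + 1.0
            res = fs.spearman_exact(x, y)
            expected = _brute_force_spearman_p(
                list(map(int, x)), list(map(int, y)))
            assert res.p_two_sided == pytest.approx(expected, abs=1e-12)

    def test_symmetries(self, rng):
        x = rng.permutation(8) + 1.0
        y = rng.permutation(8) + 1.0
        a = fs.spearman_exact(x, y)
        b = fs.spearman_exact(y, x)
        c = fs.spearman_exact(x, -y)
        assert a.rho == pytest.approx(b.rho)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)
        assert c.rho == pytest.approx(-a.rho)

    def test_ties_fall_back_to_asymptotic(self):
        res = fs.spearman_exact([1, 2, 2, 3, 4], [5, 6, 7, 8, 9])
        assert res.method == "asymptotic"
        assert "ties" in res.note

    def test_constant_input_flagged(self):
        res = fs.spearman_exact([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.method == "undefined"
        assert math.isnan(res.rho)

    def test_scipy_rho_agreement(self, rng):
        """rho matches the established midrank implementation on tie-free data."""
        from scipy.stats import spearmanr

        x = rng.permutation(9) + 1.0
        y = rng.permutation(9) + 1.0
        assert fs.spearman_exact(x, y).rho == pytest.approx(spearmanr(x, y).statistic)


class TestDdct:
    @pytest.mark.parametrize("cts, fold", [
        ((25.0, 20.0, 25.0, 20.0), 1.0),   # ddCt = 0
        ((24.0, 20.0, 25.0, 20.0), 2.0),   # ddCt = -1
        ((25.0, 20.0, 28.0, 20.0), 8.0),   # ddCt = -3
    ])
    def test_fold_change(self, cts, fold):
        assert fs.ddct_fold_change(*cts) == pytest.approx(fold)

    def test_rejects_nonpositive_ct(self):
        with pytest.raises(ValueError):
            fs.ddct_fold_change(25.0, -1.0, 25.0, 20.0)


class TestStageCorrelation:
    @staticmethod
    def _cohort_table(seed, n_per_tp=6):
        design = synth.StudyDesign(
            groups=(
                synth.GroupSpec("inflammation_d3", n_per_tp, 3),
                synth.GroupSpec("chronic_d21", n_per_tp, 21),
            ),
            maps_per_specimen=2, grid_points=16, seed=seed,
        )
        cohort = synth.simulate_cohort(design, include_curves=False)
        rows = []
        for s in cohort.specimens:
            mean_e = float(np.mean([m.e_kpa.mean() for m in s.true_maps]))
            rows.append({
                "specimen_id": s.specimen_id,
                "timepoint_days": s.timepoint_days,
                "collagen_fraction": s.col1_fraction + s.col3_fraction,
                "mean_e_kpa": mean_e,
            })
        return pd.DataFrame(rows)

    def test_chronic_stage_strongly_correlated(self):
        """Collagen-stiffness rho >= 0.8 at d21 in >=90% of seeds (n=6)."""
        hits = 0
        for seed in range(20):
            tab = self._cohort_table(seed)
            res = fs.stage_correlation(tab)
            rho = res[res["timepoint_days"] == 21].iloc[0]["rho"]
            hits += rho >= 0.8
        assert hits >= 18

    def test_inflammation_stage_decoupled(self):
        """Median |rho| < 0.5 at d3 where collagen and stiffness are independent."""
        rhos = []
        for seed in range(20):
            tab = self._cohort_table(seed)
            res = fs.stage_correlation(tab)
            rhos.append(abs(res[res["timepoint_days"] == 3].iloc[0]["rho"]))
        assert np.median(rhos) < 0.5

    def test_small_and_constant_inputs_flagged(self):
        tab = pd.DataFrame({
            "specimen_id": list("abcdefg"),
            "timepoint_days": [3, 3, 3, 21, 21, 21, 21],
            "collagen_fraction": [0.1, 0.2, 0.3, 0.5, 0.5, 0.5, 0.5],
            "mean_e_kpa": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0],
        })
        res = fs.stage_correlation(tab)
        assert "skipped" in res[res["timepoint_days"] == 3].iloc[0]["method"]
        assert "undefined" in res[res["timepoint_days"] == 21].iloc[0]["method"]
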