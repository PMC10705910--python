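"""Correlation assignment, ANOVA/Bonferroni, and the statistical screens."""

import math

import numpy as np
import pytest
from scipy import stats

from conftest import brute_force_pearson, mix_to_correlation
from sdmet.chemometrics import (
    GroupSummary,
    anova_from_data,
    anova_from_summary,
    bonferroni_compare,
    cochran_c,
    intensity_ratio,
    ks_gof,
    pearson_match,
    probability_plot_stats,
    rank_candidates,
    shapiro_wilk,
)
from sdmet.datasets import (
    CARBOHYDRATE_ION_KEYS,
    INTENSITY_SUMMARY_CBA,
    INTENSITY_SUMMARY_CBB,
    MZ_SUMMARY_CBA,
    MZ_SUMMARY_CBB,
)
from sdmet.simulate import gen_group_data
from sdmet.spectra import IonKey, MassSpectrum, SpectrumLibrary, match_ions


# ---------------------------------------------------------------------------
# pearson_match
# ---------------------------------------------------------------------------

class TestPearsonMatch:
    def test_self_correlation_is_one(self, carb_table):
        res = pearson_match(carb_table, "CB_B", "CB_B")
        assert res.r == pytest.approx(1.0, abs=1e-14)

    def test_cb_b_vs_4dg_matches_hand_summation(self, carb_table):
        res = pearson_match(carb_table, "CB_B", "4DG")
        # pairwise-complete ions are 45, 73, 103, 147
        expected = brute_force_pearson(
            [2.717, 100.0, 15.838, 23.587], [8.397, 100.0, 8.058, 28.434]
        )
        assert res.n_ions == 4
        assert res.r == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        keys = [IonKey(int(m)) for m in np.sort(rng.choice(400, n, replace=False) + 40)]
        xa = rng.uniform(0, 100, n)
        xb = rng.uniform(0, 100, n)
        table_cols = {"a": xa, "b": xb}
        from sdmet.spectra import MatchedIonTable

        table = MatchedIonTable(ions=keys, columns=table_cols)
        res = pearson_match(table, "a", "b")
        assert res.r == pytest.approx(brute_force_pearson(xa, xb), abs=1e-12)

    def test_symmetric_and_affine_invariant(self, carb_table):
        ab = pearson_match(carb_table, "CB_B", "4DG")
        ba = pearson_match(carb_table, "4DG", "CB_B")
        assert ab.r == pytest.approx(ba.r, abs=1e-14)
        # positive affine rescaling of one column leaves r unchanged
        from sdmet.spectra import MatchedIonTable

        scaled = MatchedIonTable(
            ions=carb_table.ions,
            columns={
                "CB_B": carb_table.column("CB_B") * 3.7 + 11.0,
                "4DG": carb_table.column("4DG"),
            },
        )
        assert pearson_match(scaled, "CB_B", "4DG").r == pytest.approx(ab.r, abs=1e-12)

    def test_exclusion_drops_ions(self, carb_table):
        res = pearson_match(
            carb_table, "CB_A", "CB_B", exclude=(IonKey.parse("205/204"),)
        )
        assert res.n_ions == 4  # 45, 73, 103, 147 remain pairwise complete

    def test_too_few_ions_raises(self, carb_table):
        exclude = tuple(IonKey.parse(s) for s in ("45", "73"))
        with pytest.raises(ValueError, match="pairwise-complete"):
            pearson_match(carb_table, "CB_B", "4DG", exclude=exclude)

    def test_constant_column_named_in_error(self):
        from sdmet.spectra import MatchedIonTable

        table = MatchedIonTable(
            ions=[IonKey(45), IonKey(73), IonKey(103)],
            columns={"flat": np.array([5.0, 5.0, 5.0]), "v": np.array([1.0, 2.0, 3.0])},
        )
        with pytest.raises(ValueError, match="flat"):
            pearson_match(table, "flat", "v")


class TestRankCandidates:
    def test_query_in_library_ranks_first(self, carb_library):
        ranking = rank_candidates(
            carb_library["CB_B"], carb_library, CARBOHYDRATE_ION_KEYS
        )
        assert ranking.results[0].candidate_name == "CB_B"
        assert ranking.results[0].r == 1.0

    def test_ambiguity_flag_follows_top_gap(self, carb_library):
        lib = SpectrumLibrary(
            entries={n: carb_library[n] for n in ("4DG", "2DG")}
        )
        ranking = rank_candidates(carb_library["CB_B"], lib, CARBOHYDRATE_ION_KEYS)
        rs = sorted((abs(a.r) for a in ranking.results), reverse=True)
        assert ranking.top_gap == pytest.approx(rs[0] - rs[1], abs=1e-12)
        assert ranking.ambiguous == (ranking.top_gap < ranking.ambiguity_gap)

    @pytest.mark.parametrize("r1,r2", [(0.99, 0.60), (0.95, 0.93), (0.90, 0.86)])
    def test_flag_exact_on_planted_correlations(self, r1, r2):
        """Candidates built with exact planted |r| to the query flag
        ambiguity iff the gap is below the threshold."""
        rng = np.random.default_rng(42)
        n = 12
        mz = np.sort(rng.choice(np.arange(45, 400), n, replace=False))
        x = rng.uniform(10, 90, n)

        def as_spec(name, u):
            v = 55 + 40 * (u - u.mean()) / np.abs(u - u.mean()).max()
            return MassSpectrum(
                name, tuple((int(m), float(i)) for m, i in zip(mz, v))
            ).normalized()

        query = as_spec("query", x)
        cands = {}
        for name, r in (("c1", r1), ("c2", r2)):
            y = mix_to_correlation(x, rng.standard_normal(n), r)
            cands[name] = as_spec(name, y)
        lib = SpectrumLibrary(entries=cands)
        keys = tuple(IonKey(int(m)) for m in mz)
        ranking = rank_candidates(query, lib, keys)
        assert ranking.top_gap == pytest.approx(r1 - r2, abs=1e-9)
        assert ranking.ambiguous == ((r1 - r2) < 0.05)

    def test_incomparable_candidate_kept(self, carb_library):
        sparse = MassSpectrum("sparse", peaks=((73, 100.0), (147, 20.0)))
        lib = SpectrumLibrary(
            entries={"4DG": carb_library["4DG"], "sparse": sparse}
        )
        ranking = rank_candidates(carb_library["CB_B"], lib, CARBOHYDRATE_ION_KEYS)
        by_name = {a.candidate_name: a for a in ranking.results}
        assert not by_name["sparse"].comparable
        assert math.isnan(by_name["sparse"].r)

    def test_empty_library_raises(self, carb_library):
        with pytest.raises(ValueError, match="empty"):
            rank_candidates(
                carb_library["CB_B"],
                SpectrumLibrary(entries={}),
                CARBOHYDRATE_ION_KEYS,
            )


# ---------------------------------------------------------------------------
# ANOVA / Bonferroni
# ---------------------------------------------------------------------------

class TestAnova:
    def test_reproduces_published_intensity_block(self):
        res = anova_from_summary(INTENSITY_SUMMARY_CBA, INTENSITY_SUMMARY_CBB)
        assert res.ss_model == pytest.approx(109.373548, rel=1e-3)
        assert res.ms_error == pytest.approx(715.930471, rel=1e-3)
        assert res.f_value == pytest.approx(0.15277, rel=1e-3)
        assert res.p_value == pytest.approx(0.69935, abs=1e-4)
        assert not res.verdict

    def test_reproduces_published_mz_block(self):
        res = anova_from_summary(MZ_SUMMARY_CBA, MZ_SUMMARY_CBB)
        assert res.f_value == pytest.approx(0.08517, rel=1e-3)
        assert res.ss_error == pytest.approx(647569.350, rel=1e-3)
        assert res.p_value == pytest.approx(0.77291, abs=1e-4)

    def test_standard_error_identity(self):
        assert INTENSITY_SUMMARY_CBA.se == pytest.approx(9.55822, abs=1e-5)

    def test_equal_means_give_zero_f(self):
        g = GroupSummary(n=5, mean=3.0, sd=1.0)
        res = anova_from_summary(g, g)
        assert res.ss_model == pytest.approx(0.0, abs=1e-12)
        assert res.f_value == pytest.approx(0.0, abs=1e-12)

    def test_from_data_identical_to_summary(self):
        x1 = gen_group_data(INTENSITY_SUMMARY_CBA, seed=1)
        x2 = gen_group_data(INTENSITY_SUMMARY_CBB, seed=2)
        res_d = anova_from_data(x1, x2)
        res_s = anova_from_summary(INTENSITY_SUMMARY_CBA, INTENSITY_SUMMARY_CBB)
        assert res_d.f_value == pytest.approx(res_s.f_value, rel=1e-9)
        assert res_d.ss_error == pytest.approx(res_s.ss_error, rel=1e-9)

    def test_identical_vectors_f_zero(self):
        res = anova_from_data([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.f_value == 0.0

    def test_zero_error_ss_documented_degenerate(self):
        res = anova_from_data([0.0, 0.0], [1.0, 1.0])
        assert math.isinf(res.f_value)
        assert res.p_value == 0.0

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            anova_from_data([1.0], [1.0, 2.0])


class TestBonferroni:
    def test_reproduces_published_intensity_interval(self):
        res = anova_from_summary(INTENSITY_SUMMARY_CBA, INTENSITY_SUMMARY_CBB)
        bon = bonferroni_compare(
            INTENSITY_SUMMARY_CBA, INTENSITY_SUMMARY_CBB, res.ms_error, res.df_error
        )
        assert bon.mean_difference == pytest.approx(4.21583, abs=1e-4)
        assert bon.ci_lower == pytest.approx(-18.04547, abs=1e-4)
        assert bon.ci_upper == pytest.approx(26.47712, abs=1e-4)
        assert not bon.significant

    def test_reproduces_published_mz_interval(self):
        res = anova_from_summary(MZ_SUMMARY_CBA, MZ_SUMMARY_CBB)
        bon = bonferroni_compare(
            MZ_SUMMARY_CBA, MZ_SUMMARY_CBB, res.ms_error, res.df_error
        )
        assert bon.mean_difference == pytest.approx(19.325, abs=1e-3)
        assert bon.ci_lower == pytest.approx(-117.3385, abs=1e-3)
        assert bon.ci_upper == pytest.approx(155.9885, abs=1e-3)

    def test_identical_groups_symmetric_not_significant(self):
        g = GroupSummary(n=6, mean=10.0, sd=2.0)
        res = anova_from_summary(g, g)
        bon = bonferroni_compare(g, g, res.ms_error, res.df_error)
        assert bon.mean_difference == 0.0
        assert bon.ci_lower == pytest.approx(-bon.ci_upper)
        assert not bon.significant

    @pytest.mark.parametrize("seed", range(5))
    def test_verdict_equivalent_to_f_test(self, seed):
        """Two-group case: interval excludes 0 iff ANOVA p <= alpha (F = t^2)."""
        rng = np.random.default_rng(seed)
        g1 = GroupSummary(
            n=int(rng.integers(3, 15)),
            mean=float(rng.normal(10, 5)),
            sd=float(rng.uniform(0.5, 5)),
        )
        g2 = GroupSummary(
            n=int(rng.integers(3, 15)),
            mean=float(rng.normal(10, 5)),
            sd=float(rng.uniform(0.5, 5)),
        )
        res = anova_from_summary(g1, g2)
        bon = bonferroni_compare(g1, g2, res.ms_error, res.df_error)
        assert bon.significant == res.verdict

    def test_invalid_inputs(self):
        g = GroupSummary(n=5, mean=1.0, sd=1.0)
        with pytest.raises(ValueError):
            bonferroni_compare(g, g, ms_error=0.0, df_error=8)
        with pytest.raises(ValueError):
            bonferroni_compare(g, g, ms_error=1.0, df_error=0)


# ---------------------------------------------------------------------------
# Normality / homogeneity / goodness of fit
# ---------------------------------------------------------------------------

class TestShapiroWilk:
    def test_symmetric_equispaced_n3_gives_w_one(self):
        w, _ = shapiro_wilk([-1.0, 0.0, 1.0])
        assert w == pytest.approx(1.0, abs=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            shapiro_wilk([2.0, 2.0, 2.0, 2.0])

    def test_sample_size_limits(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])

    def test_matches_independent_reference_on_lognormal(self):
        # Frozen oracle: shapiro.test() in R 4.3.3 on this exact sample
        # gives W = 0.8636935407, p = 3.71211e-05.
        rng = np.random.default_rng(20260925)
        x = np.exp(rng.normal(0.0, 0.5, 50))
        w, p = shapiro_wilk(x)
        assert w == pytest.approx(0.8636935407, abs=1e-4)
        assert p == pytest.approx(3.71211e-05, rel=1e-2)

    def test_w_never_exceeds_one(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            w, _ = shapiro_wilk(rng.normal(size=25))
            assert w <= 1.0


class TestProbabilityPlot:
    def test_exact_normal_quantiles_plot_straight(self):
        q = np.array(
            [float(v) for v in stats.norm.ppf((np.arange(1, 41) - 0.375) / 40.25)]
        )
        r_plot, outliers = probability_plot_stats(q)
        assert r_plot >= 0.9999
        assert outliers.size == 0

    def test_three_symmetric_points_are_collinear(self):
        r_plot, _ = probability_plot_stats([1.0, 2.0, 3.0])
        assert r_plot == pytest.approx(1.0, abs=1e-12)

    def test_heavy_tails_reduce_linearity(self):
        rng = np.random.default_rng(7)
        n = 200
        r_normal, _ = probability_plot_stats(rng.normal(size=n))
        r_cauchy, _ = probability_plot_stats(rng.standard_cauchy(size=n))
        assert r_cauchy < r_normal

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            probability_plot_stats([1.0, 1.0, 1.0])


class TestCochranC:
    def test_two_group_arithmetic(self):
        sds = [INTENSITY_SUMMARY_CBA, INTENSITY_SUMMARY_CBB]
        c, _ = cochran_c(sds)
        v1, v2 = 30.22574**2, 24.44037**2
        assert c == pytest.approx(max(v1, v2) / (v1 + v2), abs=1e-12)

    def test_equal_variances_give_one_over_k(self):
        groups = [GroupSummary(n=5, mean=0.0, sd=2.0) for _ in range(4)]
        c, significant = cochran_c(groups)
        assert c == pytest.approx(0.25)
        assert not significant

    def test_single_nonzero_variance_gives_one(self):
        groups = [GroupSummary(n=5, mean=0.0, sd=0.0) for _ in range(3)]
        groups.append(GroupSummary(n=5, mean=0.0, sd=1.0))
        c, significant = cochran_c(groups)
        assert c == 1.0
        assert significant

    def test_all_zero_variances_rejected(self):
        groups = [GroupSummary(n=5, mean=0.0, sd=0.0) for _ in range(3)]
        with pytest.raises(ValueError):
            cochran_c(groups)


class TestKsGof:
    def test_quantile_sample_forces_half_over_n(self):
        n = 20
        x = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        d, _ = ks_gof(x, ("norm", 0.0, 1.0))
        assert d == pytest.approx(0.5 / n, abs=1e-12)

    def test_single_midpoint_vs_uniform(self):
        d, _ = ks_gof([0.5], ("uniform", 0.0, 1.0))
        assert d == pytest.approx(0.5)

    def test_matches_direct_sup_computation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        d, _ = ks_gof(x, ("norm", 0.0, 1.0))
        xs = np.sort(x)
        cdf = stats.norm.cdf(xs)
        n = xs.size
        d_brute = max(
            np.max(np.arange(1, n + 1) / n - cdf),
            np.max(cdf - np.arange(0, n) / n),
        )
        assert d == pytest.approx(d_brute, abs=1e-12)

    def test_unspecified_distribution_rejected(self):
        with pytest.raises(ValueError, match="fully specified"):
            ks_gof([0.1, 0.2], ("norm",))


class TestIntensityRatio:
    def test_ratio_arithmetic(self):
        spec = MassSpectrum("ca", peaks=((179, 1.0), (191, 46.76)))
        assert intensity_ratio(spec, IonKey(191), IonKey(179)) == pytest.approx(46.76)

    def test_same_ion_gives_one(self):
        spec = MassSpectrum("ca", peaks=((191, 46.76),))
        assert intensity_ratio(spec, IonKey(191), IonKey(191)) == 1.0

    def test_planted_isomer_ratio_recovered(self):
        # 3-trans-caffeoylquinic-acid-like planted ratio
        ratio = 18.59
        spec = MassSpectrum(
            "ca_synthetic", peaks=((179, 100.0 / ratio), (191, 100.0))
        ).normalized()
        assert intensity_ratio(spec, IonKey(191), IonKey(179)) == pytest.approx(
            ratio, rel=1e-12
        )

    def test_missing_ion_and_zero_denominator(self):
        spec = MassSpectrum("s", peaks=((179, 0.0), (191, 10.0)))
        with pytest.raises(ValueError, match="no peak"):
            intensity_ratio(spec, IonKey(200), IonKey(179))
        with pytest.raises(ValueError, match="zero"):
            intensity_ratio(spec, IonKey(191), IonKey(179))
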