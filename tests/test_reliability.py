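"""Reliability statistics against brute-force oracles and worked examples."""

import math

import numpy as np
import pandas as pd
import pytest

from cordti.phantom import CohortSpec, PhantomSpec, simulate_cohort_truths
from cordti.reliability import (
    PairedSample,
    ReliabilityModel,
    anova_mean_squares,
    bland_altman,
    build_table,
    classify_icc,
    cohens_d,
    icc,
    mean_ci,
    paired_ttest,
    round_half_away,
    simulate_paired,
    spearman_brown,
    within_cv,
)

# ---------------------------------------------------------------------------
# brute-force reference implementations (plain loops, no shared code paths)
# ---------------------------------------------------------------------------


def bf_mean(xs):
    return sum(xs) / len(xs)


def bf_sd(xs):
    m = bf_mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def bf_paired_t(x1, x2):
    d = [a - b for a, b in zip(x1, x2)]
    return bf_mean(d) / (bf_sd(d) / math.sqrt(len(d)))


def bf_anova_ms(y):
    n, k = len(y), len(y[0])
    gm = bf_mean([v for row in y for v in row])
    rm = [bf_mean(row) for row in y]
    cm = [bf_mean([y[i][j] for i in range(n)]) for j in range(k)]
    ssr = k * sum((m - gm) ** 2 for m in rm)
    ssc = n * sum((m - gm) ** 2 for m in cm)
    sse = sum(
        (y[i][j] - rm[i] - cm[j] + gm) ** 2 for i in range(n) for j in range(k)
    )
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def bf_cv(x1, x2):
    cvs = []
    for a, b in zip(x1, x2):
        pair_sd = bf_sd([a, b])
        cvs.append(pair_sd / bf_mean([a, b]) * 100.0)
    return bf_mean(cvs)


@pytest.fixture()
def random_pairs(rng):
    x1 = rng.normal(0.58, 0.03, 16)
    x2 = x1 * 0.95 + rng.normal(0.03, 0.02, 16)
    return PairedSample(x1=x1, x2=x2)


class TestPairedT:
    def test_identical_pairs(self):
        s = PairedSample(x1=np.arange(1.0, 9.0), x2=np.arange(1.0, 9.0))
        t, df, p = paired_ttest(s)
        assert (t, df, p) == (0.0, 7, 1.0)

    def test_unit_t_by_construction(self):
        # differences with mean = sd/sqrt(n) give t = 1 exactly
        d = np.array([1.0, -1.0, 1.0, -1.0, 0.5, -0.5, 1.0, -1.0])
        shift = d.std(ddof=1) / np.sqrt(d.size) - d.mean()
        s = PairedSample(x1=d + shift, x2=np.zeros_like(d))
        t, _, _ = paired_ttest(s)
        assert t == pytest.approx(1.0, abs=1e-10)

    def test_matches_brute_force(self, random_pairs):
        t, df, p = paired_ttest(random_pairs)
        t_bf = bf_paired_t(list(random_pairs.x1), list(random_pairs.x2))
        assert t == pytest.approx(t_bf, abs=1e-10)
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(abs(t_bf), 15), abs=1e-12)


class TestCohensD:
    @pytest.mark.parametrize(
        "d_val,band",
        [(0.05, "negligible"), (0.3, "small"), (0.5, "medium"),
         (0.79, "medium"), (0.8, "large"), (-0.5, "medium")],
    )
    def test_bands(self, rng, d_val, band):
        # build a sample whose paired d equals d_val exactly
        base = rng.normal(0, 1, 16)
        base = (base - base.mean()) / base.std(ddof=1)
        diff = base + d_val
        s = PairedSample(x1=diff, x2=np.zeros(16))
        got, got_band = cohens_d(s)
        assert got == pytest.approx(d_val, abs=1e-12)
        assert got_band == band

    def test_degenerate_cases(self):
        s = PairedSample(x1=np.ones(5), x2=np.ones(5))
        assert cohens_d(s) == (0.0, "negligible")
        s = PairedSample(x1=np.ones(5) * 2, x2=np.ones(5))
        val, band = cohens_d(s)
        assert np.isnan(val) and band == "undefined"


class TestMeanCI:
    def test_published_cell_dc_fa(self, rng):
        # a sample with mean 0.603, sd 0.023, n=16 must reproduce the
        # printed interval (0.591, 0.615) at 3 decimals
        x = rng.normal(0, 1, 16)
        x = (x - x.mean()) / x.std(ddof=1) * 0.023 + 0.603
        m, sd, (lo, hi) = mean_ci(x)
        assert round_half_away(lo) == 0.591
        assert round_half_away(hi) == 0.615

    def test_zero_sd_collapses(self):
        m, sd, (lo, hi) = mean_ci(np.full(10, 1.5))
        assert lo == hi == 1.5

    def test_width_scales_inverse_sqrt_n(self, rng):
        x = rng.normal(0, 1.0, 400)
        _, _, (lo1, hi1) = mean_ci(x[:100])
        _, _, (lo2, hi2) = mean_ci(x)
        # 4x the sample -> about half the width (t quantile nearly equal)
        assert (hi2 - lo2) == pytest.approx((hi1 - lo1) / 2.0, rel=0.25)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            mean_ci(np.array([1.0]))


class TestBlandAltman:
    @pytest.mark.parametrize(
        "D,sd,lo,hi",
        [(-0.003, 0.023, -0.048, 0.042),  # published FA PT cell
         (0.005, 0.074, -0.140, 0.150),   # published RD PT cell
         (0.010, 0.058, -0.104, 0.124)],  # published RD DC cell
    )
    def test_published_loa_cells(self, rng, D, sd, lo, hi):
        d = rng.normal(0, 1, 16)
        d = (d - d.mean()) / d.std(ddof=1) * sd + D
        s = PairedSample(x1=d, x2=np.zeros(16))
        ba = bland_altman(s)
        assert round_half_away(ba.loa[0]) == lo
        assert round_half_away(ba.loa[1]) == hi
        assert ba.loa[0] <= ba.mean_diff <= ba.loa[1]
        assert ba.ci[0] <= ba.mean_diff <= ba.ci[1]
        # CI of D is narrower than the LOA for n > 3
        assert ba.ci[1] - ba.ci[0] < ba.loa[1] - ba.loa[0]

    def test_identical_pairs(self):
        s = PairedSample(x1=np.arange(5.0), x2=np.arange(5.0))
        ba = bland_altman(s)
        assert ba.mean_diff == 0 and ba.loa == (0, 0) and ba.n_outside == 0

    def test_matches_brute_force(self, random_pairs):
        ba = bland_altman(random_pairs)
        d = list(random_pairs.diff)
        assert ba.mean_diff == pytest.approx(bf_mean(d), abs=1e-12)
        assert ba.sd_diff == pytest.approx(bf_sd(d), abs=1e-12)
        assert ba.loa[0] == pytest.approx(bf_mean(d) - 1.96 * bf_sd(d), abs=1e-10)


class TestWithinCV:
    def test_identical_pairs_zero(self):
        s = PairedSample(x1=np.full(6, 3.0), x2=np.full(6, 3.0))
        assert within_cv(s).cv == 0.0

    def test_boundary_ten_percent_is_acceptable(self):
        # invert the formula: pair (x1, x2) around mean 10 with CV_i = 10%
        m, cv = 10.0, 0.10
        d = cv * m * math.sqrt(2.0)
        s = PairedSample(
            x1=np.full(4, m + d / 2.0), x2=np.full(4, m - d / 2.0)
        )
        res = within_cv(s)
        assert res.cv == pytest.approx(10.0, abs=1e-9)
        assert res.band == "acceptable"

    def test_matches_brute_force_two_value_sd(self, random_pairs):
        res = within_cv(random_pairs)
        assert res.cv == pytest.approx(
            bf_cv(list(random_pairs.x1), list(random_pairs.x2)), abs=1e-10
        )

    def test_rms_aggregation_and_bands(self, random_pairs):
        res = within_cv(random_pairs, aggregation="rms")
        assert res.cv >= within_cv(random_pairs).cv  # RMS >= mean
        from cordti.reliability import cv_band

        assert cv_band(15.0) == "moderate" and cv_band(25.0) == "high"

    def test_non_positive_mean_excluded_with_warning(self):
        s = PairedSample(x1=np.array([1.0, -2.0, 1.0]), x2=np.array([1.2, 0.5, 0.9]))
        with pytest.warns(UserWarning, match="excluded"):
            res = within_cv(s)
        assert res.n_excluded == 1


class TestICC:
    def test_identical_pairs_consistency_one(self):
        s = PairedSample(x1=np.arange(1.0, 9.0), x2=np.arange(1.0, 9.0))
        assert icc(s, "consistency").single == pytest.approx(1.0)

    def test_constant_offset_contrast(self):
        s = PairedSample(x1=np.arange(1.0, 9.0), x2=np.arange(1.0, 9.0) + 0.5)
        cons = icc(s, "consistency")
        absr = icc(s, "absolute")
        assert cons.single == pytest.approx(1.0)
        assert absr.single < 1.0

    def test_consistency_at_least_absolute_with_offset(self, rng):
        x1 = rng.normal(0.6, 0.05, 16)
        s = PairedSample(x1=x1, x2=x1 + 0.03 + rng.normal(0, 0.01, 16))
        assert icc(s, "consistency").single >= icc(s, "absolute").single

    def test_mean_squares_match_brute_force(self, random_pairs):
        msr, msc, mse = anova_mean_squares(
            np.column_stack([random_pairs.x1, random_pairs.x2])
        )
        y = [[a, b] for a, b in zip(random_pairs.x1, random_pairs.x2)]
        bf = bf_anova_ms(y)
        assert msr == pytest.approx(bf[0], abs=1e-10)
        assert msc == pytest.approx(bf[1], abs=1e-10)
        assert mse == pytest.approx(bf[2], abs=1e-10)

    def test_forms_match_brute_force_formulas(self, random_pairs):
        y = [[a, b] for a, b in zip(random_pairs.x1, random_pairs.x2)]
        msr, msc, mse = bf_anova_ms(y)
        n, k = 16, 2
        cons = (msr - mse) / (msr + (k - 1) * mse)
        absr = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc(random_pairs, "consistency").single == pytest.approx(cons, abs=1e-10)
        assert icc(random_pairs, "absolute").single == pytest.approx(absr, abs=1e-10)

    def test_average_is_spearman_brown_of_single(self, random_pairs):
        for model in ("consistency", "absolute"):
            r = icc(random_pairs, model)
            assert r.average == pytest.approx(spearman_brown(r.single), abs=1e-12)
            assert r.average >= r.single > 0
            assert r.average_ci[0] == pytest.approx(
                spearman_brown(r.single_ci[0]), abs=1e-12
            )

    def test_matches_pingouin(self, random_pairs):
        pg = pytest.importorskip("pingouin")
        df = pd.DataFrame(
            {
                "targets": np.r_[np.arange(16), np.arange(16)],
                "raters": ["a"] * 16 + ["b"] * 16,
                "scores": np.r_[random_pairs.x1, random_pairs.x2],
            }
        )
        ref = pg.intraclass_corr(df, "targets", "raters", "scores").set_index("Type")
        for model, t1, tk in [
            ("consistency", "ICC(C,1)", "ICC(C,k)"),
            ("absolute", "ICC(A,1)", "ICC(A,k)"),
        ]:
            mine = icc(random_pairs, model)
            assert mine.single == pytest.approx(ref.loc[t1, "ICC"], abs=1e-10)
            assert mine.average == pytest.approx(ref.loc[tk, "ICC"], abs=1e-10)
            # pingouin prints its CI at 2 decimals
            assert mine.single_ci[0] == pytest.approx(
                ref.loc[t1, "CI95"][0], abs=0.006
            )
            assert mine.single_ci[1] == pytest.approx(
                ref.loc[t1, "CI95"][1], abs=0.006
            )

    def test_parameter_recovery(self, rng):
        ests = [
            icc(simulate_paired(200, 0.9, rng=rng), "absolute").single
            for _ in range(40)
        ]
        assert np.median(ests) == pytest.approx(0.9, abs=0.05)

    def test_zero_between_participant_variance_reported_as_computed(self, rng):
        s = PairedSample(x1=rng.normal(0, 1, 12), x2=rng.normal(0, 1, 12))
        r = icc(s, "absolute")
        assert r.single <= 1.0 and np.isfinite(r.single_ci).all()


class TestClassifyICC:
    @pytest.mark.parametrize(
        "value,cic,koo",
        [(0.65, "good", "moderate"), (0.95, "excellent", "excellent"),
         (0.10, "poor", "poor"), (0.45, "moderate", "poor"),
         (0.80, "excellent", "good")],
    )
    def test_bands(self, value, cic, koo):
        assert classify_icc(value) == (cic, koo)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_icc(1.5)


@pytest.fixture(scope="module")
def tidy():
    cohort = CohortSpec(n_participants=16, seed=21)
    return simulate_cohort_truths(cohort, PhantomSpec())


class TestBuildTable:

    def test_row_count_and_layout(self, tidy):
        table = build_table(tidy)
        # 3 comparisons (2 per-scanner + inter-scanner) x 4 metrics x 3 regions
        assert len(table) == 36
        assert set(table.comparison) == {"skyra", "prisma", "prisma_vs_skyra"}
        assert (table.groupby("comparison").size() == 12).all()

    def test_pooled_mean_identity(self, tidy):
        table = build_table(tidy)
        assert np.allclose(
            table.pooled_mean, (table.test_mean + table.retest_mean) / 2.0, atol=1e-12
        )

    def test_bonferroni_correction(self, tidy):
        table = build_table(tidy, correction="bonferroni")
        assert np.allclose(
            table.p_corrected, np.minimum(table.p * 12, 1.0), atol=1e-12
        )
        raw = build_table(tidy, correction="none")
        assert np.allclose(raw.p_corrected, raw.p)

    def test_no_true_effects_gives_construction_icc(self):
        # no scanner offsets, known variance ratio: ICC(ad) = 0.04^2/(0.04^2+0.02^2)
        cohort = CohortSpec(n_participants=200, seed=4)
        tidy = simulate_cohort_truths(cohort, PhantomSpec())
        table = build_table(tidy, icc_model="consistency")
        row = table[
            (table.comparison == "skyra") & (table.metric == "ad") & (table.region == "PT")
        ].iloc[0]
        assert row.icc_single == pytest.approx(0.8, abs=0.07)

    def test_model_results_round_trip(self, tidy):
        res = ReliabilityModel.from_dataframe(tidy).fit()
        assert res.table.equals(build_table(tidy))
        rep = res.report_table()
        assert (rep.test_mean == round_half_away(res.table.test_mean.to_numpy())).all()
        text = res.summary()
        assert "icc_single" in text and "skyra" in text

    def test_single_session_skipped_with_warning(self, tidy):
        solo = tidy[(tidy.session == 1) & (tidy.scanner == "skyra")]
        with pytest.warns(UserWarning, match="fewer than 2 sessions"):
            table = build_table(solo)
        assert len(table) == 0

    def test_incomplete_pairs_skipped_with_warning(self, tidy):
        broken = tidy[
            ~(
                (tidy.participant <= 15)
                & (tidy.scanner == "skyra")
                & (tidy.session == 2)
            )
        ]
        with pytest.warns(UserWarning, match="incomplete pairs"):
            table = build_table(broken)
        assert (table[table.comparison == "skyra"].n == 1).sum() == 0


class TestRounding:
    def test_half_away_from_zero(self):
        assert round_half_away(0.0005) == 0.001
        assert round_half_away(-0.0005) == -0.001
        assert round_half_away(0.0004) == 0.0
        assert list(round_half_away(np.array([1.2345, -1.2345]))) == [1.235, -1.235]
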