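"""Test-retest and inter-scanner reliability statistics.

Implements the full battery used in DTI reproducibility studies on paired
designs (n participants, k = 2 conditions):

* paired t-test and Cohen's d (paired definition, d = mean(diff)/SD(diff))
  with the conventional effect-size bands;
* t-based 95% confidence intervals of group means;
* Bland-Altman analysis: mean difference D, 1.96-SD limits of agreement and
  the t-based CI of D;
* within-participant coefficient of variation, CV_i = within-participant SD
  / within-participant mean x 100 (for two values the SD is |x1 - x2|/sqrt(2)),
  aggregated across participants and banded (<=10% acceptable, <=20%
  moderate, >20% high);
* single and average intraclass correlation coefficients from the two-way
  ANOVA mean squares, in both consistency and absolute-agreement forms,
  with F-distribution 95% CIs (the average-measurement CI is the
  Spearman-Brown step-up of the single-measurement CI, matching common
  statistical-package output) and Cicchetti / Koo reliability bands.

The module exposes the individual statistics as functions and wraps the
whole table in a statsmodels-style pair: :class:`ReliabilityModel` built
from a tidy DataFrame, whose :meth:`~ReliabilityModel.fit` returns a
:class:`ReliabilityResults` carrying the full-precision table, a rounded
report and ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSample",
    "BAResult",
    "CVResult",
    "ICCResult",
    "paired_ttest",
    "cohens_d",
    "mean_ci",
    "bland_altman",
    "within_cv",
    "anova_mean_squares",
    "icc",
    "classify_icc",
    "spearman_brown",
    "round_half_away",
    "simulate_paired",
    "build_table",
    "ReliabilityModel",
    "ReliabilityResults",
]

METRICS = ("fa", "rd", "md", "ad")
REGIONS = ("PT", "DC", "AH")


def round_half_away(x, decimals: int = 3):
    """Round half away from zero (report convention), elementwise."""
    x = np.asarray(x, dtype=float)
    factor = 10.0**decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PairedSample:
    """Paired measurements (test/retest or scanner-pooled pair)."""

    x1: np.ndarray
    x2: np.ndarray
    ids: np.ndarray | None = None
    metric: str = ""
    region: str = ""

    def __post_init__(self) -> None:
        x1 = np.asarray(self.x1, dtype=float)
        x2 = np.asarray(self.x2, dtype=float)
        if x1.shape != x2.shape or x1.ndim != 1:
            raise ValueError("x1 and x2 must be equal-length 1-D arrays")
        if x1.size < 2:
            raise ValueError("need at least 2 pairs")
        if np.any(~np.isfinite(x1)) or np.any(~np.isfinite(x2)):
            raise ValueError("missing or non-finite pairs are not allowed")
        object.__setattr__(self, "x1", x1)
        object.__setattr__(self, "x2", x2)

    @property
    def n(self) -> int:
        return self.x1.size

    @property
    def diff(self) -> np.ndarray:
        return self.x1 - self.x2


def paired_ttest(sample: PairedSample) -> tuple[float, int, float]:
    """Two-sided paired t-test: returns (t, df, p) with df = n - 1.

    Zero difference variance degenerates to p = 1 when the mean difference
    is 0 (identical pairs) and p = 0 otherwise (a constant non-zero shift).
    """
    d = sample.diff
    n = sample.n
    sd = d.std(ddof=1)
    if sd == 0:
        return (0.0, n - 1, 1.0) if d.mean() == 0 else (np.inf, n - 1, 0.0)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


def cohens_d(sample: PairedSample) -> tuple[float, str]:
    """Paired Cohen's d = mean(diff) / SD(diff) with its magnitude band.

    Bands: |d| < 0.20 negligible, 0.20-0.49 small, 0.50-0.79 medium,
    >= 0.80 large.  Zero difference variance is undefined (NaN, flagged
    'undefined') unless all differences are zero.
    """
    d = sample.diff
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, "negligible"
        return np.nan, "undefined"
    val = float(d.mean() / sd)
    a = abs(val)
    if a < 0.20:
        band = "negligible"
    elif a < 0.50:
        band = "small"
    elif a < 0.80:
        band = "medium"
    else:
        band = "large"
    return val, band


def mean_ci(
    values: np.ndarray, level: float = 0.95
) -> tuple[float, float, tuple[float, float]]:
    """Mean, SD and the t-based confidence interval of the mean."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values")
    m = float(values.mean())
    sd = float(values.std(ddof=1))
    half = stats.t.ppf(0.5 + level / 2.0, n - 1) * sd / np.sqrt(n)
    return m, sd, (m - half, m + half)


@dataclass(frozen=True)
class BAResult:
    """Bland-Altman agreement summary for a paired sample."""

    mean_diff: float
    sd_diff: float
    ci: tuple[float, float]  # t-based CI of the mean difference
    loa: tuple[float, float]  # mean_diff +/- 1.96 sd_diff
    n_outside: int


def bland_altman(sample: PairedSample, level: float = 0.95) -> BAResult:
    """Mean difference, limits of agreement and CI of the mean difference.

    LOA use the fixed 1.96 multiplier; the CI of D uses the t quantile with
    df = n - 1.  ``n_outside`` counts pairs beyond the LOA.
    """
    d = sample.diff
    n = sample.n
    D = float(d.mean())
    sd = float(d.std(ddof=1))
    half = float(stats.t.ppf(0.5 + level / 2.0, n - 1) * sd / np.sqrt(n))
    loa = (D - 1.96 * sd, D + 1.96 * sd)
    n_outside = int(np.sum(np.abs(d - D) > 1.96 * sd))
    return BAResult(
        mean_diff=D, sd_diff=sd, ci=(D - half, D + half), loa=loa, n_outside=n_outside
    )


@dataclass(frozen=True)
class CVResult:
    """Within-participant coefficient of variation, in percent."""

    per_participant: np.ndarray  # CV_i %
    cv: float  # aggregated CV %
    band: str  # acceptable / moderate / high
    aggregation: str  # mean or rms
    n_excluded: int = 0


def cv_band(cv: float, tol: float = 1e-9) -> str:
    # tol guards the <=10 / <=20 cutpoints against float round-off
    if cv <= 10.0 + tol:
        return "acceptable"
    if cv <= 20.0 + tol:
        return "moderate"
    return "high"


def within_cv(sample: PairedSample, aggregation: str = "mean") -> CVResult:
    """Within-participant CV: (|x1 - x2| / sqrt(2)) / pair mean x 100.

    Participants with a non-positive pair mean are excluded with a warning.
    Aggregation across participants is the arithmetic mean by default; RMS
    is available via ``aggregation='rms'``.
    """
    means = (sample.x1 + sample.x2) / 2.0
    ok = means > 0
    n_excluded = int(np.sum(~ok))
    if n_excluded:
        warnings.warn(
            f"{n_excluded} participant(s) with non-positive mean excluded from CV",
            stacklevel=2,
        )
    sds = np.abs(sample.diff[ok]) / np.sqrt(2.0)
    cv_i = sds / means[ok] * 100.0
    if aggregation == "mean":
        agg = float(cv_i.mean())
    elif aggregation == "rms":
        agg = float(np.sqrt(np.mean(cv_i**2)))
    else:
        raise ValueError("aggregation must be 'mean' or 'rms'")
    return CVResult(
        per_participant=cv_i,
        cv=agg,
        band=cv_band(agg),
        aggregation=aggregation,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------


def anova_mean_squares(y: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares of an (n rows x k columns) data matrix.

    Rows are participants, columns are conditions (test/retest).  Returns
    (MSR, MSC, MSE): between-rows, between-columns and residual mean
    squares.
    """
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    gm = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * np.sum((row_means - gm) ** 2)
    ssc = n * np.sum((col_means - gm) ** 2)
    sse = np.sum((y - row_means[:, None] - col_means[None, :] + gm) ** 2)
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def spearman_brown(r: float, k: float = 2.0) -> float:
    """Step a single-measurement reliability up to the mean of k measurements."""
    return k * r / (1.0 + (k - 1.0) * r)


@dataclass(frozen=True)
class ICCResult:
    """Single/average ICC with 95% CIs and the underlying mean squares."""

    single: float
    single_ci: tuple[float, float]
    average: float
    average_ci: tuple[float, float]
    model: str  # 'absolute' or 'consistency'
    ms: tuple[float, float, float]  # (MSR, MSC, MSE)
    n: int
    k: int


def icc(
    sample: PairedSample, model: str = "absolute", level: float = 0.95
) -> ICCResult:
    """Two-way ICC of a paired sample (k = 2 conditions).

    ``model='consistency'`` ignores a systematic condition offset
    (ICC(C,1) = (MSR - MSE) / (MSR + (k-1) MSE)); ``'absolute'`` penalises
    it (ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE)/n)).
    Average-measurement forms are the exact Spearman-Brown step-ups of the
    single forms.  CIs follow the standard F-distribution constructions;
    the absolute-agreement CI uses the Satterthwaite degrees of freedom.
    Average CIs are the Spearman-Brown step-ups of the single CI bounds.

    Values can be negative when the between-participant variance is small;
    they are reported as computed.
    """
    y = np.column_stack([sample.x1, sample.x2])
    n, k = y.shape
    msr, msc, mse = anova_mean_squares(y)
    alpha = 1.0 - level

    if model == "consistency":
        single = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0:
            lo, hi = 1.0, 1.0
        else:
            f_obs = msr / mse
            df2 = (n - 1) * (k - 1)
            fl = f_obs / stats.f.ppf(1 - alpha / 2, n - 1, df2)
            fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, n - 1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    elif model == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        single = (msr - mse) / denom if denom != 0 else 1.0
        if mse == 0 and msc == 0:
            lo, hi = 1.0, 1.0
        else:
            r = single
            a = k * r / (n * (1 - r)) if r < 1 else np.inf
            b = 1 + k * r * (n - 1) / (n * (1 - r)) if r < 1 else np.inf
            if np.isfinite(a):
                v = (a * msc + b * mse) ** 2 / (
                    (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
                )
            else:
                v = (msc + (n - 1) * mse) ** 2 / (
                    msc**2 / (k - 1) + ((n - 1) * mse) ** 2 / ((n - 1) * (k - 1))
                )
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f1 * mse) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            hi = n * (f2 * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msr
            )
    else:
        raise ValueError("model must be 'absolute' or 'consistency'")

    single = float(min(single, 1.0))
    lo, hi = float(lo), float(hi)
    return ICCResult(
        single=single,
        single_ci=(lo, hi),
        average=float(spearman_brown(single, k)),
        average_ci=(float(spearman_brown(lo, k)), float(spearman_brown(hi, k))),
        model=model,
        ms=(msr, msc, mse),
        n=n,
        k=k,
    )


def classify_icc(value: float) -> tuple[str, str]:
    """Reliability bands of an ICC value (or CI endpoint).

    Cicchetti: < 0.4 poor, 0.4-0.59 moderate, 0.60-0.74 good, 0.75-1
    excellent.  Koo: < 0.5 poor, 0.5-0.75 moderate, 0.75-0.9 good, > 0.9
    excellent.
    """
    if not (-1.0 <= value <= 1.0):
        raise ValueError("ICC must lie in [-1, 1]")
    if value < 0.4:
        cic = "poor"
    elif value < 0.60:
        cic = "moderate"
    elif value < 0.75:
        cic = "good"
    else:
        cic = "excellent"
    if value < 0.5:
        koo = "poor"
    elif value < 0.75:
        koo = "moderate"
    elif value <= 0.9:
        koo = "good"
    else:
        koo = "excellent"
    return cic, koo


def simulate_paired(
    n: int,
    true_icc: float,
    mean: float = 0.58,
    total_sd: float = 0.03,
    rng: np.random.Generator | None = None,
) -> PairedSample:
    """Draw one paired cohort with a known true single ICC.

    x_ij = mean + p_i + e_ij with Var(p) = icc * total_sd^2 and
    Var(e) = (1 - icc) * total_sd^2; no condition (session) offset.
    Used for estimator recovery and CI calibration studies.
    """
    if rng is None:
        rng = np.random.default_rng()
    sd_p = total_sd * np.sqrt(true_icc)
    sd_e = total_sd * np.sqrt(1.0 - true_icc)
    p = rng.normal(0.0, sd_p, size=n)
    x1 = mean + p + rng.normal(0.0, sd_e, size=n)
    x2 = mean + p + rng.normal(0.0, sd_e, size=n)
    return PairedSample(x1=x1, x2=x2)


# ---------------------------------------------------------------------------
# table assembly (statsmodels-style Model / Results)
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "comparison", "metric", "region", "n",
    "test_mean", "test_sd", "test_ci_lo", "test_ci_hi",
    "retest_mean", "retest_sd", "retest_ci_lo", "retest_ci_hi",
    "pooled_mean", "pooled_sd", "pooled_ci_lo", "pooled_ci_hi",
    "t", "p", "p_corrected", "d", "d_band",
    "diff_mean", "diff_sd", "diff_ci_lo", "diff_ci_hi",
    "loa_lo", "loa_hi", "n_outside_loa",
    "cv_pct", "cv_band",
    "icc_single", "icc_single_lo", "icc_single_hi",
    "icc_average", "icc_average_lo", "icc_average_hi",
    "icc_single_cicchetti", "icc_single_koo",
]


def _row_for_sample(
    sample: PairedSample,
    comparison: str,
    icc_model: str,
    cv_aggregation: str,
) -> dict:
    t, _, p = paired_ttest(sample)
    d, d_band = cohens_d(sample)
    ba = bland_altman(sample)
    cv = within_cv(sample, cv_aggregation)
    ic = icc(sample, icc_model)
    m1, s1, ci1 = mean_ci(sample.x1)
    m2, s2, ci2 = mean_ci(sample.x2)
    pooled = (sample.x1 + sample.x2) / 2.0
    mp, sp, cip = mean_ci(pooled)
    cic, koo = classify_icc(np.clip(ic.single, -1.0, 1.0))
    return {
        "comparison": comparison,
        "metric": sample.metric,
        "region": sample.region,
        "n": sample.n,
        "test_mean": m1, "test_sd": s1, "test_ci_lo": ci1[0], "test_ci_hi": ci1[1],
        "retest_mean": m2, "retest_sd": s2, "retest_ci_lo": ci2[0], "retest_ci_hi": ci2[1],
        "pooled_mean": mp, "pooled_sd": sp, "pooled_ci_lo": cip[0], "pooled_ci_hi": cip[1],
        "t": t, "p": p, "p_corrected": np.nan, "d": d, "d_band": d_band,
        "diff_mean": ba.mean_diff, "diff_sd": ba.sd_diff,
        "diff_ci_lo": ba.ci[0], "diff_ci_hi": ba.ci[1],
        "loa_lo": ba.loa[0], "loa_hi": ba.loa[1], "n_outside_loa": ba.n_outside,
        "cv_pct": cv.cv, "cv_band": cv.band,
        "icc_single": ic.single,
        "icc_single_lo": ic.single_ci[0], "icc_single_hi": ic.single_ci[1],
        "icc_average": ic.average,
        "icc_average_lo": ic.average_ci[0], "icc_average_hi": ic.average_ci[1],
        "icc_single_cicchetti": cic, "icc_single_koo": koo,
    }


def _paired_samples_from_tidy(tidy: pd.DataFrame):
    """Yield (comparison, metric, region, PairedSample) for each table row.

    Comparisons: per-scanner test vs retest (sessions 1 and 2), plus the
    inter-scanner comparison of per-participant session means when two
    scanners are present.  Participants with incomplete pairs are skipped
    with a warning.
    """
    scanners = sorted(tidy["scanner"].unique())
    pivot = tidy.pivot_table(
        index=["participant", "region", "metric"],
        columns=["scanner", "session"],
        values="value",
    )
    for scanner in scanners:
        sessions = sorted(tidy.loc[tidy.scanner == scanner, "session"].unique())
        if len(sessions) < 2:
            warnings.warn(
                f"scanner {scanner}: fewer than 2 sessions, test-retest skipped",
                stacklevel=3,
            )
            continue
        s1, s2 = sessions[:2]
        for (region, metric), grp in pivot.groupby(level=["region", "metric"]):
            sub = grp[[(scanner, s1), (scanner, s2)]].dropna()
            if len(sub) < 2:
                warnings.warn(
                    f"{scanner}/{metric}/{region}: incomplete pairs, row skipped",
                    stacklevel=3,
                )
                continue
            yield scanner, metric, region, PairedSample(
                x1=sub[(scanner, s1)].to_numpy(),
                x2=sub[(scanner, s2)].to_numpy(),
                metric=metric,
                region=region,
            )
    if len(scanners) >= 2:
        sc1, sc2 = scanners[:2]
        for (region, metric), grp in pivot.groupby(level=["region", "metric"]):
            a = grp[sc1].mean(axis=1)
            b = grp[sc2].mean(axis=1)
            sub = pd.concat([a, b], axis=1).dropna()
            if len(sub) < 2:
                continue
            yield f"{sc1}_vs_{sc2}", metric, region, PairedSample(
                x1=sub.iloc[:, 0].to_numpy(),
                x2=sub.iloc[:, 1].to_numpy(),
                metric=metric,
                region=region,
            )


def build_table(
    tidy: pd.DataFrame,
    icc_model: str = "absolute",
    cv_aggregation: str = "mean",
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Full-precision reliability table from tidy per-acquisition metrics.

    ``tidy`` columns: participant, scanner, session, region, metric, value.
    One row per comparison x metric x region.  The multiple-comparison
    correction (default Bonferroni across the metric x region tests of each
    comparison) fills ``p_corrected``; raw p is always kept.
    """
    rows = [
        _row_for_sample(s, comp, icc_model, cv_aggregation)
        for comp, _m, _r, s in _paired_samples_from_tidy(tidy)
    ]
    table = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    if len(table) == 0:
        return table
    if correction == "bonferroni":
        m = table.groupby("comparison")["p"].transform("size")
        table["p_corrected"] = np.minimum(table["p"] * m, 1.0)
    elif correction in (None, "none"):
        table["p_corrected"] = table["p"]
    else:
        raise ValueError("correction must be 'bonferroni' or 'none'")
    return table


class ReliabilityModel:
    """Reliability analysis of a tidy tract-metric table.

    Parameters
    ----------
    data : DataFrame
        Tidy table with columns participant, scanner, session, region,
        metric, value (one row per acquisition and metric).
    """

    REQUIRED = ("participant", "scanner", "session", "region", "metric", "value")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        self.data = data.copy()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "ReliabilityModel":
        return cls(data)

    def fit(
        self,
        icc_model: str = "absolute",
        cv_aggregation: str = "mean",
        correction: str = "bonferroni",
    ) -> "ReliabilityResults":
        table = build_table(self.data, icc_model, cv_aggregation, correction)
        return ReliabilityResults(
            model=self,
            table=table,
            options={
                "icc_model": icc_model,
                "cv_aggregation": cv_aggregation,
                "correction": correction,
            },
        )


@dataclass
class ReliabilityResults:
    """Fitted reliability battery: full-precision table plus report views."""

    model: ReliabilityModel
    table: pd.DataFrame
    options: dict

    def report_table(self, decimals: int = 3) -> pd.DataFrame:
        """Report view rounded half-away-from-zero (3 decimals by default)."""
        out = self.table.copy()
        num = out.select_dtypes(include=[float]).columns
        out[num] = out[num].apply(lambda c: round_half_away(c.to_numpy(), decimals))
        return out

    def summary(self) -> str:
        """Plain-text summary in the style of a study results table."""
        rep = self.report_table()
        lines = [
            "Reliability analysis "
            f"(ICC model: {self.options['icc_model']}, "
            f"CV aggregation: {self.options['cv_aggregation']}, "
            f"correction: {self.options['correction']})",
        ]
        for comp, grp in rep.groupby("comparison", sort=False):
            lines.append(f"\n== {comp} ==")
            cols = [
                "metric", "region",
                "test_mean", "retest_mean", "pooled_mean", "p",
                "diff_mean", "loa_lo", "loa_hi", "cv_pct",
                "icc_single", "icc_average", "icc_single_koo",
            ]
            lines.append(grp[cols].to_string(index=False))
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.report_table().to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)

    def plot_bland_altman(self, metric: str, region: str, comparison: str, ax=None):
        """Bland-Altman scatter with D, LOA and CI lines for one table row."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        found = None
        for comp, m, r, s in _paired_samples_from_tidy(self.model.data):
            if (comp, m, r) == (comparison, metric, region):
                found = s
                break
        if found is None:
            raise ValueError(f"no row {comparison}/{metric}/{region}")
        ba = bland_altman(found)
        if ax is None:
            _, ax = plt.subplots()
        avg = (found.x1 + found.x2) / 2.0
        ax.scatter(avg, found.diff, color="k", s=18)
        ax.axhline(ba.mean_diff, color="k")
        for y in ba.loa:
            ax.axhline(y, color="k", linestyle=":")
        for y in ba.ci:
            ax.axhline(y, color="gray", linestyle="--", linewidth=0.8)
        ax.set_xlabel(f"mean of pair ({metric} {region})")
        ax.set_ylabel("difference")
        ax.set_title(comparison)
        return ax
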