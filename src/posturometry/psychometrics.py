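"""Reliability, agreement and group-discrimination statistics.

Implements the statistical battery applied to each screening endpoint:

* test-retest reliability — Wilcoxon signed-rank for systematic occasion
  differences, ICC(3,1) (two-way mixed-effects, single-measure,
  consistency) with an F-based 95% CI, SEM and MDC in original units;
* construct validity — Spearman rank correlation, ICC, and Bland-Altman
  fixed/proportional bias against a reference device;
* discriminative validity — Mann-Whitney U between groups;
* the conventional qualitative bands for ICC and Spearman coefficients,
  and an advisory normality report (Lilliefors KS + Shapiro-Wilk).

All estimators use pairwise deletion of incomplete rows and report the
exclusion count; no multiplicity correction is applied (the comparison
count is surfaced instead).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "ReliabilityResult",
    "AgreementResult",
    "GroupComparison",
    "DegenerateDataError",
    "icc_3_1",
    "sem",
    "mdc",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "spearman",
    "bland_altman",
    "classify_icc",
    "classify_spearman",
    "normality_report",
    "evaluate_reliability",
    "evaluate_agreement",
    "MDC_FACTOR",
]

#: MDC = 1.96 * sqrt(2) * SEM — the 95% threshold for a real individual change.
MDC_FACTOR: float = 1.96 * math.sqrt(2.0)


class DegenerateDataError(ValueError):
    """The data admit no meaningful estimate (e.g. constant columns)."""


@dataclass
class PairedMeasurements:
    """An n x 2 matrix of paired observations of one endpoint.

    Columns are two occasions (reliability) or two devices (validity).
    Rows with a non-finite cell are excluded pairwise at construction;
    ``n_excluded`` reports how many.
    """

    values: np.ndarray
    labels: tuple[str, str] = ("A", "B")
    variable_name: str = ""
    units: str = ""
    n_excluded: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError(f"values must be (n, 2), got {v.shape}")
        keep = np.all(np.isfinite(v), axis=1)
        self.n_excluded = int((~keep).sum())
        self.values = v[keep]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def a(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def b(self) -> np.ndarray:
        return self.values[:, 1]

    def require(self, n_min: int) -> None:
        if self.n < n_min:
            raise DegenerateDataError(
                f"{self.variable_name or 'endpoint'}: need n >= {n_min} complete "
                f"pairs, have {self.n} ({self.n_excluded} excluded)")


@dataclass
class ReliabilityResult:
    variable_name: str
    units: str
    n: int
    p_systematic: float
    icc: float
    icc_ci: tuple[float, float]
    icc_band: str
    sem: float
    mdc: float
    sem_formula: str = "sd*sqrt(1-icc)"
    degenerate: bool = False
    n_excluded: int = 0


@dataclass
class AgreementResult:
    variable_name: str
    units: str
    n: int
    p_systematic: float
    rho: float
    rho_p: float
    rho_band: str
    icc: float
    icc_ci: tuple[float, float]
    bias: float
    loa: tuple[float, float]
    prop_slope: float
    prop_p: float
    degenerate: bool = False
    n_excluded: int = 0


@dataclass
class GroupComparison:
    variable_name: str = ""
    units: str = ""
    n_a: int = 0
    n_b: int = 0
    median_a: float = math.nan
    iqr_a: float = math.nan
    median_b: float = math.nan
    iqr_b: float = math.nan
    p: float = math.nan


# ---------------------------------------------------------------------------
# reliability


def icc_3_1(paired: PairedMeasurements, alpha: float = 0.05
            ) -> tuple[float, tuple[float, float]]:
    """Single-measure consistency ICC from a two-way mixed-effects model.

    With k = 2 raters (occasions) and n subjects, the two-way ANOVA gives

        ICC(3,1) = (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error)

    where MS_error is the residual after removing subject and occasion
    effects.  Negative estimates are preserved.  The CI follows the
    F-distribution method: F = MS_subjects / MS_error with (n-1) and
    (n-1)(k-1) degrees of freedom.
    """
    paired.require(3)
    x = paired.values
    n, k = x.shape
    if np.ptp(x[:, 0]) == 0 and np.ptp(x[:, 1]) == 0:
        raise DegenerateDataError("both columns constant; ICC undefined")
    grand = x.mean()
    ms_rows = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    ss_cols = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_err = np.sum((x - grand) ** 2) - k * np.sum((x.mean(axis=1) - grand) ** 2) - ss_cols
    ss_err = max(ss_err, 0.0)  # mathematically >= 0; guards roundoff
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    if denom == 0:
        raise DegenerateDataError("zero total variance; ICC undefined")
    icc = (ms_rows - ms_err) / denom
    if ms_err == 0:
        return float(icc), (float(icc), float(icc))
    f_obs = ms_rows / ms_err
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (f_l - 1) / (f_l + k - 1)
    hi = (f_u - 1) / (f_u + k - 1)
    return float(icc), (float(lo), float(hi))


def _pooled_sd(paired: PairedMeasurements) -> float:
    """Pooled between-subject SD: root mean of the two occasion variances."""
    v1 = np.var(paired.a, ddof=1)
    v2 = np.var(paired.b, ddof=1)
    return float(math.sqrt((v1 + v2) / 2.0))


def sem(paired: PairedMeasurements, icc: float | None = None, *,
        formula: str = "standard") -> float:
    """Standard error of measurement in the endpoint's original units.

    ``formula="standard"``: SEM = SD_pooled * sqrt(1 - ICC), with
    SD_pooled the root mean of the two occasion variances — this
    estimates the within-subject SD.  ``formula="footnote"`` selects the
    alternative 2*SD*ICC form some reports print; it is provided for
    comparison only and is not the default.
    """
    if icc is None:
        icc, _ = icc_3_1(paired)
    if not np.isfinite(icc) or icc > 1:
        raise DegenerateDataError(f"ICC {icc} out of range; SEM undefined")
    sd = _pooled_sd(paired)
    if formula == "standard":
        return float(sd * math.sqrt(max(0.0, 1.0 - icc)))
    if formula == "footnote":
        return float(2.0 * sd * icc)
    raise ValueError(f"formula must be 'standard' or 'footnote', got {formula!r}")


def mdc(sem_value: float) -> float:
    """Minimal detectable change: MDC = 1.96 * sqrt(2) * SEM."""
    if sem_value < 0 or not np.isfinite(sem_value):
        raise ValueError(f"SEM must be finite and >= 0, got {sem_value}")
    return float(MDC_FACTOR * sem_value)


# ---------------------------------------------------------------------------
# hypothesis tests


def wilcoxon_signed_rank(paired: PairedMeasurements) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value for A vs B.

    Zero differences are dropped before ranking; the exact null
    distribution is used for n <= 25 without tied absolute differences,
    the tie-corrected normal approximation otherwise.  All-zero
    differences give p = 1 (no evidence of any shift).
    """
    paired.require(3)
    d = paired.a - paired.b
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    if d.size < 5:
        # exact but powerless at this size; still well-defined
        method = "exact"
    else:
        ties = np.unique(np.abs(d)).size < d.size
        method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    return float(res.pvalue)


def mann_whitney_u(group_a: np.ndarray, group_b: np.ndarray, *,
                   variable_name: str = "", units: str = "") -> GroupComparison:
    """Two-sided Mann-Whitney U comparison with medians and IQRs.

    Exact p-value when the smaller group has n <= 8 and there are no
    cross-group ties; tie-corrected normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 3 or b.size < 3:
        raise ValueError(f"each group needs n >= 3, got {a.size} and {b.size}")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    q = lambda x: np.percentile(x, [25, 75])
    qa, qb = q(a), q(b)
    return GroupComparison(
        variable_name=variable_name, units=units, n_a=a.size, n_b=b.size,
        median_a=float(np.median(a)), iqr_a=float(qa[1] - qa[0]),
        median_b=float(np.median(b)), iqr_b=float(qb[1] - qb[0]),
        p=float(res.pvalue))


def spearman(paired: PairedMeasurements) -> tuple[float, float]:
    """Spearman rank correlation (average ranks on ties) with t-approximation p."""
    paired.require(4)
    rho, p = stats.spearmanr(paired.a, paired.b)
    return float(rho), float(p)


def bland_altman(paired: PairedMeasurements
                 ) -> tuple[float, tuple[float, float], float, float]:
    """Bland-Altman agreement: fixed bias, 95% limits, proportional bias.

    bias = mean(A - B); limits of agreement bias +/- 1.96 * SD(A - B)
    (sample SD); proportional bias is the OLS slope of the differences on
    the pair means (A + B)/2 with its two-sided p-value.
    """
    paired.require(3)
    diff = paired.a - paired.b
    mean = (paired.a + paired.b) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    if np.ptp(mean) == 0 or sd == 0:
        slope, p = 0.0, 1.0
    else:
        fit = stats.linregress(mean, diff)
        slope, p = float(fit.slope), float(fit.pvalue)
    return bias, loa, slope, p


# ---------------------------------------------------------------------------
# qualitative bands and normality

_ICC_BANDS = ((0.20, "poor"), (0.40, "fair"), (0.60, "moderate"),
              (0.80, "good"), (1.00, "very_good"))
_RHO_BANDS = ((0.30, "negligible"), (0.50, "low"), (0.70, "moderate"),
              (0.90, "high"), (1.00, "very_high"))


def _band(value: float, bands) -> str:
    if not np.isfinite(value):
        raise ValueError("band undefined for non-finite input")
    for upper, label in bands:
        if value <= upper:
            return label
    return bands[-1][1]


def classify_icc(icc: float) -> str:
    """Conventional reliability band; intervals upper-closed, negatives poor."""
    return _band(icc, _ICC_BANDS)


def classify_spearman(rho: float) -> str:
    """Conventional correlation-strength band (on the magnitude)."""
    return _band(abs(rho), _RHO_BANDS)


def normality_report(series: np.ndarray) -> dict:
    """Advisory normality check: Lilliefors-corrected KS and Shapiro-Wilk.

    Returns both p-values and ``nonparametric_recommended`` when either
    falls below 0.05.  The pipeline uses nonparametric tests regardless;
    this report only documents why.
    """
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError(f"need n >= 3 for a normality check, got {x.size}")
    if np.ptp(x) == 0:
        return {"ks_p": 0.0, "shapiro_p": 0.0, "nonparametric_recommended": True}
    _, ks_p = lilliefors(x, dist="norm")
    _, sw_p = stats.shapiro(x)
    return {"ks_p": float(ks_p), "shapiro_p": float(sw_p),
            "nonparametric_recommended": bool(ks_p < 0.05 or sw_p < 0.05)}


# ---------------------------------------------------------------------------
# per-endpoint bundles


def evaluate_reliability(paired: PairedMeasurements) -> ReliabilityResult:
    """Full test-retest battery for one endpoint (occasion 1 vs occasion 2)."""
    paired.require(3)
    degenerate = False
    try:
        icc, ci = icc_3_1(paired)
        sem_v = sem(paired, icc)
        mdc_v = mdc(sem_v)
        band = classify_icc(icc)
    except DegenerateDataError:
        degenerate = True
        icc, ci, sem_v, mdc_v, band = math.nan, (math.nan, math.nan), 0.0, 0.0, "poor"
    return ReliabilityResult(
        variable_name=paired.variable_name, units=paired.units, n=paired.n,
        p_systematic=wilcoxon_signed_rank(paired),
        icc=icc, icc_ci=ci, icc_band=band, sem=sem_v, mdc=mdc_v,
        degenerate=degenerate, n_excluded=paired.n_excluded)


def evaluate_agreement(paired: PairedMeasurements) -> AgreementResult:
    """Full device-agreement battery for one endpoint (device A vs B)."""
    paired.require(4)
    degenerate = False
    try:
        icc, ci = icc_3_1(paired)
    except DegenerateDataError:
        degenerate = True
        icc, ci = math.nan, (math.nan, math.nan)
    rho, rho_p = spearman(paired)
    bias, loa, slope, slope_p = bland_altman(paired)
    return AgreementResult(
        variable_name=paired.variable_name, units=paired.units, n=paired.n,
        p_systematic=wilcoxon_signed_rank(paired),
        rho=rho, rho_p=rho_p, rho_band=classify_spearman(rho),
        icc=icc, icc_ci=ci, bias=bias, loa=loa,
        prop_slope=slope, prop_p=slope_p,
        degenerate=degenerate, n_excluded=paired.n_excluded)
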