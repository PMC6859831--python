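"""Test-retest agreement statistics for paired same-visit measurements.

Implements the agreement toolkit used to assess intravisit and
intraoperator repeatability of the quantitative indices:

* Bland-Altman analysis of the paired differences d_i = m1_i - m2_i:
  bias (mean difference), 95% limits of agreement bias ± 1.96·SD(d),
  the coefficient of repeatability CR = 1.96·SD(d), and a one-sample
  t-test of the differences against zero.
* CR expressed as a fraction of the cohort's average measurement
  (Bland-Altman analysis yields no CV, so CR/mean plays that role).
* ICC(3,1): the two-way mixed-effects, single-measurement, consistency
  intraclass correlation, equal to between-subject variance over
  between-subject plus residual variance, with the exact F-based
  (Shrout-Fleiss) 95% confidence interval.
* Coefficient of variation: within-person SD (from duplicate
  measurements, sqrt of mean d²/2) over the grand mean, in percent.
* A Pearson screen of |difference| against a clinical-activity flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PairedMeasurements:
    """Paired same-visit measurements of one index across subjects."""

    subject_ids: list[str]
    m1: np.ndarray
    m2: np.ndarray
    index_name: str = "index"
    units: str = "mm2"

    def __post_init__(self) -> None:
        self.m1 = np.asarray(self.m1, dtype=float)
        self.m2 = np.asarray(self.m2, dtype=float)
        if not (len(self.subject_ids) == self.m1.size == self.m2.size):
            raise ValueError("subject_ids, m1, m2 must have equal length")
        if not (np.isfinite(self.m1).all() and np.isfinite(self.m2).all()):
            raise ValueError("measurements must be finite")

    @property
    def n(self) -> int:
        return self.m1.size

    @property
    def differences(self) -> np.ndarray:
        # fixed direction scan1 - scan2 for sign reproducibility
        return self.m1 - self.m2

    @classmethod
    def from_frame(cls, df: pd.DataFrame, index_name: str = "index") -> "PairedMeasurements":
        return cls(
            subject_ids=list(df["subject_id"].astype(str)),
            m1=df["m1"].to_numpy(),
            m2=df["m2"].to_numpy(),
            index_name=index_name,
        )


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    cr: float
    p_value: float
    cr_over_mean: float
    n: int
    degenerate_p: bool = False


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bland-Altman summary of paired differences.

    Uses the sample (n-1) SD of the differences, CR = 1.96·SD, limits
    of agreement bias ± CR, and a two-sided one-sample t-test of the
    differences against zero.  With zero difference SD the t-test is
    degenerate; p is reported as 1.0 for zero bias and 0.0 otherwise,
    with ``degenerate_p`` set.
    """
    if pairs.n < 3:
        raise ValueError("Bland-Altman analysis needs at least 3 pairs")
    d = pairs.differences
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    cr = 1.96 * sd
    degenerate = sd == 0
    if degenerate:
        p = 1.0 if bias == 0 else 0.0
    else:
        p = float(stats.ttest_1samp(d, 0.0).pvalue)
    grand_mean = float(((pairs.m1 + pairs.m2) / 2).mean())
    ratio = cr / grand_mean if grand_mean > 0 else math.nan
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - cr,
        loa_upper=bias + cr,
        cr=cr,
        p_value=p,
        cr_over_mean=ratio,
        n=pairs.n,
        degenerate_p=degenerate,
    )


def cr_over_mean(cr: float, grand_mean: float) -> float:
    """Coefficient of repeatability as a fraction of the cohort average."""
    if grand_mean <= 0:
        raise ValueError("grand mean must be positive")
    return cr / grand_mean


@dataclass
class ICCResult:
    icc: float
    ci_lower: float
    ci_upper: float
    n: int
    model: str = "ICC(3,1) two-way mixed, consistency"


def icc_3_1(pairs: PairedMeasurements, ci: float = 0.95) -> ICCResult:
    """ICC(3,1): two-way mixed-effects, consistency, single measurement.

    From the two-way ANOVA decomposition with n subjects and k=2
    replicates: BMS the between-subject mean square and EMS the
    residual (subject x replicate interaction) mean square,

        ICC = (BMS - EMS) / (BMS + (k-1)·EMS),

    the sample counterpart of between-subject variance over
    between-subject plus measurement variance.  The confidence
    interval is the exact F-based interval: with F = BMS/EMS,
    FL = F / F_{alpha/2; n-1, (n-1)(k-1)} and
    FU = F · F_{alpha/2; (n-1)(k-1), n-1}, the bounds are
    (FL-1)/(FL+k-1) and (FU-1)/(FU+k-1).
    """
    n = pairs.n
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    k = 2
    data = np.column_stack([pairs.m1, pairs.m2])
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    if np.allclose(data, grand):
        raise ValueError("zero total variance: ICC undefined")
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_rater = n * ((rater_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_rater
    bms = ss_subj / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if bms + (k - 1) * ems == 0:
        raise ValueError("degenerate variance structure: ICC undefined")
    icc = (bms - ems) / (bms + (k - 1) * ems)

    alpha = 1.0 - ci
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if ems == 0:
        lo = hi = 1.0
    else:
        f_obs = bms / ems
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + (k - 1))
        hi = (fu - 1) / (fu + (k - 1))
    return ICCResult(icc=float(icc), ci_lower=float(lo), ci_upper=float(hi), n=n)


@dataclass
class CVResult:
    cv_percent: float
    within_sd: float
    grand_mean: float


def coefficient_of_variation(pairs: PairedMeasurements) -> CVResult:
    """Within-person CV in percent, from duplicate measurements.

    For duplicates the within-person variance of subject i is
    d_i²/2; the within-person SD is the root of its mean over
    subjects, and CV = 100 · within-SD / grand mean of all
    measurements.  Computed on the raw scale.
    """
    if pairs.n < 2:
        raise ValueError("CV needs at least 2 subjects")
    grand_mean = float(np.concatenate([pairs.m1, pairs.m2]).mean())
    if grand_mean <= 0:
        raise ValueError("grand mean must be positive for a CV")
    within_var = float((pairs.differences**2 / 2).mean())
    within_sd = math.sqrt(within_var)
    return CVResult(
        cv_percent=100.0 * within_sd / grand_mean,
        within_sd=within_sd,
        grand_mean=grand_mean,
    )


def activity_correlation(
    abs_diffs: np.ndarray, activity: np.ndarray
) -> tuple[float, float]:
    """Pearson r (and two-sided p) of |difference| vs a clinical-activity flag."""
    d = np.asarray(abs_diffs, dtype=float)
    a = np.asarray(activity, dtype=float)
    if d.shape != a.shape or d.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(d) == 0 or np.ptp(a) == 0:
        raise ValueError("inputs must be non-constant")
    res = stats.pearsonr(d, a)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AgreementReport:
    """Per-index agreement summary (Bland-Altman, ICC, CV blocks)."""

    indices: dict[str, dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, blk in self.indices.items():
            ba: BlandAltmanResult = blk["bland_altman"]
            icc: ICCResult | None = blk.get("icc")
            cv: CVResult | None = blk.get("cv")
            rows.append(
                {
                    "index": name,
                    "n": ba.n,
                    "bias": ba.bias,
                    "loa_lower": ba.loa_lower,
                    "loa_upper": ba.loa_upper,
                    "p_value": ba.p_value,
                    "cr": ba.cr,
                    "mean": blk["grand_mean"],
                    "sd": blk["grand_sd"],
                    "cr_over_mean": ba.cr_over_mean,
                    "icc": icc.icc if icc else math.nan,
                    "icc_ci_lower": icc.ci_lower if icc else math.nan,
                    "icc_ci_upper": icc.ci_upper if icc else math.nan,
                    "cv_percent": cv.cv_percent if cv else math.nan,
                }
            )
        return pd.DataFrame(rows)


def repeatability_report(
    measurements: dict[str, PairedMeasurements]
) -> AgreementReport:
    """Assemble the full agreement report across indices.

    ICC and CV blocks are included when computable (nonzero variance,
    positive mean); the Bland-Altman block is always present.
    """
    report = AgreementReport()
    for name, pairs in measurements.items():
        blk: dict = {
            "bland_altman": bland_altman(pairs),
            "grand_mean": float(((pairs.m1 + pairs.m2) / 2).mean()),
            "grand_sd": float(((pairs.m1 + pairs.m2) / 2).std(ddof=1)),
            "n": pairs.n,
        }
        try:
            blk["icc"] = icc_3_1(pairs)
        except ValueError:
            blk["icc"] = None
        try:
            blk["cv"] = coefficient_of_variation(pairs)
        except ValueError:
            blk["cv"] = None
        report.indices[name] = blk
    return report
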