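"""Cohort-level statistics for the chin-point method validation.

Reproduces the study's statistical layer on any measured cohort:

* per-variable descriptives (mean, SD, 95% CI) of the four lip distances
  under the ACP- and MCP-anchored reference lines, with paired t-tests
  (ACP vs MCP) at each timepoint — the "Table 2" analogue;
* pre- vs post-surgery comparison of the ACP-to-MCP distance |x|
  (mean/SD/median/IQR, Wilcoxon signed-rank) — "Table 3";
* method-agreement errors ME and MAE between post-surgery ACP- and
  MCP-based measurements — "Table 4";
* sex-stratified post-surgery MCP-based lip positions with Welch
  t-tests — "Table 5";
* Pearson correlations between ACP(T1) vs MCP(T1) and MCP(T0) vs
  MCP(T1) per variable.

Shapiro–Wilk normality checks are computed per variable and logged, but
do not switch tests automatically.  Significance uses a Bonferroni-style
threshold; the default "paper" mode reproduces the published decision
rule p < 0.01 for alpha = 0.05 over 4 tests, while "exact" mode returns
alpha / n_tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError, ValidationError
from .landmarks import Cohort, chin_deviation_qc
from .lips import LIP_VARIABLES
from .pipeline import measure_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "PairedSeries",
    "Descriptive",
    "ValiditySummary",
    "AnalysisConfig",
    "CohortResults",
    "descriptive",
    "paired_t",
    "wilcoxon_signed_rank",
    "validity_errors",
    "pearson_r",
    "independent_t",
    "bonferroni_threshold",
    "run_validation",
]


@dataclass(frozen=True)
class PairedSeries:
    """Two measurement series aligned subject-by-subject."""

    labels: tuple[str, ...]
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        labels = tuple(str(s) for s in self.labels)
        if not (len(labels) == a.size == b.size):
            raise ValidationError("paired series must have equal, aligned lengths")
        if a.size < 2:
            raise ValidationError("paired series needs at least 2 subjects")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValidationError("paired series contains non-finite values")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.a.size

    def differences(self) -> np.ndarray:
        return self.a - self.b


@dataclass(frozen=True)
class Descriptive:
    n: int
    mean: float
    sd: float
    ci95_low: float
    ci95_high: float


@dataclass(frozen=True)
class ValiditySummary:
    """Method-agreement errors between two measurement routes (a - b)."""

    me_mean: float
    me_sd: float
    me_min: float
    me_max: float
    mae_mean: float
    mae_sd: float
    mae_min: float
    mae_max: float


def descriptive(values, confidence: float = 0.95) -> Descriptive:
    """Sample mean, SD (n-1 denominator) and t-based confidence interval."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("descriptive statistics need n >= 2")
    n = x.size
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    half = float(sps.t.ppf(0.5 + confidence / 2.0, n - 1) * sd / math.sqrt(n))
    return Descriptive(n=n, mean=mean, sd=sd, ci95_low=mean - half, ci95_high=mean + half)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float


def paired_t(series: PairedSeries) -> PairedTResult:
    """Two-sided paired t-test on a - b.

    Zero-variance convention: if all differences are identical the test
    statistic is degenerate; a zero mean difference yields t = 0, p = 1,
    a nonzero one t = +/-inf, p = 0.
    """
    d = series.differences()
    n = d.size
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return PairedTResult(t=0.0, df=n - 1, p=1.0)
        return PairedTResult(t=math.copysign(math.inf, d[0]), df=n - 1, p=0.0)
    res = sps.ttest_rel(series.a, series.b)
    return PairedTResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue))


@dataclass(frozen=True)
class WilcoxonResult:
    w: float  # sum of ranks of positive differences (average ranks for ties)
    p: float
    n_nonzero: int
    method: str  # "exact" | "normal"


_EXACT_WILCOXON_MAX_N = 25


def _wilcoxon_exact_counts(ranks2: np.ndarray) -> np.ndarray:
    """Counts of each doubled positive-rank sum over all 2^n sign patterns."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts += shifted
    return counts


def wilcoxon_signed_rank(series: PairedSeries) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test (two-sided).

    Zero differences are dropped; ties receive average ranks.  The exact
    null distribution (enumeration via dynamic programming over the
    realized rank multiset) is used for n <= 25 nonzero differences, a
    normal approximation with continuity and tie corrections above.
    """
    d = series.differences()
    d = d[d != 0.0]
    n = d.size
    if n < 5:
        raise ValidationError(
            "fewer than 5 nonzero differences; the signed-rank null "
            "distribution is too coarse to be meaningful"
        )
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= _EXACT_WILCOXON_MAX_N:
        ranks2 = np.rint(2.0 * ranks).astype(int)
        counts = _wilcoxon_exact_counts(ranks2)
        w2 = int(round(2.0 * w))
        denom = 2.0**n
        p_le = counts[: w2 + 1].sum() / denom
        p_ge = counts[w2:].sum() / denom
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(w=w, p=float(p), n_nonzero=n, method="exact")
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    if var <= 0:
        return WilcoxonResult(w=w, p=1.0, n_nonzero=n, method="normal")
    z = (w - mu - 0.5 * np.sign(w - mu)) / math.sqrt(var)
    p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return WilcoxonResult(w=w, p=p, n_nonzero=n, method="normal")


def validity_errors(series: PairedSeries) -> ValiditySummary:
    """ME and MAE summaries of d = a - b (ACP-based minus MCP-based)."""
    d = series.differences()
    ad = np.abs(d)
    return ValiditySummary(
        me_mean=float(np.mean(d)),
        me_sd=float(np.std(d, ddof=1)),
        me_min=float(np.min(d)),
        me_max=float(np.max(d)),
        mae_mean=float(np.mean(ad)),
        mae_sd=float(np.std(ad, ddof=1)),
        mae_min=float(np.min(ad)),
        mae_max=float(np.max(ad)),
    )


def pearson_r(series: PairedSeries) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value."""
    if series.n < 3:
        raise ValidationError("Pearson correlation needs n >= 3")
    if np.ptp(series.a) == 0.0 or np.ptp(series.b) == 0.0:
        raise ValidationError("Pearson correlation undefined for a constant series")
    res = sps.pearsonr(series.a, series.b)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def independent_t(group1, group2) -> WelchResult:
    """Welch's unequal-variance two-sample t-test (two-sided)."""
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs n >= 2")
    res = sps.ttest_ind(x, y, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the validation analysis."""

    alpha: float = 0.05
    n_tests: int = 4
    aesthetic_window: float = 2.0  # mm
    target_angle: float = 170.0  # deg
    bonferroni_mode: str = "paper"  # "paper" | "exact"
    distance_mode: str = "perpendicular"  # | "horizontal"
    qc_threshold: float = 3.0  # mm

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ParameterError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_tests < 1:
            raise ParameterError("n_tests must be >= 1")
        if self.bonferroni_mode not in ("paper", "exact"):
            raise ParameterError(f"unknown bonferroni mode {self.bonferroni_mode!r}")


def bonferroni_threshold(config: AnalysisConfig) -> float:
    """Decision threshold for the multiple-comparison correction.

    "exact" divides alpha by the number of tests.  "paper" reproduces the
    published decision rule, which states the 0.05/4 correction as a
    p < 0.01 threshold; for any other (alpha, n_tests) it falls back to
    the exact division.
    """
    if config.bonferroni_mode == "paper" and (
        config.alpha == 0.05 and config.n_tests == 4
    ):
        return 0.01
    return config.alpha / config.n_tests


@dataclass
class CohortResults:
    """Assembled output tables of one validation run."""

    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    table5: pd.DataFrame
    correlations: pd.DataFrame
    normality: pd.DataFrame
    measurements: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _paired_from_wide(wide: pd.DataFrame, tp: str, col_a: str, col_b: str) -> PairedSeries:
    sub = wide[wide["timepoint"] == tp].sort_values("subject_id")
    return PairedSeries(
        labels=tuple(sub["subject_id"]),
        a=sub[col_a].to_numpy(),
        b=sub[col_b].to_numpy(),
    )


def run_validation(cohort: Cohort, config: AnalysisConfig | None = None) -> CohortResults:
    """Run the full measurement + statistics pipeline on a cohort.

    Records failing the chin-deviation QC are excluded (whole subject)
    and logged; subjects must then be paired across T0/T1.
    """
    config = config or AnalysisConfig()

    qc_rows = []
    failing_subjects = set()
    for rec in cohort.records:
        qc = chin_deviation_qc(rec, threshold=config.qc_threshold)
        qc_rows.append(
            {
                "subject_id": rec.subject_id,
                "timepoint": rec.timepoint,
                "deviation_mm": qc.deviation_mm,
                "passed": qc.passed,
            }
        )
        if not qc.passed:
            failing_subjects.add(rec.subject_id)
            logger.warning(
                "excluding subject %s: chin deviation %.2f mm > %.1f mm",
                rec.subject_id,
                qc.deviation_mm,
                config.qc_threshold,
            )
    kept = [s for s in cohort.subject_ids() if s not in failing_subjects]
    filtered = cohort.subset(kept)
    if len(filtered) == 0:
        raise ValidationError("no paired subjects: cohort is empty after QC")
    unpaired = filtered.unpaired_subject_ids()
    if unpaired:
        raise ValidationError(
            "unpaired subjects (missing T0 or T1): " + ", ".join(sorted(unpaired))
        )

    wide = measure_cohort(
        filtered, target_angle=config.target_angle, mode=config.distance_mode
    )
    if wide.empty:
        raise ValidationError("no paired subjects")

    # ---- Table 2: ACP vs MCP lip positions per timepoint ------------------
    t2_rows = []
    for tp in ("T0", "T1"):
        for var in LIP_VARIABLES:
            series = _paired_from_wide(wide, tp, f"{var}_acp", f"{var}_mcp")
            da, db = descriptive(series.a), descriptive(series.b)
            test = paired_t(series)
            t2_rows.append(
                {
                    "timepoint": tp,
                    "variable": var,
                    "n": series.n,
                    "acp_mean": da.mean,
                    "acp_sd": da.sd,
                    "acp_ci95_low": da.ci95_low,
                    "acp_ci95_high": da.ci95_high,
                    "mcp_mean": db.mean,
                    "mcp_sd": db.sd,
                    "mcp_ci95_low": db.ci95_low,
                    "mcp_ci95_high": db.ci95_high,
                    "t": test.t,
                    "df": test.df,
                    "p": test.p,
                }
            )
    table2 = pd.DataFrame(t2_rows)

    # ---- Table 3: |x| at T0 vs T1 -----------------------------------------
    x_series = _paired_from_wide(
        pd.concat(
            [
                wide[wide["timepoint"] == "T0"][["subject_id", "x_abs_mm"]]
                .rename(columns={"x_abs_mm": "a"})
                .set_index("subject_id"),
                wide[wide["timepoint"] == "T1"][["subject_id", "x_abs_mm"]]
                .rename(columns={"x_abs_mm": "b"})
                .set_index("subject_id"),
            ],
            axis=1,
        )
        .reset_index()
        .assign(timepoint="both"),
        "both",
        "a",
        "b",
    )
    wtest = wilcoxon_signed_rank(x_series)
    t3_rows = []
    for tp, vals in (("T0", x_series.a), ("T1", x_series.b)):
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        d = descriptive(vals)
        t3_rows.append(
            {
                "timepoint": tp,
                "n": vals.size,
                "mean": d.mean,
                "sd": d.sd,
                "median": float(med),
                "iqr25": float(q25),
                "iqr75": float(q75),
                "wilcoxon_w": wtest.w,
                "wilcoxon_p": wtest.p,
                "wilcoxon_method": wtest.method,
            }
        )
    table3 = pd.DataFrame(t3_rows)

    # ---- Table 4: validity errors at T1 ------------------------------------
    t4_rows = []
    for var in LIP_VARIABLES:
        series = _paired_from_wide(wide, "T1", f"{var}_acp", f"{var}_mcp")
        v = validity_errors(series)
        t4_rows.append({"variable": var, "n": series.n, **v.__dict__})
    table4 = pd.DataFrame(t4_rows)

    # ---- Table 5: sex-stratified T1 MCP-based positions --------------------
    t1 = wide[wide["timepoint"] == "T1"]
    t5_rows = []
    for var in LIP_VARIABLES:
        male = t1[t1["sex"] == "male"][f"{var}_mcp"].to_numpy()
        female = t1[t1["sex"] == "female"][f"{var}_mcp"].to_numpy()
        row: dict = {"variable": var, "n_male": male.size, "n_female": female.size}
        if male.size >= 2 and female.size >= 2:
            dm, df_ = descriptive(male), descriptive(female)
            welch = independent_t(male, female)
            row.update(
                male_mean=dm.mean,
                male_sd=dm.sd,
                male_ci95_low=dm.ci95_low,
                male_ci95_high=dm.ci95_high,
                female_mean=df_.mean,
                female_sd=df_.sd,
                female_ci95_low=df_.ci95_low,
                female_ci95_high=df_.ci95_high,
                t=welch.t,
                df=welch.df,
                p=welch.p,
            )
        else:
            row.update(
                male_mean=np.nan, male_sd=np.nan, male_ci95_low=np.nan,
                male_ci95_high=np.nan, female_mean=np.nan, female_sd=np.nan,
                female_ci95_low=np.nan, female_ci95_high=np.nan,
                t=np.nan, df=np.nan, p=np.nan,
            )
        t5_rows.append(row)
    table5 = pd.DataFrame(t5_rows)

    # ---- correlations -------------------------------------------------------
    corr_rows = []
    for var in LIP_VARIABLES:
        s1 = _paired_from_wide(wide, "T1", f"{var}_acp", f"{var}_mcp")
        mcp_pairs = _paired_from_wide(
            pd.concat(
                [
                    wide[wide["timepoint"] == "T0"][["subject_id", f"{var}_mcp"]]
                    .rename(columns={f"{var}_mcp": "a"})
                    .set_index("subject_id"),
                    wide[wide["timepoint"] == "T1"][["subject_id", f"{var}_mcp"]]
                    .rename(columns={f"{var}_mcp": "b"})
                    .set_index("subject_id"),
                ],
                axis=1,
            )
            .reset_index()
            .assign(timepoint="both"),
            "both",
            "a",
            "b",
        )
        r1, p1 = pearson_r(s1)
        r2, p2 = pearson_r(mcp_pairs)
        corr_rows.append(
            {
                "variable": var,
                "acp_t1_vs_mcp_t1_r": r1,
                "acp_t1_vs_mcp_t1_p": p1,
                "mcp_t0_vs_mcp_t1_r": r2,
                "mcp_t0_vs_mcp_t1_p": p2,
            }
        )
    correlations = pd.DataFrame(corr_rows)

    # ---- normality log ------------------------------------------------------
    norm_rows = []
    for tp in ("T0", "T1"):
        for var in LIP_VARIABLES:
            series = _paired_from_wide(wide, tp, f"{var}_acp", f"{var}_mcp")
            d = series.differences()
            if np.ptp(d) == 0.0:
                w_stat, p_val = np.nan, np.nan
            else:
                sw = sps.shapiro(d)
                w_stat, p_val = float(sw.statistic), float(sw.pvalue)
            norm_rows.append(
                {
                    "timepoint": tp,
                    "variable": var,
                    "shapiro_w": w_stat,
                    "shapiro_p": p_val,
                }
            )
            if np.isfinite(p_val) and p_val < 0.05:
                logger.info(
                    "Shapiro-Wilk: ACP-MCP differences for %s at %s depart "
                    "from normality (p=%.3g)", var, tp, p_val,
                )
    normality = pd.DataFrame(norm_rows)

    threshold = bonferroni_threshold(config)
    aesthetic = {}
    for var in LIP_VARIABLES:
        vals = t1[f"{var}_mcp"].to_numpy()
        aesthetic[var] = float(np.mean(np.abs(vals) <= config.aesthetic_window))
    n_subjects = len(filtered.subject_ids())
    summary = {
        "n_subjects": n_subjects,
        "n_male": int((t1["sex"] == "male").sum()),
        "n_female": int((t1["sex"] == "female").sum()),
        "qc_excluded": sorted(failing_subjects),
        "significance_threshold": threshold,
        "bonferroni_mode": config.bonferroni_mode,
        "aesthetic_window_mm": config.aesthetic_window,
        "aesthetic_within_fraction_t1_mcp": aesthetic,
        "target_angle_deg": config.target_angle,
        "distance_mode": config.distance_mode,
    }
    return CohortResults(
        table2=table2,
        table3=table3,
        table4=table4,
        table5=table5,
        correlations=correlations,
        normality=normality,
        measurements=wide,
        summary=summary,
    )
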