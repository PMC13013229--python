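"""Cohort-level statistics on marker tables.

Mirrors a pre/post treatment-response analysis workflow:

* normality-gated paired tests (Shapiro-Wilk on the paired differences at
  alpha 0.05 selects paired t vs Wilcoxon signed-rank);
* normality-gated two-sample comparisons (t vs Mann-Whitney U) and
  chi-square / Fisher's exact for categorical characteristics;
* survival association of marker *change direction* (delta >= 0 vs < 0) with
  a composite endpoint via Kaplan-Meier, log-rank and Cox models, optionally
  adjusted for age, sex, treatment type and changes in troponin T, NT-proBNP,
  6-minute walk distance and NYHA class;
* inter-rater agreement via the single-rater, absolute-agreement, two-way
  random-effects intraclass correlation coefficient, ICC(2,1).

No multiple-testing correction is applied anywhere; all p values are
unadjusted and exploratory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConvergenceError,
    DegenerateVarianceError,
    InsufficientDataError,
    NoEventsError,
)
from .markers import MARKER_NAMES

__all__ = [
    "CohortTable",
    "PairedTestResult",
    "GroupComparison",
    "SurvivalResult",
    "ICCResult",
    "ADJUSTMENT_COVARIATES",
    "paired_change_test",
    "compare_groups",
    "categorical_test",
    "survival_association",
    "icc_agreement",
    "marker_change_table",
]

NORMALITY_ALPHA = 0.05

#: Covariates of the adjusted Cox model (treatment is dummy-coded,
#: tafamidis as reference).
ADJUSTMENT_COVARIATES: Tuple[str, ...] = (
    "age",
    "sex",
    "treatment",
    "delta_troponin",
    "delta_ntprobnp",
    "delta_sixmwd",
    "delta_nyha",
)

_CLINICAL_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "treatment",
    "nyha_pre",
    "nyha_post",
    "ntprobnp_pre",
    "ntprobnp_post",
    "troponin_pre",
    "troponin_post",
    "sixmwd_pre",
    "sixmwd_post",
    "time_months",
    "event",
)


@dataclass
class CohortTable:
    """Per-patient pre/post marker panels plus clinical covariates and outcomes.

    ``data`` holds one row per patient with columns ``pre_<marker>`` and
    ``post_<marker>`` for each of the 26 canonical markers, the clinical
    columns of :data:`_CLINICAL_COLUMNS`, and outcome (``time_months``,
    ``event``).  Missing values are permitted (NaN) except in id/time/event.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing_cols = [c for c in _CLINICAL_COLUMNS if c not in df.columns]
        for m in MARKER_NAMES:
            missing_cols += [c for c in (f"pre_{m}", f"post_{m}") if c not in df.columns]
        if missing_cols:
            raise ValueError(f"cohort table missing columns: {missing_cols[:6]} ...")
        if (df["time_months"] < 0).any():
            raise ValueError("negative follow-up times")
        for col in ("nyha_pre", "nyha_post"):
            vals = df[col].dropna()
            if not vals.isin([1, 2, 3, 4]).all():
                raise ValueError(f"{col} outside NYHA classes 1-4")

    def __len__(self) -> int:
        return len(self.data)

    def pre(self, marker: str) -> pd.Series:
        return self.data[f"pre_{marker}"]

    def post(self, marker: str) -> pd.Series:
        return self.data[f"post_{marker}"]

    def delta(self, marker: str) -> pd.Series:
        """Post-minus-pre change; NaN where either side is missing."""
        return self.post(marker) - self.pre(marker)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# paired pre/post tests
# ---------------------------------------------------------------------------


@dataclass
class PairedTestResult:
    marker: str
    test_used: str  # "paired_t" | "wilcoxon_signed_rank" | "degenerate" | "error"
    p_value: float
    n_pairs: int
    n_dropped: int
    pre_median: float
    pre_iqr: Tuple[float, float]
    post_median: float
    post_iqr: Tuple[float, float]
    degenerate: bool = False
    error: Optional[str] = None

    @property
    def median_difference(self) -> float:
        """Pre-minus-post median difference (positive = reduction)."""
        return self.pre_median - self.post_median


def _shapiro_normal(x: np.ndarray, alpha: float = NORMALITY_ALPHA) -> bool:
    """Shapiro-Wilk gate: True when normality is NOT rejected at alpha."""
    if len(x) < 3 or np.ptp(x) == 0:
        return False  # too few / constant: take the non-parametric path
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(x).pvalue > alpha


def paired_change_test(
    pre: Sequence[float], post: Sequence[float], marker: str = ""
) -> PairedTestResult:
    """Normality-gated paired pre/post comparison.

    Shapiro-Wilk on the paired differences (alpha 0.05) selects a paired t
    test (normal) or Wilcoxon signed-rank (otherwise; zero differences are
    dropped per the classical convention, with an exact null for small
    samples).  Incomplete pairs are dropped and counted.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    ok = np.isfinite(pre) & np.isfinite(post)
    n_dropped = int((~ok).sum())
    pre, post = pre[ok], post[ok]
    if len(pre) < 2:
        raise InsufficientDataError(f"{marker or 'paired test'}: fewer than 2 complete pairs")

    def _med_iqr(x):
        return float(np.median(x)), (float(np.percentile(x, 25)), float(np.percentile(x, 75)))

    pre_med, pre_iqr = _med_iqr(pre)
    post_med, post_iqr = _med_iqr(post)
    diffs = post - pre

    if np.all(diffs == 0):
        return PairedTestResult(
            marker, "degenerate", 1.0, len(pre), n_dropped,
            pre_med, pre_iqr, post_med, post_iqr, degenerate=True,
        )

    if _shapiro_normal(diffs):
        p = float(stats.ttest_rel(post, pre).pvalue)
        test = "paired_t"
    else:
        nz = diffs[diffs != 0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(
                stats.wilcoxon(nz, zero_method="wilcox", correction=True, method="auto").pvalue
            )
        test = "wilcoxon_signed_rank"
    return PairedTestResult(
        marker, test, p, len(pre), n_dropped, pre_med, pre_iqr, post_med, post_iqr
    )


# ---------------------------------------------------------------------------
# independent-group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    test_used: str  # "t_test" | "mann_whitney" | "chi_square" | "fisher_exact"
    p_value: float
    n_a: int
    n_b: int


def categorical_test(table: np.ndarray) -> GroupComparison:
    """Chi-square test on a contingency table, or Fisher's exact (2x2) when
    any expected cell count is below 5."""
    table = np.asarray(table, dtype=float)
    totals = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / totals
    if table.shape == (2, 2) and (expected < 5).any():
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        return GroupComparison("fisher_exact", p, int(table[0].sum()), int(table[1].sum()))
    p = float(stats.chi2_contingency(table, correction=False).pvalue)
    return GroupComparison("chi_square", p, int(table[0].sum()), int(table[1].sum()))


def compare_groups(values_a, values_b, kind: str = "continuous") -> GroupComparison:
    """Two-sided comparison of two independent groups.

    Continuous: Shapiro-Wilk gate on each group (alpha 0.05) picks an
    independent-samples t test (both normal) or Mann-Whitney U.  Categorical:
    group labels are cross-tabulated and tested by chi-square, or Fisher's
    exact for sparse 2x2 tables (any expected count < 5).
    """
    if kind == "categorical":
        a = pd.Series(list(values_a))
        b = pd.Series(list(values_b))
        cats = sorted(set(a.dropna()) | set(b.dropna()))
        table = np.array(
            [[int((g == c).sum()) for c in cats] for g in (a.dropna(), b.dropna())], dtype=float
        )
        return categorical_test(table)
    if kind != "continuous":
        raise ValueError(f"kind must be 'continuous' or 'categorical', got {kind!r}")

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs >= 2 observations")
    if _shapiro_normal(a) and _shapiro_normal(b):
        p = float(stats.ttest_ind(a, b).pvalue)
        return GroupComparison("t_test", p, len(a), len(b))
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return GroupComparison("mann_whitney", p, len(a), len(b))


# ---------------------------------------------------------------------------
# survival association of marker change direction
# ---------------------------------------------------------------------------


@dataclass
class SurvivalResult:
    marker: str
    n_used: int
    n_increase: int  # delta >= 0 stratum ("not reduced")
    n_decrease: int
    n_events: int
    univariate_hr: float
    univariate_ci: Tuple[float, float]
    logrank_p: float
    univariate_cox_p: float
    adjusted_hr: Optional[float] = None
    adjusted_ci: Optional[Tuple[float, float]] = None
    adjusted_p: Optional[float] = None
    n_complete_case: Optional[int] = None
    km_curves: Dict[str, pd.DataFrame] = field(default_factory=dict)


def _adjustment_frame(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Design matrix for the adjusted Cox model (treatment dummy-coded,
    tafamidis reference; sex coded male=1)."""
    out = pd.DataFrame(index=df.index)
    for cov in covariates:
        if cov == "sex":
            out["sex_male"] = (df["sex"].astype(str).str.upper().str.startswith("M")).astype(float)
        elif cov == "treatment":
            t = df["treatment"].astype(str).str.lower()
            out["treatment_patisiran"] = (t == "patisiran").astype(float)
            out["treatment_inotersen"] = (t == "inotersen").astype(float)
        elif cov == "delta_troponin":
            out["delta_troponin"] = df["troponin_post"] - df["troponin_pre"]
        elif cov == "delta_ntprobnp":
            out["delta_ntprobnp"] = df["ntprobnp_post"] - df["ntprobnp_pre"]
        elif cov == "delta_sixmwd":
            out["delta_sixmwd"] = df["sixmwd_post"] - df["sixmwd_pre"]
        elif cov == "delta_nyha":
            out["delta_nyha"] = df["nyha_post"] - df["nyha_pre"]
        else:
            out[cov] = df[cov].astype(float)
    # z-scale continuous covariates for conditioning; the hazard ratio of the
    # change-direction indicator is invariant to covariate scaling
    for col in out.columns:
        if not col.startswith(("sex_", "treatment_")):
            sd = out[col].std(ddof=0)
            if np.isfinite(sd) and sd > 0:
                out[col] = (out[col] - out[col].mean()) / sd
    return out


def survival_association(
    cohort: CohortTable,
    marker: str,
    covariates: Sequence[str] = ADJUSTMENT_COVARIATES,
) -> SurvivalResult:
    """Association of a marker's change direction with the composite endpoint.

    Patients are stratified by whether the marker increased (delta >= 0, the
    "not reduced" stratum) or decreased after treatment.  Returns
    Kaplan-Meier curves per stratum, the log-rank p, the univariate Cox
    hazard ratio (increase vs decrease) and, when ``covariates`` is
    non-empty, the adjusted hazard ratio on complete cases.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter
    from lifelines.statistics import logrank_test
    import lifelines.exceptions

    df = cohort.data
    delta = cohort.delta(marker)
    ok = delta.notna() & df["time_months"].notna() & df["event"].notna()
    d = df[ok].copy()
    d["increase"] = (delta[ok] >= 0).astype(int)
    n_events = int(d["event"].sum())
    if n_events == 0:
        raise NoEventsError(f"{marker}: no events observed")
    inc, dec = d[d["increase"] == 1], d[d["increase"] == 0]
    if len(inc) == 0 or len(dec) == 0:
        raise InsufficientDataError(f"{marker}: one change-direction stratum is empty")
    if inc["event"].sum() == 0 and dec["event"].sum() == 0:
        raise NoEventsError(f"{marker}: no events in either stratum")

    lr = logrank_test(
        inc["time_months"], dec["time_months"], inc["event"], dec["event"]
    )

    km: Dict[str, pd.DataFrame] = {}
    for label, grp in (("increase", inc), ("decrease", dec)):
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time_months"], grp["event"], label=label)
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time_months", "survival"]
        km[label] = sf

    def _fit_cox(frame: pd.DataFrame, context: str):
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(frame, duration_col="time_months", event_col="event")
        except (lifelines.exceptions.ConvergenceError, np.linalg.LinAlgError) as exc:
            raise ConvergenceError(f"{marker}: {context} Cox fit failed: {exc}") from exc
        return cph

    uni = _fit_cox(d[["time_months", "event", "increase"]], "univariate")
    with np.errstate(over="ignore"):
        hr = float(np.exp(uni.params_["increase"]))
        ci = tuple(np.exp(uni.confidence_intervals_.loc["increase"]).tolist())
    uni_p = float(uni.summary.loc["increase", "p"])

    result = SurvivalResult(
        marker=marker,
        n_used=len(d),
        n_increase=len(inc),
        n_decrease=len(dec),
        n_events=n_events,
        univariate_hr=hr,
        univariate_ci=(float(ci[0]), float(ci[1])),
        logrank_p=float(lr.p_value),
        univariate_cox_p=uni_p,
        km_curves=km,
    )

    if covariates:
        adj = _adjustment_frame(d, covariates)
        frame = pd.concat(
            [d[["time_months", "event", "increase"]], adj], axis=1
        ).dropna()
        result.n_complete_case = len(frame)
        if frame["event"].sum() > 0 and len(frame) >= frame.shape[1]:
            cph = _fit_cox(frame, "adjusted")
            with np.errstate(over="ignore"):
                result.adjusted_hr = float(np.exp(cph.params_["increase"]))
                aci = np.exp(cph.confidence_intervals_.loc["increase"])
            result.adjusted_ci = (float(aci.iloc[0]), float(aci.iloc[1]))
            result.adjusted_p = float(cph.summary.loc["increase", "p"])
    return result


# ---------------------------------------------------------------------------
# inter-rater agreement
# ---------------------------------------------------------------------------


@dataclass
class ICCResult:
    icc: float
    p_value: float
    f_statistic: float
    df1: int
    df2: int
    n_subjects: int
    n_raters: int


def icc_agreement(readings) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``readings`` is a subjects x raters matrix with no missing cells.
    Computed from the classical two-way ANOVA mean squares:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with the F test of MSR/MSE reported (df n-1, (n-1)(k-1)).
    """
    x = np.asarray(readings, dtype=float)
    if x.ndim != 2:
        raise ValueError("readings must be a 2-D subjects x raters matrix")
    n, k = x.shape
    if k < 2 or n < 3:
        raise InsufficientDataError("need >= 2 raters and >= 3 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("readings contain missing/non-finite cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    if msr <= 1e-12 * max(1.0, grand**2):
        raise DegenerateVarianceError("zero between-subject variance; ICC undefined")

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = float((msr - mse) / denom)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse == 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = float(msr / mse)
        p = float(stats.f.sf(f_stat, df1, df2))
    return ICCResult(icc, p, f_stat, df1, df2, n, k)


# ---------------------------------------------------------------------------
# marker change table
# ---------------------------------------------------------------------------


def marker_change_table(cohort: CohortTable) -> List[PairedTestResult]:
    """Paired pre/post test for all 26 markers, sorted by ascending p value
    (most to least significant; ties broken by marker name, failed markers
    flagged and listed last)."""
    rows: List[PairedTestResult] = []
    for m in MARKER_NAMES:
        try:
            rows.append(paired_change_test(cohort.pre(m), cohort.post(m), marker=m))
        except Exception as exc:
            rows.append(
                PairedTestResult(
                    m, "error", float("nan"), 0, len(cohort), float("nan"),
                    (float("nan"), float("nan")), float("nan"),
                    (float("nan"), float("nan")), error=str(exc),
                )
            )
    ok = sorted((r for r in rows if r.error is None), key=lambda r: (r.p_value, r.marker))
    bad = sorted((r for r in rows if r.error is not None), key=lambda r: r.marker)
    return ok + bad
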