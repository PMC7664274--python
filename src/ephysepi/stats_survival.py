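"""Group inference and survival analysis.

Comparisons follow the study's statistical recipe: an F-test on the
group variances gates the choice between Student's and Welch's unpaired
two-tailed t-test, D'Agostino-Pearson omnibus normality is reported per
group, and the family of comparisons in a results table is corrected
with the Benjamini-Krieger-Yekutieli (BKY) two-stage step-up procedure
at a 5% false discovery rate.  Survival cohorts are summarized with the
Kaplan-Meier product-limit estimator and compared with the unweighted
(Mantel-Cox) log-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult", "SurvivalRecord",
    "compare_groups", "bky_fdr", "km_estimate", "logrank",
    "build_results_table", "significance_stars",
]


@dataclass(frozen=True)
class SurvivalRecord:
    subject_id: str
    group: str
    day: int
    event: bool  # True = death, False = censored

    def __post_init__(self):
        if self.day < 0:
            raise ValueError("day must be non-negative")


@dataclass
class ComparisonResult:
    metric: str
    group_a: str
    group_b: str
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    n_a: int
    n_b: int
    test_used: str  # "student" | "welch"
    t_statistic: float
    p_value: float
    f_test_p: float
    normality_p_a: float
    normality_p_b: float
    bky_significant: bool | None = None


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(x.size))


def _normality_p(x: np.ndarray) -> float:
    # the omnibus test needs n >= 8; report NaN below that
    if x.size < 8:
        return float("nan")
    return float(sps.normaltest(x).pvalue)


def compare_groups(
    a,
    b,
    metric: str = "",
    group_a: str = "a",
    group_b: str = "b",
    force_test: str | None = None,
    welch_gate_p: float = 0.05,
) -> ComparisonResult:
    """Two-group comparison with the variance-gated t-test.

    An F-test (two-sided) compares variances; Welch's correction is used
    when its p < ``welch_gate_p``, Student's t otherwise.  ``force_test``
    overrides the gate ("student" or "welch").
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need n >= 3 per group")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both groups")

    if vb == 0 or va == 0:
        f_p = 0.0
    else:
        f = va / vb
        p_one = sps.f.sf(f, a.size - 1, b.size - 1)
        f_p = float(2 * min(p_one, 1 - p_one))
    if force_test is not None:
        test = force_test
    else:
        test = "welch" if f_p < welch_gate_p else "student"
    res = sps.ttest_ind(a, b, equal_var=(test == "student"))
    return ComparisonResult(
        metric=metric, group_a=group_a, group_b=group_b,
        mean_a=float(a.mean()), sem_a=_sem(a),
        mean_b=float(b.mean()), sem_b=_sem(b),
        n_a=int(a.size), n_b=int(b.size),
        test_used=test,
        t_statistic=float(res.statistic), p_value=float(res.pvalue),
        f_test_p=f_p,
        normality_p_a=_normality_p(a), normality_p_b=_normality_p(b),
    )


def _step_up(p_sorted: np.ndarray, level: float) -> int:
    """Number of rejections of the linear (BH) step-up at ``level``."""
    m = p_sorted.size
    crit = level * np.arange(1, m + 1) / m
    hits = np.where(p_sorted <= crit)[0]
    return int(hits[-1] + 1) if hits.size else 0


def bky_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Krieger-Yekutieli two-stage step-up significance flags.

    Stage 1 runs the linear step-up at q' = q/(1+q) to estimate the
    number of true nulls m0 = m - r1; stage 2 re-runs the step-up at
    level q' m / m0.  Returns booleans in input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    q1 = q / (1.0 + q)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    r1 = _step_up(ps, q1)
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    m0 = m - r1
    r2 = _step_up(ps, q1 * m / m0)
    flags = np.zeros(m, dtype=bool)
    flags[order[:r2]] = True
    return flags


# --- survival --------------------------------------------------------------

def km_estimate(records, group: str | None = None):
    """Kaplan-Meier product-limit curve and median survival day.

    The median is the first day at which the survival probability drops
    to <= 0.5; it is None when survival never reaches 0.5 (e.g. no
    deaths).  Returns ``(curve, median)`` where ``curve`` is a DataFrame
    with columns day / survival / at_risk / deaths.
    """
    from lifelines import KaplanMeierFitter

    recs = [r for r in records if group is None or r.group == group]
    if not recs:
        raise ValueError(f"no records for group {group!r}")
    days = np.array([r.day for r in recs])
    events = np.array([r.event for r in recs], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(days, events)
    surv = kmf.survival_function_.iloc[:, 0]
    curve = pd.DataFrame({
        "day": surv.index.to_numpy(dtype=float),
        "survival": surv.to_numpy(),
        "at_risk": kmf.event_table["at_risk"].reindex(surv.index).to_numpy(),
        "deaths": kmf.event_table["observed"].reindex(surv.index).to_numpy(),
    })
    # first day at which survival drops to <= 0.5 (tolerant of the
    # product-limit rounding, e.g. 5/6 * 3/5 = 0.5 + 1e-16)
    hit = curve[curve["survival"] <= 0.5 + 1e-9]
    median = float(hit["day"].iloc[0]) if len(hit) else None
    return curve, median


def logrank(records):
    """Unweighted (Mantel-Cox) log-rank test between exactly two groups.

    Returns ``(chi_square, p_value)`` with 1 degree of freedom.
    """
    from lifelines.statistics import logrank_test

    groups = sorted({r.group for r in records})
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(groups)}")
    if not any(r.event for r in records):
        raise ValueError("log-rank needs at least one event")
    a = [r for r in records if r.group == groups[0]]
    b = [r for r in records if r.group == groups[1]]
    res = logrank_test(
        [r.day for r in a], [r.day for r in b],
        event_observed_A=[r.event for r in a],
        event_observed_B=[r.event for r in b],
    )
    return float(res.test_statistic), float(res.p_value)


# --- reporting -------------------------------------------------------------

#: Star thresholds used in the study's tables.
STAR_LEVELS = ((0.0001, "****"), (0.005, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float, significant: bool = True) -> str:
    if not significant or not np.isfinite(p):
        return ""
    for thresh, stars in STAR_LEVELS:
        if p < thresh:
            return stars
    return ""


def build_results_table(comparisons, q: float = 0.05) -> pd.DataFrame:
    """Publication-style table: mean +/- SEM per group, test marker, and
    significance stars gated by the BKY flags (the FDR family is the set
    of comparisons passed in)."""
    comparisons = list(comparisons)
    if not comparisons:
        raise ValueError("no comparisons to tabulate")
    flags = bky_fdr([c.p_value for c in comparisons], q=q)
    rows = []
    for c, flag in zip(comparisons, flags):
        c.bky_significant = bool(flag)
        rows.append({
            "metric": c.metric,
            c.group_a: f"{c.mean_a:.2f} ± {c.sem_a:.2f}",
            c.group_b: f"{c.mean_b:.2f} ± {c.sem_b:.2f}",
            "n": f"{c.n_a}/{c.n_b}",
            "test": "Welch" if c.test_used == "welch" else "Student",
            "t": round(c.t_statistic, 3),
            "p": c.p_value,
            "q<=0.05": bool(flag),
            "stars": significance_stars(c.p_value, bool(flag)),
        })
    return pd.DataFrame(rows)
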