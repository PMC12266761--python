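"""Cohort statistics: Mann–Whitney (pooled and per-patient modes), one-way
ANOVA with Tukey/Dunnett post hoc, and two-stage adaptive FDR control.

The study design this serves plots per-patient means but computes
significance on pooled organelles; both inference modes are first-class
here so pseudoreplication sensitivity is always visible. Tests are
two-sided throughout.

The two-stage step-up FDR procedure (Benjamini–Krieger–Yekutieli) runs a
linear step-up at q' = q/(1+q) to estimate the number of true nulls
m0 = m − r1, then reruns the step-up at q'·m/m0; its discoveries always
contain the plain Benjamini–Hochberg discoveries at the same q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: p-value thresholds for the figure-legend star convention.
STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))

#: largest min-group size at which the exact Mann–Whitney null is enumerated
EXACT_MAX_N = 8


def significance_stars(p: float) -> str:
    """Map a p-value to the *, **, ***, **** convention (else 'ns')."""
    if not (0 <= p <= 1):
        raise ValueError(f"p-value {p} outside [0, 1]")
    for thresh, stars in STAR_THRESHOLDS:
        if p <= thresh:
            return stars
    return "ns"


@dataclass
class ComparisonResult:
    metric: str
    mode: str  # "pooled" | "per_patient"
    n1: int
    n2: int
    U: float
    p_value: float
    direction: str  # "greater" | "less" | "none" — sign of median(y) - median(x)
    stars: str
    method: str  # "exact" | "asymptotic"
    degenerate: bool = False


def mann_whitney(x, y, metric: str = "", mode: str = "pooled") -> ComparisonResult:
    """Two-sided Mann–Whitney U comparison of two samples.

    Exact null enumeration when min(n1, n2) <= 8 and there are no ties
    across the pooled sample; otherwise the normal approximation with
    tie-corrected variance and 0.5 continuity correction. ``U`` is the
    statistic of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return ComparisonResult(metric, mode, x.size, y.size,
                                U=x.size * y.size / 2.0, p_value=1.0,
                                direction="none", stars="ns",
                                method="degenerate", degenerate=True)
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = min(x.size, y.size) <= EXACT_MAX_N and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if use_exact else "asymptotic",
                           use_continuity=True)
    med_diff = float(np.median(y) - np.median(x))
    direction = "greater" if med_diff > 0 else ("less" if med_diff < 0 else "none")
    p = float(min(res.pvalue, 1.0))
    return ComparisonResult(metric, mode, int(x.size), int(y.size),
                            U=float(res.statistic), p_value=p,
                            direction=direction, stars=significance_stars(p),
                            method=method)


# ---------------------------------------------------------------------------
# ANOVA + post hoc
# ---------------------------------------------------------------------------

@dataclass
class PosthocResult:
    F: float
    p_omnibus: float
    comparisons: pd.DataFrame  # columns: group_a, group_b, statistic, p_adj, stars


def anova_posthoc(groups: dict[str, np.ndarray], posthoc: str = "tukey",
                  control: str | None = None) -> PosthocResult:
    """One-way ANOVA with Tukey HSD or Dunnett multiple-comparison post hoc.

    ``posthoc="dunnett"`` compares every group against the named ``control``
    (adjusted p-values from the multivariate-t Dunnett distribution);
    ``"tukey"`` compares all pairs via the studentized range.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for n, a in zip(names, arrays):
        if a.size < 2:
            raise ValueError(f"group {n!r} has fewer than 2 observations")
    F, p_omnibus = sps.f_oneway(*arrays)
    rows = []
    if posthoc == "tukey":
        res = sps.tukey_hsd(*arrays)
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                p = float(res.pvalue[i, j])
                rows.append({"group_a": names[i], "group_b": names[j],
                             "statistic": float(res.statistic[i, j]),
                             "p_adj": p, "stars": significance_stars(p)})
    elif posthoc == "dunnett":
        if control is None or control not in groups:
            raise ValueError("Dunnett post hoc requires a named control group")
        treat_names = [n for n in names if n != control]
        # the Dunnett distribution is integrated by randomized QMC inside
        # scipy; fix its stream so repeated runs give identical adjusted p
        res = sps.dunnett(*[np.asarray(groups[n], float) for n in treat_names],
                          control=np.asarray(groups[control], float),
                          rng=np.random.default_rng(0))
        for name, stat, p in zip(treat_names, np.atleast_1d(res.statistic),
                                 np.atleast_1d(res.pvalue)):
            p = float(p)
            rows.append({"group_a": control, "group_b": name,
                         "statistic": float(stat),
                         "p_adj": p, "stars": significance_stars(p)})
    else:
        raise ValueError("posthoc must be 'tukey' or 'dunnett'")
    return PosthocResult(float(F), float(p_omnibus),
                         pd.DataFrame(rows, columns=["group_a", "group_b",
                                                     "statistic", "p_adj", "stars"]))


# ---------------------------------------------------------------------------
# FDR procedures
# ---------------------------------------------------------------------------

def _step_up(p: np.ndarray, level: float) -> np.ndarray:
    """Benjamini–Hochberg linear step-up at ``level``: boolean rejections."""
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    crit = level * np.arange(1, m + 1) / m
    below = np.nonzero(sorted_p <= crit)[0]
    rejected = np.zeros(m, dtype=bool)
    if below.size:
        rejected[order[: below[-1] + 1]] = True
    return rejected


def benjamini_hochberg(p_values, q: float = 0.05) -> np.ndarray:
    """Plain BH step-up; boolean discovery flags in input order."""
    p = _validated_p(p_values)
    return _step_up(p, q)


@dataclass
class FdrPanelResult:
    p_values: np.ndarray
    q: float
    rejected: np.ndarray  # boolean discovery flags, input order
    m0_hat: int  # estimated number of true nulls
    n_discoveries: int


def _validated_p(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1D array")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bky_two_stage(p_values, q: float = 0.05) -> FdrPanelResult:
    """Two-stage adaptive step-up FDR control (Benjamini–Krieger–Yekutieli).

    Stage 1: linear step-up at q' = q/(1+q), giving r1 rejections and the
    null-count estimate m0 = m − r1. If r1 = 0 nothing is rejected; if
    r1 = m everything is. Stage 2: linear step-up at q'·m/m0; its
    rejections are the discoveries.
    """
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    p = _validated_p(p_values)
    m = p.size
    q_prime = q / (1.0 + q)
    stage1 = _step_up(p, q_prime)
    r1 = int(stage1.sum())
    if r1 == 0:
        rejected = np.zeros(m, dtype=bool)
    elif r1 == m:
        rejected = np.ones(m, dtype=bool)
    else:
        m0 = m - r1
        rejected = _step_up(p, q_prime * m / m0)
    return FdrPanelResult(p, float(q), rejected, m0_hat=m - r1,
                          n_discoveries=int(rejected.sum()))


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

def standard_error(values) -> float:
    """SEM with sample (ddof=1) standard deviation."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        return float("nan")
    return float(v.std(ddof=1) / np.sqrt(v.size))


def summarize_cohorts(
    table: pd.DataFrame,
    metrics: list[str],
    group_col: str = "group",
    patient_col: str = "patient_id",
    groups: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Figure-style two-group report: mean ± SEM per group plus both
    inference modes' Mann–Whitney p-values and stars, one row per metric
    per mode.

    Pooled mode treats every organelle as an observation; per-patient mode
    tests the per-patient metric means (dots in the figures). A group with
    a single patient is reported with an insufficient-replication flag.
    """
    if group_col not in table.columns or patient_col not in table.columns:
        raise ValueError("table needs group and patient columns")
    if groups is None:
        groups = tuple(pd.unique(table[group_col]))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    g1, g2 = groups
    rows = []
    for metric in metrics:
        if metric not in table.columns or table[metric].dropna().empty:
            rows.append({"metric": metric, "mode": "skipped",
                         "flag": "empty metric column"})
            continue
        x_all = table.loc[table[group_col] == g1, metric].dropna().to_numpy()
        y_all = table.loc[table[group_col] == g2, metric].dropna().to_numpy()
        x_pp = table[table[group_col] == g1].groupby(patient_col)[metric].mean().to_numpy()
        y_pp = table[table[group_col] == g2].groupby(patient_col)[metric].mean().to_numpy()
        for mode, (x, y) in (("pooled", (x_all, y_all)),
                             ("per_patient", (x_pp, y_pp))):
            cmp = mann_whitney(x, y, metric=metric, mode=mode)
            flag = ""
            if mode == "per_patient" and min(x.size, y.size) < 2:
                flag = "insufficient replication"
            rows.append(
                {
                    "metric": metric,
                    "mode": mode,
                    f"mean_{g1}": float(np.mean(x)),
                    f"sem_{g1}": standard_error(x),
                    f"mean_{g2}": float(np.mean(y)),
                    f"sem_{g2}": standard_error(y),
                    "n1": cmp.n1,
                    "n2": cmp.n2,
                    "U": cmp.U,
                    "p_value": cmp.p_value,
                    "stars": cmp.stars,
                    "direction": cmp.direction,
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows)
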