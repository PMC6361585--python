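"""Cross-neuron statistics: response-magnitude correlations, proportion
contrasts, group time-course tests, and the normality gate.

These mirror the population-level analyses of the recording study:
Pearson correlations of per-unit response magnitudes between stimuli,
chi-square contrasts of response-category proportions between groups,
repeated-measures ANOVA with Holm-Sidak-corrected window-vs-baseline
comparisons for sustained time courses, and a D'Agostino-Pearson
normality gate that substitutes mid-ranks when data are non-normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    x_label: str
    y_label: str
    n: int
    r_squared: float
    p: float
    slope: float
    intercept: float


@dataclass(frozen=True)
class ProportionTable:
    counts: np.ndarray             # groups x categories
    expected: np.ndarray
    chi_square: float
    p: float
    dof: int


def correlate_responses(x, y, x_label: str = "x", y_label: str = "y",
                        subset=None) -> CorrelationResult:
    """Pearson correlation with fitted least-squares line.

    ``subset`` is an optional boolean mask restricting the paired
    magnitudes (e.g. to units significantly excited by footshock).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired per unit")
    if subset is not None:
        subset = np.asarray(subset, dtype=bool)
        x, y = x[subset], y[subset]
    if x.size < 3:
        raise ValueError("need at least 3 paired magnitudes")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("zero variance in correlated magnitudes")
    res = stats.linregress(x, y)
    return CorrelationResult(x_label=x_label, y_label=y_label, n=int(x.size),
                             r_squared=float(res.rvalue ** 2),
                             p=float(res.pvalue), slope=float(res.slope),
                             intercept=float(res.intercept))


def compare_proportions(counts) -> ProportionTable:
    """Chi-square test of independence, no continuity correction."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need a groups x categories table, >= 2 each")
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty table")
    expected = row @ col / total
    if np.any(expected == 0.0):
        raise ValueError("zero expected count; collapse categories first")
    if np.array_equal(counts / row, np.broadcast_to((counts / row)[0],
                                                    counts.shape)):
        # identical group proportions: statistic exactly 0
        dof = (counts.shape[0] - 1) * (counts.shape[1] - 1)
        return ProportionTable(counts, expected, 0.0, 1.0, dof)
    chi2, p, dof, expected = stats.chi2_contingency(counts, correction=False)
    return ProportionTable(counts, expected, float(chi2), float(p), int(dof))


def group_time_course_test(values: pd.DataFrame,
                           baseline: str = "baseline",
                           gate_normality: bool = True,
                           alpha: float = ALPHA) -> dict:
    """Repeated-measures one-way ANOVA across time windows, with
    Holm-Sidak-adjusted pairwise comparisons of each window vs baseline.

    ``values`` has one row per unit and one column per window (including
    the baseline column). If the pooled values fail the D'Agostino-
    Pearson normality test the whole matrix is mid-rank transformed
    before testing (the rank gate used throughout the study).
    """
    from statsmodels.stats.anova import AnovaRM
    from statsmodels.stats.multitest import multipletests

    if values.shape[1] < 2:
        raise ValueError("need >= 2 windows (including baseline)")
    if baseline not in values.columns:
        raise ValueError(f"no column {baseline!r} in values")
    data = values.copy()
    ranked = False
    if gate_normality and data.size >= 8:
        flat, ranked = normality_gate(data.values.ravel())
        if ranked:
            data = pd.DataFrame(flat.reshape(data.shape), index=data.index,
                                columns=data.columns)

    long = data.reset_index(names="unit").melt(
        id_vars="unit", var_name="window", value_name="value")
    anova = AnovaRM(long, depvar="value", subject="unit",
                    within=["window"]).fit()
    f_stat = float(anova.anova_table["F Value"].iloc[0])
    p_overall = float(anova.anova_table["Pr > F"].iloc[0])

    windows = [c for c in data.columns if c != baseline]
    raw = []
    for w in windows:
        if np.allclose(data[w], data[baseline]):
            raw.append(1.0)
        else:
            _, p = stats.ttest_rel(data[w], data[baseline])
            raw.append(float(p))
    adjusted = multipletests(raw, alpha=alpha, method="holm-sidak")[1] \
        if windows else np.array([])
    return {"F": f_stat, "p": p_overall, "ranked": ranked,
            "window_p_raw": dict(zip(windows, raw)),
            "window_p_adjusted": dict(zip(windows, map(float, adjusted)))}


def normality_gate(samples, alpha: float = ALPHA) -> tuple[np.ndarray, bool]:
    """D'Agostino-Pearson omnibus gate; mid-ranks substituted on failure.

    Returns ``(samples_or_ranks, transformed)``. With n < 8 (the test's
    minimum) the gate is skipped and the data pass through untransformed.
    Idempotent: ranks of mid-ranks are the mid-ranks themselves.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 8:
        return x, False
    _, p = stats.normaltest(x)
    if p < alpha:
        return stats.rankdata(x), True
    return x, False
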