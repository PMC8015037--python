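"""Nonparametric repeated-measures statistics over trial-response tables.

The design: a Kolmogorov-Smirnov normality screen motivates the
nonparametric route; paired contrasts (pre- vs during-stimulation values,
repeated infusion stages) use the Wilcoxon signed-rank and Friedman tests,
between-group contrasts the Kruskal-Wallis test, all two-sided at
alpha = 0.05 with Bonferroni-corrected post-hoc pairwise comparisons.
Descriptives are medians with interquartile ranges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
EXACT_N_MAX = 25  # exact signed-rank distribution up to this n


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return float(min(1.0, m * p))


def median_iqr(sample: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(np.asarray(sample, dtype=float), [25, 50, 75])
    return float(med), float(q1), float(q3)


@dataclass
class TestRecord:
    test: str
    statistic: float
    p_value: float
    n: int
    degenerate: bool = False
    note: str = ""
    posthoc: list["TestRecord"] = field(default_factory=list)
    adjusted_p: float = float("nan")
    descriptives: dict = field(default_factory=dict)


def screen_normality(sample: np.ndarray, alpha: float = ALPHA) -> TestRecord:
    """KS test of the sample against a normal with its own mean and SD.

    The analysis path is nonparametric regardless; the decision is logged
    only, mirroring the screening role of the test in the design.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("normality screen needs at least 5 observations")
    if np.ptp(x) < 1e-12:
        return TestRecord(test="ks-normality", statistic=float("nan"),
                          p_value=float("nan"), n=x.size, degenerate=True,
                          note="constant sample")
    res = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return TestRecord(test="ks-normality", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=x.size,
                      note="normality rejected" if res.pvalue < alpha else
                           "normality not rejected")


def signed_rank(x: np.ndarray, y: np.ndarray) -> TestRecord:
    """Two-sided Wilcoxon signed-rank on paired samples.

    Exact null distribution for n <= 25 without ties/zeros, normal
    approximation with tie correction otherwise.  All-zero differences give
    a degenerate p = 1 record.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = y - x
    nz = d[d != 0]
    if nz.size == 0:
        return TestRecord(test="wilcoxon", statistic=0.0, p_value=1.0,
                          n=d.size, degenerate=True, note="all differences zero")
    ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= EXACT_N_MAX and not ties) else "approx"
    res = sps.wilcoxon(x, y, alternative="two-sided", method=method)
    return TestRecord(test="wilcoxon", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=d.size, note=method)


def paired_prepost(values: pd.DataFrame, t_pre_s: float = 10.0,
                   t_post_s: float = 30.0,
                   pre_col: str = "pre", post_col: str = "post") -> TestRecord:
    """Within-trial contrast of the normalized parameter at the 10th s
    (pre-stimulation) vs the 30th s (stimulation) of the trial."""
    rec = signed_rank(values[pre_col].to_numpy(), values[post_col].to_numpy())
    rec.note = (rec.note + f"; contrast {t_pre_s:g}s vs {t_post_s:g}s").strip("; ")
    rec.descriptives = {
        "pre": median_iqr(values[pre_col].to_numpy()),
        "post": median_iqr(values[post_col].to_numpy()),
    }
    return rec


def value_at(trace_t: np.ndarray, trace_v: np.ndarray, at_s: float) -> float:
    """Trace value at a trial time (linear interpolation)."""
    return float(np.interp(at_s, trace_t, trace_v))


def repeated_friedman(table: pd.DataFrame, alpha: float = ALPHA) -> TestRecord:
    """Friedman test across repeated stages (columns) over animals (rows),
    with post-hoc pairwise signed-rank tests (Bonferroni over all pairs)
    when the omnibus test is significant.

    Animals with missing stages are dropped (complete-block design).
    """
    complete = table.dropna(axis=0)
    n_dropped = len(table) - len(complete)
    if complete.shape[1] < 3:
        raise ValueError("Friedman test needs at least 3 repeated stages")
    if len(complete) < 2:
        raise ValueError("Friedman test needs at least 2 complete blocks")
    cols = [complete[c].to_numpy(dtype=float) for c in complete.columns]
    if all(np.array_equal(cols[0], c) for c in cols[1:]):
        rec = TestRecord(test="friedman", statistic=0.0, p_value=1.0,
                         n=len(complete), degenerate=True,
                         note="identical stages")
    else:
        res = sps.friedmanchisquare(*cols)
        rec = TestRecord(test="friedman", statistic=float(res.statistic),
                         p_value=float(res.pvalue), n=len(complete))
    if n_dropped:
        rec.note = (rec.note + f"; {n_dropped} incomplete blocks dropped").strip("; ")
    rec.descriptives = {str(c): median_iqr(complete[c].to_numpy()) for c in complete.columns}
    if rec.p_value < alpha:
        pairs = list(itertools.combinations(complete.columns, 2))
        for a, b in pairs:
            sub = signed_rank(complete[a].to_numpy(), complete[b].to_numpy())
            sub.test = f"wilcoxon[{a} vs {b}]"
            sub.adjusted_p = bonferroni(sub.p_value, len(pairs))
            rec.posthoc.append(sub)
    return rec


def groups_kruskal(groups: dict[str, np.ndarray], alpha: float = ALPHA) -> TestRecord:
    """Kruskal-Wallis H across independent groups with post-hoc pairwise
    Mann-Whitney contrasts (Bonferroni over all pairs) when significant."""
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size < 3 for a in arrays.values()):
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate(list(arrays.values()))
    n = int(pooled.size)
    if np.ptp(pooled) < 1e-12:
        return TestRecord(test="kruskal-wallis", statistic=0.0, p_value=1.0,
                          n=n, degenerate=True, note="identical constant groups")
    res = sps.kruskal(*arrays.values())
    rec = TestRecord(test="kruskal-wallis", statistic=float(res.statistic),
                     p_value=float(res.pvalue), n=n)
    rec.descriptives = {k: median_iqr(v) for k, v in arrays.items()}
    if rec.p_value < alpha:
        pairs = list(itertools.combinations(arrays, 2))
        for a, b in pairs:
            mw = sps.mannwhitneyu(arrays[a], arrays[b], alternative="two-sided")
            sub = TestRecord(test=f"mann-whitney[{a} vs {b}]",
                             statistic=float(mw.statistic),
                             p_value=float(mw.pvalue),
                             n=arrays[a].size + arrays[b].size)
            sub.adjusted_p = bonferroni(sub.p_value, len(pairs))
            rec.posthoc.append(sub)
    return rec


def stage_means(normalized: pd.DataFrame,
                value_col: str = "normalized_integral") -> pd.DataFrame:
    """Per-animal mean over the triple trials of each stage: rows = animals,
    columns = stages (the value entering Friedman/Kruskal-Wallis)."""
    wide = (normalized.groupby(["animal", "stage"])[value_col].mean()
            .unstack("stage"))
    return wide


def experiment_report(normalized: pd.DataFrame, alpha: float = ALPHA,
                      value_col: str = "normalized_integral") -> dict:
    """Run the full group-level plan on a baseline-normalized integral table
    with columns (animal, group, stage, trial, normalized_integral).

    Returns {'friedman': {group: TestRecord}, 'kruskal': {stage: TestRecord},
    'stage_means': wide table}.
    """
    wide = stage_means(normalized, value_col)
    group_of = normalized.groupby("animal")["group"].first()
    report: dict = {"friedman": {}, "kruskal": {}, "stage_means": wide}
    for group in group_of.unique():
        animals = group_of[group_of == group].index
        report["friedman"][group] = repeated_friedman(wide.loc[animals], alpha)
    for stage in wide.columns:
        samples = {g: wide.loc[group_of[group_of == g].index, stage].dropna().to_numpy()
                   for g in group_of.unique()}
        report["kruskal"][stage] = groups_kruskal(samples, alpha)
    return report
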