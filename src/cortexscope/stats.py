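"""Nonparametric repeated-measures tests: Friedman, Dunn's post hoc, paired t.

The Friedman statistic and Dunn's pairwise comparisons are computed from their
defining rank formulas (with mean ranks for ties and the tie-corrected
denominator), since these are the inferential core of the group comparisons;
the paired t-test delegates to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class RepeatedMeasuresTable:
    """n_subjects x k_conditions matrix of one value per cell."""

    values: np.ndarray
    subjects: tuple | None = None
    conditions: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x conditions)")
        if np.isnan(self.values).any():
            raise ValueError("missing cells are not allowed")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 conditions")
        if self.conditions is None:
            self.conditions = tuple(f"c{i}" for i in range(k))


def _within_subject_ranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, axis=1)


def friedman_test(table: RepeatedMeasuresTable | np.ndarray) -> tuple[float, int, float]:
    """Friedman chi-square test on within-subject ranks.

    Q = [12 / (n k (k+1))] * sum_j R_j^2 - 3 n (k+1), divided by the tie
    correction 1 - sum(t^3 - t) / (n k (k^2 - 1)); p from chi-square, k-1 df.
    An all-tied table yields Q = 0, p = 1.
    """
    if not isinstance(table, RepeatedMeasuresTable):
        table = RepeatedMeasuresTable(np.asarray(table))
    vals = table.values
    n, k = vals.shape
    ranks = _within_subject_ranks(vals)
    rj = ranks.sum(axis=0)
    q = 12.0 / (n * k * (k + 1)) * float((rj**2).sum()) - 3.0 * n * (k + 1)
    tie_sum = 0.0
    for row in vals:
        _, counts = np.unique(row, return_counts=True)
        tie_sum += float((counts**3 - counts).sum())
    denom = 1.0 - tie_sum / (n * k * (k * k - 1))
    if denom <= 0:  # every row fully tied
        return 0.0, k - 1, 1.0
    q /= denom
    q = max(q, 0.0)
    p = float(sps.chi2.sf(q, k - 1))
    return float(q), k - 1, p


def dunn_posthoc(
    table: RepeatedMeasuresTable | np.ndarray,
    comparisons: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Dunn's multiple-comparisons test on the Friedman (within-subject) ranks.

    For a pair (a, b): z = (Rbar_a - Rbar_b) / sqrt(k (k+1) / (6 n)); two-sided
    normal p, Bonferroni-adjusted over the requested comparisons.  By default
    the comparisons are every non-reference condition against the first
    (reference) condition.
    """
    if not isinstance(table, RepeatedMeasuresTable):
        table = RepeatedMeasuresTable(np.asarray(table))
    vals = table.values
    n, k = vals.shape
    conds = list(table.conditions)
    if comparisons is None:
        comparisons = [(conds[j], conds[0]) for j in range(1, k)]
    for a, b in comparisons:
        if a not in conds or b not in conds:
            raise ValueError(f"unknown condition in comparison ({a}, {b})")
    mean_ranks = _within_subject_ranks(vals).mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    m = len(comparisons)
    rows = []
    for a, b in comparisons:
        z = (mean_ranks[conds.index(a)] - mean_ranks[conds.index(b)]) / se
        p = 2.0 * float(sps.norm.sf(abs(z)))
        rows.append({"a": a, "b": b, "z": float(z), "p": p, "p_adj": min(1.0, p * m)})
    return pd.DataFrame(rows)


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p).

    Zero-variance differences are degenerate: t = 0, p = 1 when the mean
    difference is also zero, otherwise t = +/-inf with p reported as 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, n - 1, 1.0
        return float(np.sign(d.mean()) * np.inf), n - 1, 0.0
    res = sps.ttest_rel(a, b)
    return float(res.statistic), n - 1, float(res.pvalue)


def friedman_dunn_table(
    df: pd.DataFrame,
    value: str,
    condition: str = "condition",
    subject: str = "subject",
    group_by: list[str] | None = None,
    reference: str = "saline",
) -> pd.DataFrame:
    """Friedman + Dunn (each condition vs reference) per group of a long table.

    Returns one row per (group, contrast) with the Friedman statistic/p and
    the Dunn z / adjusted p for that contrast.
    """
    group_by = group_by or []
    out = []
    grouped = df.groupby(group_by) if group_by else [((), df)]
    for keys, grp in grouped:
        pivot = grp.pivot_table(index=subject, columns=condition, values=value)
        if pivot.isna().any().any():
            raise ValueError(f"missing cell in group {keys}")
        conds = [reference] + [c for c in pivot.columns if c != reference]
        table = RepeatedMeasuresTable(pivot[conds].to_numpy(), conditions=tuple(conds))
        q, dof, p = friedman_test(table)
        dunn = dunn_posthoc(table)
        for row in dunn.itertuples(index=False):
            rec = dict(zip(group_by, keys if isinstance(keys, tuple) else (keys,)))
            rec.update({"friedman_q": q, "friedman_df": dof, "friedman_p": p,
                        "contrast": f"{row.a} vs {row.b}", "z": row.z,
                        "p": row.p, "p_adj": row.p_adj})
            out.append(rec)
    return pd.DataFrame(out)
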