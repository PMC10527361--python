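"""Per-peptide two-group statistics with Benjamini-Hochberg FDR control.

Group comparisons (benign vs malignant basal signal, mutation-positive vs
negative LFC profiles, recurrent vs non-recurrent) use the classical
pooled-variance two-sample two-tailed Student's t-test per peptide, with
Benjamini-Hochberg step-up adjustment across peptides. Following the
reporting style "p < 0.05, FDR x%", the FDR attached to a p-threshold set
is the maximum q-value among the peptides passing that p threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVarianceError, InvalidArgumentError


def t_test_two_sample(a, b) -> tuple[float, float]:
    """Pooled-variance Student's t with df = n_a + n_b - 2, two-tailed p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidArgumentError("each group needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise DegenerateVarianceError(
            "zero pooled variance with unequal means: t is undefined"
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the original order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1; computed as a reverse
    running minimum so every q is exactly one of the p_(j)*m/j terms.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def differential_table(
    matrix,
    labels,
    groups: tuple[str, str] | None = None,
    p_threshold: float = 0.05,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-peptide t-test table, BH-adjusted, sorted by p.

    ``matrix`` is a samples x peptides DataFrame (log2 signal or LFC);
    ``labels`` assigns each sample to one of two groups; ``delta`` is
    group2 minus group1 (sorted label order when ``groups`` is None).
    Peptides with fewer than 2 non-missing values in either group are
    reported as untestable (NaN statistics) rather than erroring the table.
    """
    values = matrix if isinstance(matrix, pd.DataFrame) else matrix.values
    labels = pd.Series(np.asarray(labels), index=values.index)
    if groups is None:
        groups = tuple(sorted(labels.unique()))
    if len(set(labels) - set(groups)) or len(groups) != 2:
        raise InvalidArgumentError(f"labels must take exactly the two values {groups}")
    g1 = values.loc[labels == groups[0]]
    g2 = values.loc[labels == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise InvalidArgumentError("both groups need >= 2 samples")

    rows = []
    for pep in values.columns:
        a = g1[pep].dropna().to_numpy()
        b = g2[pep].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows.append((pep, np.nan, np.nan, np.nan, np.nan, np.nan, False))
            continue
        try:
            t, p = t_test_two_sample(a, b)
        except DegenerateVarianceError:
            rows.append((pep, a.mean(), b.mean(), b.mean() - a.mean(),
                         np.nan, np.nan, False))
            continue
        rows.append((pep, a.mean(), b.mean(), b.mean() - a.mean(), t, p, True))
    table = pd.DataFrame(
        rows,
        columns=["peptide_id", "mean_group1", "mean_group2", "delta",
                 "t_statistic", "p_value", "testable"],
    )
    testable = table["testable"].to_numpy()
    q = np.full(len(table), np.nan)
    if testable.any():
        q[testable] = bh_adjust(table.loc[testable, "p_value"].to_numpy())
    table["q_value"] = q
    table.attrs["groups"] = groups
    table.attrs["n_pass_p"] = int((table["p_value"] < p_threshold).sum())
    table.attrs["n_pass_q"] = int((table["q_value"] < q_threshold).sum())
    table.attrs["fdr_at_p_threshold"] = fdr_at_p_threshold(table, p_threshold)
    return table.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def fdr_at_p_threshold(table: pd.DataFrame, p_threshold: float = 0.05) -> float:
    """The FDR figure paired with a p cut: max q among peptides with p below it."""
    passing = table.loc[table["p_value"] < p_threshold, "q_value"]
    return float(passing.max()) if len(passing) else float("nan")
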