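"""Phenotypic layer: twin correlations by zygosity and mean-level contrasts.

Cross-twin correlations are computed on double-entered pair data (each family
contributes both twin orderings) so they are exactly invariant to arbitrary
twin order; within-twin cross-trait correlations are computed on individuals.
Pair counts, not double-entered counts, are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pairs import POOLED, pairs_by_group


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx <= 0 or sy <= 0:
        raise ValueError("zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def twin_correlations(
    scores: pd.DataFrame,
    columns: list[str],
    scheme: dict[str, tuple[str, ...]] = POOLED,
) -> pd.DataFrame:
    """Cross-twin within-trait, cross-twin cross-trait and within-twin
    cross-trait Pearson correlations, per analysis group.

    Returns a tidy frame with columns group, kind, trait_1, trait_2, r,
    n_pairs.
    """
    pair_arrays = pairs_by_group(scores, columns, scheme)
    k = len(columns)
    rows = []
    for group, arr in pair_arrays.items():
        n = arr.shape[0]
        if n < 3:
            raise ValueError(f"group {group!r} has fewer than 3 complete pairs")
        t1, t2 = arr[:, :k], arr[:, k:]
        de_a = np.vstack([t1, t2])  # double entry: both orderings
        de_b = np.vstack([t2, t1])
        ind = np.vstack([t1, t2])  # individuals, for within-twin correlations
        for i in range(k):
            if de_a[:, i].std() <= 0:
                raise ValueError(
                    f"trait {columns[i]!r} has zero variance in group {group!r}"
                )
        for i in range(k):
            for j in range(k):
                if j < i:
                    continue
                r_ct = _pearson(de_a[:, i], de_b[:, j])
                kind = (
                    "cross_twin_within_trait" if i == j else "cross_twin_cross_trait"
                )
                rows.append(
                    dict(group=group, kind=kind, trait_1=columns[i],
                         trait_2=columns[j], r=r_ct, n_pairs=n)
                )
                if j > i:
                    rows.append(
                        dict(group=group, kind="within_twin_cross_trait",
                             trait_1=columns[i], trait_2=columns[j],
                             r=_pearson(ind[:, i], ind[:, j]), n_pairs=n)
                    )
    return pd.DataFrame(rows)


@dataclass
class MeanComparison:
    difference: float
    t: float
    p: float
    d: float
    n1: int
    n2: int


def compare_means(x: np.ndarray, y: np.ndarray) -> MeanComparison:
    """Welch two-sample comparison with Cohen d on the pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 observations")
    s1, s2 = x.var(ddof=1), y.var(ddof=1)
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("degenerate groups: zero pooled variance")
    t, p = sps.ttest_ind(x, y, equal_var=False)
    diff = x.mean() - y.mean()
    return MeanComparison(
        difference=float(diff), t=float(t), p=float(p),
        d=float(diff / np.sqrt(sp2)), n1=n1, n2=n2,
    )


def compare_means_paired(x: np.ndarray, y: np.ndarray) -> MeanComparison:
    """Within-person paired contrast; d computed on the difference scores."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired comparison requires equal-length samples")
    d = x - y
    sd = d.std(ddof=1)
    if sd <= 0:
        raise ValueError("degenerate paired contrast: zero difference variance")
    t, p = sps.ttest_rel(x, y)
    return MeanComparison(
        difference=float(d.mean()), t=float(t), p=float(p),
        d=float(d.mean() / sd), n1=len(x), n2=len(y),
    )
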