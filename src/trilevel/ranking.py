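"""Within-level MCC ranking, six-group classification and summed-rank ordering.

Each term's three MCCs are ranked across terms within their level
(rank 1 = highest MCC = most discriminating, ties get mean ranks).  The
relative order of a term's three level ranks assigns it to one of the six
strict orderings of {methylation, microRNA, mRNA}; the level listed first
is the one most altered between tumor and normal.  Summing the three ranks
gives an overall dysfunction ranking: the smaller the sum, the more
dysfunctional the term across all levels.
"""

from __future__ import annotations

from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import LEVELS, ValidationError

#: The six possible strict orderings, e.g. "methylation<microRNA<mRNA".
GROUP_LABELS = tuple("<".join(p) for p in permutations(LEVELS))


def rank_with_ties(values: Sequence[float]) -> np.ndarray:
    """Descending ranks: rank 1 for the largest value, ties share mean ranks."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot rank an empty list")
    if not np.isfinite(arr).all():
        raise ValidationError("non-finite values cannot be ranked")
    return stats.rankdata(-arr, method="average")


def classify_groups(mcc_table: pd.DataFrame) -> pd.DataFrame:
    """Rank MCCs within each level and assign every term to one of six groups.

    `mcc_table` is indexed by term id with one column per level.  Returns a
    DataFrame with columns ``term``, ``mcc_<level>``, ``rank_<level>``,
    ``group``, ``tie_flag`` and ``summed_rank``.  Within-term rank ties are
    resolved by the fixed level priority methylation -> microRNA -> mRNA
    and flagged, so the six group counts always partition the terms.
    """
    if len(mcc_table) == 0:
        raise ValidationError("need at least one term")
    if mcc_table.index.duplicated().any():
        dup = mcc_table.index[mcc_table.index.duplicated()][0]
        raise ValidationError(f"duplicate term id {dup!r}")
    for level in LEVELS:
        if level not in mcc_table.columns:
            raise ValidationError(f"missing MCC column for level {level!r}")
        col = mcc_table[level]
        if col.isna().any():
            term = mcc_table.index[col.isna()][0]
            raise ValidationError(f"term {term!r} has no MCC at level {level!r}")
    ranks = {level: rank_with_ties(mcc_table[level].to_numpy()) for level in LEVELS}
    records = []
    for i, term in enumerate(mcc_table.index):
        term_ranks = {level: ranks[level][i] for level in LEVELS}
        # stable sort on (rank, level priority) forces a strict ordering
        ordered = sorted(LEVELS, key=lambda lv: (term_ranks[lv], LEVELS.index(lv)))
        tie = len({term_ranks[lv] for lv in LEVELS}) < 3
        records.append(
            {
                "term": term,
                **{f"mcc_{lv}": float(mcc_table.at[term, lv]) for lv in LEVELS},
                **{f"rank_{lv}": float(term_ranks[lv]) for lv in LEVELS},
                "group": "<".join(ordered),
                "tie_flag": bool(tie),
                "summed_rank": float(sum(term_ranks.values())),
            }
        )
    return pd.DataFrame.from_records(records)


def group_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Count terms per group, all six orderings listed (zero counts included)."""
    counts = table["group"].value_counts()
    return pd.DataFrame(
        {"group": GROUP_LABELS, "count": [int(counts.get(g, 0)) for g in GROUP_LABELS]}
    )


def overall_ranking(table: pd.DataFrame) -> pd.DataFrame:
    """Order terms by ascending summed rank (smallest = most dysfunctional).

    Ties are broken lexicographically by term id and flagged in
    ``sum_tie``.  Adds a 1-based ``position`` column.
    """
    out = table.sort_values(["summed_rank", "term"], kind="mergesort").reset_index(drop=True)
    out["position"] = np.arange(1, len(out) + 1)
    sums = out["summed_rank"].to_numpy()
    tie = np.zeros(len(out), dtype=bool)
    tie[1:] |= sums[1:] == sums[:-1]
    tie[:-1] |= sums[:-1] == sums[1:]
    out["sum_tie"] = tie
    return out


def top_k(ordered_terms: Sequence[str] | pd.DataFrame, k: int) -> list[str]:
    """First `k` terms of the overall ranking; requires 1 <= k <= T."""
    terms = list(ordered_terms["term"]) if isinstance(ordered_terms, pd.DataFrame) else list(ordered_terms)
    if not 1 <= k <= len(terms):
        raise ValidationError(f"k={k} outside 1..{len(terms)}")
    return terms[:k]


def compare_levels(mcc_table: pd.DataFrame) -> pd.DataFrame:
    """Welch one-sided-greater t-tests between every ordered pair of levels.

    Returns one row per ordered (greater, lesser) pair with the two means,
    the p-value of H1: mean(greater) > mean(lesser), and a ``degenerate``
    flag set when both MCC distributions have zero variance (p is then 0,
    1 or 0.5 by the sign of the mean difference).
    """
    if len(mcc_table) < 2:
        raise ValidationError("need at least two terms to compare levels")
    rows = []
    for a in LEVELS:
        for b in LEVELS:
            if a == b:
                continue
            xa = mcc_table[a].to_numpy(dtype=float)
            xb = mcc_table[b].to_numpy(dtype=float)
            degenerate = xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0
            if degenerate:
                d = xa.mean() - xb.mean()
                p = 0.0 if d > 0 else 1.0 if d < 0 else 0.5
            else:
                p = float(stats.ttest_ind(xa, xb, equal_var=False, alternative="greater").pvalue)
            rows.append(
                {
                    "greater": a,
                    "lesser": b,
                    "mean_greater": float(xa.mean()),
                    "mean_lesser": float(xb.mean()),
                    "p_value": p,
                    "degenerate": bool(degenerate),
                }
            )
    return pd.DataFrame.from_records(rows)
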