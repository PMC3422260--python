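"""Downstream stages: high-frequency members, enrichment, independent validation.

Genes and microRNAs recurring across many of the top dysfunctional sets
are the recurrent actors of the disease; their overlap with a reference
pathway is assessed with an upper-tail hypergeometric test, and their
discriminating ability is re-checked on an independent cohort.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .datatypes import OmicsMatrix, TermLevelSets, ValidationError
from .discriminate import score_set

#: Membership classes a frequency table can be computed over.
LEVEL_CLASSES = ("gene_mrna", "gene_methylation", "microRNA")

_CLASS_TO_ATTR = {
    "gene_mrna": "mrna_genes",
    "gene_methylation": "methylation_genes",
    "microRNA": "mirnas",
}


def member_frequency(
    top_terms: Sequence[str],
    sets: Sequence[TermLevelSets],
    level_class: str,
) -> pd.DataFrame:
    """Count, per member id, the top terms whose set at `level_class` contains it.

    Returns a DataFrame with columns ``member`` and ``count`` sorted by
    descending count then member id; members absent from every top term do
    not appear (their count is 0).
    """
    if level_class not in LEVEL_CLASSES:
        raise ValidationError(f"unknown level class {level_class!r}; expected one of {LEVEL_CLASSES}")
    by_term: Mapping[str, TermLevelSets] = {ts.term_id: ts for ts in sets}
    counter: Counter[str] = Counter()
    for term in top_terms:
        if term not in by_term:
            raise ValidationError(f"unknown term {term!r} in top list")
        counter.update(getattr(by_term[term], _CLASS_TO_ATTR[level_class]))
    records = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(records, columns=["member", "count"])


def high_frequency(freq: pd.DataFrame, threshold: int = 50) -> frozenset[str]:
    """Members with count strictly greater than `threshold`."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    if len(freq) == 0:
        return frozenset()
    return frozenset(freq.loc[freq["count"] > threshold, "member"])


def hypergeom_enrichment(
    hits: Iterable[str], reference: Iterable[str], universe: Iterable[str]
) -> float:
    """Upper-tail hypergeometric p-value of the hits/reference overlap.

    P(X >= |hits ∩ reference|) for X ~ Hypergeom(N=|universe|,
    K=|reference|, n=|hits|).  Both hits and reference must be subsets of
    the universe.
    """
    universe = frozenset(universe)
    hits = frozenset(hits)
    reference = frozenset(reference)
    if not universe:
        raise ValidationError("enrichment universe is empty")
    if not hits <= universe:
        raise ValidationError(f"hit(s) outside the universe: {sorted(hits - universe)[:5]}")
    if not reference <= universe:
        raise ValidationError(
            f"reference gene(s) outside the universe: {sorted(reference - universe)[:5]}"
        )
    k = len(hits & reference)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(reference), len(hits)))


def validate_independent(high_freq_genes: Iterable[str], independent: OmicsMatrix) -> float:
    """LOOCV-NNA MCC of an independent cohort restricted to the given genes."""
    genes = frozenset(high_freq_genes)
    present = genes & set(independent.feature_ids)
    if not present:
        raise ValidationError(
            f"none of the genes are measured in the independent cohort; "
            f"missing: {sorted(genes)[:10]}"
        )
    return score_set(independent, genes)
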