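"""Tri-level gene-set construction.

For each functional term three parallel member sets are built: the
annotated genes with methylation measurements, the microRNAs whose
consensus-predicted targets intersect the term, and the annotated genes
measured on the mRNA platform.  Terms lacking members at any level are
filtered out before scoring.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Mapping, Sequence

from .datatypes import AnnotationMap, TargetPredictionTable, TermLevelSets, ValidationError

logger = logging.getLogger(__name__)


def check_unique_terms(sets: Sequence[TermLevelSets]) -> None:
    seen: set[str] = set()
    for ts in sets:
        if ts.term_id in seen:
            raise ValidationError(f"duplicate term id {ts.term_id!r}")
        seen.add(ts.term_id)


def consensus_targets(predictions: TargetPredictionTable, min_tools: int = 3) -> dict[str, frozenset[str]]:
    """microRNA -> gene map keeping pairs predicted by >= `min_tools` distinct tools.

    Duplicate records from one tool count once: the consensus counts tools,
    not records.
    """
    if not 1 <= min_tools <= max(1, len(predictions.tool_universe)):
        raise ValidationError(
            f"min_tools={min_tools} outside 1..{len(predictions.tool_universe)}"
        )
    if len(predictions) == 0:
        logger.warning("empty prediction table; consensus target map is empty")
        return {}
    counts = predictions.frame.groupby(["microRNA", "gene"])["tool"].nunique()
    kept = counts[counts >= min_tools]
    out: dict[str, set[str]] = {}
    for (mirna, gene) in kept.index:
        out.setdefault(mirna, set()).add(gene)
    return {m: frozenset(gs) for m, gs in out.items()}


def build_term_sets(
    annotation: AnnotationMap,
    meth_features: Iterable[str],
    mirna_features: Iterable[str],
    mrna_features: Iterable[str],
    targets: Mapping[str, frozenset[str]],
) -> list[TermLevelSets]:
    """Construct the three member sets for every annotated term.

    methylation = annotated genes with methylation data; microRNA =
    measured microRNAs with >=1 target annotated to the term; mRNA =
    annotated genes measured on the mRNA platform.  Empty sets are allowed
    here; `filter_terms` removes them.
    """
    meth = frozenset(meth_features)
    mirna = frozenset(mirna_features)
    mrna = frozenset(mrna_features)
    if not meth or not mirna or not mrna:
        raise ValidationError("every measured-feature universe must be nonempty")
    out = []
    for term, genes in annotation.terms.items():
        out.append(
            TermLevelSets(
                term_id=term,
                methylation_genes=genes & meth,
                mirnas=frozenset(m for m in mirna if targets.get(m, frozenset()) & genes),
                mrna_genes=genes & mrna,
            )
        )
    return out


def filter_terms(sets: Sequence[TermLevelSets], min_size: int = 1) -> list[TermLevelSets]:
    """Keep terms whose three member sets each have >= `min_size` members."""
    if min_size < 1:
        raise ValidationError("min_size must be >= 1")
    kept = [
        ts
        for ts in sets
        if min(len(ts.methylation_genes), len(ts.mirnas), len(ts.mrna_genes)) >= min_size
    ]
    if not kept:
        raise ValidationError(
            "no term has members at all three levels; loosen min_size or check inputs"
        )
    return kept


def write_level_gmts(sets: Sequence[TermLevelSets], outdir: str | os.PathLike) -> dict[str, str]:
    """Emit one GMT file per level (term, member count, members)."""
    from .datatypes import LEVELS
    from .io import write_gmt
    from .datatypes import AnnotationMap

    paths = {}
    for level in LEVELS:
        terms = {ts.term_id: ts.members(level) for ts in sets if ts.members(level)}
        path = os.path.join(outdir, f"sets_{level}.gmt")
        write_gmt(AnnotationMap(terms=terms), path)
        paths[level] = path
    return paths
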