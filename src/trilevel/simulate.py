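"""Synthetic multi-omics study generator with planted ground truth.

Emulates the structure the analysis assumes: three platforms (methylation,
microRNA, mRNA) measuring overlapping but non-identical feature universes
on two-class (tumor / normal) cohorts, a term -> gene annotation map,
multi-tool microRNA target predictions, and an independent validation
cohort drawn from the same generative law.

The generative model is deliberately simple: every feature f has a fixed
baseline level b_f ~ Normal(baseline_mean, baseline_sd) shared by all
samples (as gene-specific expression levels are on a log-intensity
platform), sample values are b_f + Normal(0, noise_sd) i.i.d., and a
planted effect (term, level, delta) shifts the tumor-class mean of every
member feature of that term at that level by delta * noise_sd, with a
random sign per feature (dysregulated sets contain both up- and
down-regulated members; a uniform one-directional shift would be nearly
parallel to the baseline profile and invisible to cosine distance).  The shared
baseline matters: it is what makes cosine similarity discriminative
(samples of one class cluster around a common profile direction), exactly
as on real array data.  Planted effect sizes stay recoverable as
standardized mean differences, and 1-NN cosine separability is tunable by
delta.  MicroRNA signal is planted on the microRNA rows themselves (the
pipeline scores microRNA sets on the microRNA matrix, not on target
mRNA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import LEVELS, NORMAL, TUMOR, AnnotationMap, OmicsMatrix, TargetPredictionTable, ValidationError

#: Names for the prediction tools of the synthetic consensus.
DEFAULT_TOOLS = ("toolA", "toolB", "toolC", "toolD", "toolE", "toolF")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults are sized for desk-scale runs: 300 genes, 60 microRNAs,
    40 terms of 5-12 genes, 30 tumor + 30 normal samples per platform.
    Term sizes and per-microRNA target counts are kept small relative to
    the gene universe (a few percent) so member sets stay term-specific,
    mirroring the sparsity of real annotations and targetomes.
    """

    n_genes: int = 300
    n_mirnas: int = 60
    n_terms: int = 40
    term_size_min: int = 5
    term_size_max: int = 12
    n_tumor: int = 30
    n_normal: int = 30
    n_tumor_independent: int = 20
    n_normal_independent: int = 20
    meth_fraction: float = 0.7
    #: (term index, level, standardized effect size delta) triples.
    planted_effects: tuple[tuple[int, str, float], ...] = ()
    noise_sd: float = 1.0
    n_tools: int = 6
    targets_min: int = 3
    targets_max: int = 6
    #: per-tool prediction probability for true target pairs
    p_tool_true: float = 0.8
    #: per-tool prediction probability for non-target (background) pairs
    p_tool_background: float = 0.05
    #: per-feature baseline level: drawn once per feature from
    #: Normal(baseline_mean, baseline_sd), shared by every sample (log-intensity
    #: scale).  A nonzero baseline is what makes cosine similarity meaningful:
    #: all samples share a platform profile and class differences perturb it.
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.term_size_min <= self.term_size_max <= self.n_genes:
            raise ValidationError("term size range must lie within [1, n_genes]")
        if not 0 < self.meth_fraction <= 1:
            raise ValidationError("meth_fraction must be in (0, 1]")
        if not 1 <= self.n_tools <= len(DEFAULT_TOOLS):
            raise ValidationError(f"n_tools must be in 1..{len(DEFAULT_TOOLS)}")
        for idx, level, delta in self.planted_effects:
            if not 0 <= idx < self.n_terms:
                raise ValidationError(f"planted term index {idx} outside 0..{self.n_terms - 1}")
            if level not in LEVELS:
                raise ValidationError(f"unknown planted level {level!r}")
            if delta < 0:
                raise ValidationError("planted effect sizes must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground-truth record of one generated study."""

    seed: int
    noise_sd: float
    #: term -> level -> planted standardized effect size (0 when unplanted)
    effects: dict[str, dict[str, float]]
    #: (term, level) -> the feature ids whose tumor mean was shifted
    planted_features: dict[tuple[str, str], frozenset[str]]
    #: level -> feature -> signed shift in units of noise_sd (|value| = delta)
    shift_signs: dict[str, dict[str, float]] = field(default_factory=dict)

    def ordering(self, term_id: str) -> list[list[str]]:
        """Levels grouped by descending planted effect; a group of >1 is a tie."""
        if term_id not in self.effects:
            raise ValidationError(f"unknown term {term_id!r}")
        eff = self.effects[term_id]
        groups: dict[float, list[str]] = {}
        for level in LEVELS:
            groups.setdefault(eff[level], []).append(level)
        return [groups[d] for d in sorted(groups, reverse=True)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t, **{f"delta_{lv}": eff[lv] for lv in LEVELS}}
            for t, eff in self.effects.items()
        ]
        return pd.DataFrame.from_records(rows)


def truth_group(truth: SyntheticTruth, term_id: str) -> list[list[str]]:
    """Expected level ordering for a term (ties grouped together)."""
    return truth.ordering(term_id)


@dataclass
class SyntheticStudy:
    """The full bundle one simulation produces."""

    matrices: dict[str, OmicsMatrix]
    annotation: AnnotationMap
    predictions: TargetPredictionTable
    independent: OmicsMatrix
    truth: SyntheticTruth
    config: SimulationConfig
    #: microRNA -> true target genes (the generative assignment)
    true_targets: dict[str, frozenset[str]]


def _sample_matrix(
    rng: np.random.Generator,
    level: str,
    feature_ids: list[str],
    baselines: np.ndarray,
    shifts: dict[str, float],
    n_tumor: int,
    n_normal: int,
    noise_sd: float,
    sample_prefix: str,
) -> OmicsMatrix:
    n = n_tumor + n_normal
    values = baselines[:, None] + rng.normal(0.0, noise_sd, size=(len(feature_ids), n))
    for i, f in enumerate(feature_ids):
        d = shifts.get(f, 0.0)
        if d:
            values[i, :n_tumor] += d * noise_sd
    sample_ids = [f"{sample_prefix}_TU{i:03d}" for i in range(n_tumor)] + [
        f"{sample_prefix}_NO{i:03d}" for i in range(n_normal)
    ]
    labels = [TUMOR] * n_tumor + [NORMAL] * n_normal
    return OmicsMatrix(
        level=level, feature_ids=feature_ids, sample_ids=sample_ids, values=values, labels=labels
    )


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a complete synthetic study from a SimulationConfig.

    Identical configs (including seed) give bitwise-identical output.
    Raises :class:`ValidationError` when a planted (term, level) has no
    member features at that level.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    mirnas = [f"mir-{i:03d}" for i in range(config.n_mirnas)]
    term_ids = [f"T{i:04d}" for i in range(config.n_terms)]

    # annotation: uniform random member subsets within the size range
    terms: dict[str, frozenset[str]] = {}
    for t in term_ids:
        size = int(rng.integers(config.term_size_min, config.term_size_max + 1))
        terms[t] = frozenset(rng.choice(genes, size=size, replace=False))
    annotation = AnnotationMap(terms=terms)

    # methylation platform covers a random fraction of the gene universe
    n_meth = max(1, int(round(config.meth_fraction * config.n_genes)))
    meth_genes = sorted(rng.choice(genes, size=n_meth, replace=False))

    # true microRNA -> target assignments
    true_targets: dict[str, frozenset[str]] = {}
    for m in mirnas:
        k = int(rng.integers(config.targets_min, config.targets_max + 1))
        true_targets[m] = frozenset(rng.choice(genes, size=k, replace=False))

    # resolve planted effects into per-level feature shifts (max on overlap)
    effects = {t: {lv: 0.0 for lv in LEVELS} for t in term_ids}
    planted_features: dict[tuple[str, str], frozenset[str]] = {}
    shifts: dict[str, dict[str, float]] = {lv: {} for lv in LEVELS}
    meth_set = frozenset(meth_genes)
    for idx, level, delta in config.planted_effects:
        term = term_ids[idx]
        members = annotation.terms[term]
        if level == "methylation":
            feats = members & meth_set
        elif level == "mRNA":
            feats = frozenset(members)
        else:
            feats = frozenset(m for m in mirnas if true_targets[m] & members)
        if not feats:
            raise ValidationError(
                f"planted term {term!r} has no member features at level {level!r}"
            )
        effects[term][level] = max(effects[term][level], delta)
        planted_features[(term, level)] = feats
        for f in sorted(feats):
            sign = shifts[level][f] / abs(shifts[level][f]) if shifts[level].get(f) else (
                1.0 if rng.random() < 0.5 else -1.0
            )
            # overlapping plantings keep the larger magnitude, sign fixed per feature
            if abs(shifts[level].get(f, 0.0)) < delta:
                shifts[level][f] = sign * delta

    # per-feature baseline levels, fixed properties of each platform's features
    baselines = {
        "methylation": rng.normal(config.baseline_mean, config.baseline_sd, len(meth_genes)),
        "microRNA": rng.normal(config.baseline_mean, config.baseline_sd, len(mirnas)),
        "mRNA": rng.normal(config.baseline_mean, config.baseline_sd, len(genes)),
    }
    matrices = {
        "methylation": _sample_matrix(
            rng, "methylation", meth_genes, baselines["methylation"], shifts["methylation"],
            config.n_tumor, config.n_normal, config.noise_sd, "METH",
        ),
        "microRNA": _sample_matrix(
            rng, "microRNA", mirnas, baselines["microRNA"], shifts["microRNA"],
            config.n_tumor, config.n_normal, config.noise_sd, "MIR",
        ),
        "mRNA": _sample_matrix(
            rng, "mRNA", genes, baselines["mRNA"], shifts["mRNA"],
            config.n_tumor, config.n_normal, config.noise_sd, "MRNA",
        ),
    }

    # per-tool predictions: conditionally independent given true-target status
    tools = DEFAULT_TOOLS[: config.n_tools]
    true_mask = np.zeros((config.n_mirnas, config.n_genes), dtype=bool)
    gene_index = {g: j for j, g in enumerate(genes)}
    for i, m in enumerate(mirnas):
        for g in true_targets[m]:
            true_mask[i, gene_index[g]] = True
    p = np.where(true_mask, config.p_tool_true, config.p_tool_background)
    records = []
    for tool in tools:
        hit = rng.random(p.shape) < p
        for i, j in np.argwhere(hit):
            records.append((mirnas[i], genes[j], tool))
    predictions = TargetPredictionTable(
        frame=pd.DataFrame(records, columns=list(TargetPredictionTable.COLUMNS)),
        tool_universe=frozenset(tools),
    )

    # independent cohort: fresh mRNA draw from the same generative law
    # (same per-gene baselines and planted shifts, new samples)
    independent = _sample_matrix(
        rng, "mRNA", genes, baselines["mRNA"], shifts["mRNA"],
        config.n_tumor_independent, config.n_normal_independent, config.noise_sd, "VAL",
    )

    truth = SyntheticTruth(
        seed=config.seed,
        noise_sd=config.noise_sd,
        effects=effects,
        planted_features=planted_features,
        shift_signs={lv: dict(shifts[lv]) for lv in LEVELS},
    )
    return SyntheticStudy(
        matrices=matrices,
        annotation=annotation,
        predictions=predictions,
        independent=independent,
        truth=truth,
        config=config,
        true_targets=true_targets,
    )
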