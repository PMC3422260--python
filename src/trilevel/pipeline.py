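"""One-shot pipeline: simulate/load -> build sets -> score -> rank -> downstream.

Every stage writes its result as a TSV before the next stage consumes it,
so a run can be inspected or restarted at any boundary, and a manifest
records the seed, configuration hash and library versions for
reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy

from . import __version__, io
from .datatypes import LEVELS, ValidationError
from .discriminate import score_all
from .downstream import high_frequency, hypergeom_enrichment, member_frequency, validate_independent
from .genesets import build_term_sets, consensus_targets, filter_terms, write_level_gmts
from .ranking import classify_groups, compare_levels, group_counts, overall_ranking, top_k
from .simulate import SimulationConfig, generate_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Defaults follow the published analysis: a microRNA-target consensus of
    3 tools, the top 300 dysfunctional sets, and a member-frequency
    threshold of 50.
    """

    output_dir: str = "trilevel_run"
    # input paths (ignored when simulate is set)
    matrix_paths: dict | None = None      # level -> matrix TSV
    label_paths: dict | None = None       # level -> label TSV
    annotation_path: str | None = None    # GMT
    predictions_path: str | None = None   # TSV
    independent_path: str | None = None   # matrix TSV
    independent_labels_path: str | None = None
    reference_path: str | None = None     # pathway gene list (optional)
    simulate: dict | None = None          # SimulationConfig overrides
    min_tools: int = 3
    min_size: int = 1
    top_k: int = 300
    freq_threshold: int = 50
    seed: int = 0
    log_level: str = "INFO"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute every pipeline stage and write all intermediate tables.

    Returns the manifest dict (also written to ``manifest.json``).  Reruns
    with an identical config reproduce byte-identical numeric tables.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    outputs: list[str] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = os.path.join(outdir, name)
        io.write_table(df, path)
        outputs.append(name)

    # --- inputs -----------------------------------------------------------
    @_stage("inputs")
    def load_inputs():
        if config.simulate is not None:
            sim = SimulationConfig(**{"seed": config.seed, **config.simulate})
            study = generate_study(sim)
            logger.info("simulated study: %d terms, %d genes, %d microRNAs",
                        sim.n_terms, sim.n_genes, sim.n_mirnas)
            bundle_dir = os.path.join(outdir, "inputs")
            os.makedirs(bundle_dir, exist_ok=True)
            for level, m in study.matrices.items():
                io.write_matrix(m, os.path.join(bundle_dir, f"{level}.tsv"),
                                os.path.join(bundle_dir, f"{level}.labels.tsv"))
            io.write_gmt(study.annotation, os.path.join(bundle_dir, "annotation.gmt"))
            io.write_predictions(study.predictions, os.path.join(bundle_dir, "predictions.tsv"))
            io.write_matrix(study.independent, os.path.join(bundle_dir, "independent.tsv"),
                            os.path.join(bundle_dir, "independent.labels.tsv"))
            io.write_table(study.truth.to_frame(), os.path.join(bundle_dir, "truth.tsv"))
            return study.matrices, study.annotation, study.predictions, study.independent
        matrices = {
            level: io.read_matrix(config.matrix_paths[level], level, config.label_paths[level])
            for level in LEVELS
        }
        annotation = io.read_gmt(config.annotation_path)
        if config.predictions_path is None or not os.path.exists(config.predictions_path):
            raise FileNotFoundError(
                f"prediction file not found: {config.predictions_path} "
                f"(required by the build-sets stage)"
            )
        predictions = io.read_predictions(config.predictions_path)
        independent = None
        if config.independent_path:
            independent = io.read_matrix(
                config.independent_path, "mRNA", config.independent_labels_path
            )
        return matrices, annotation, predictions, independent

    matrices, annotation, predictions, independent = load_inputs()

    # --- build-sets -------------------------------------------------------
    @_stage("build-sets")
    def build():
        targets = consensus_targets(predictions, min_tools=config.min_tools)
        sets = build_term_sets(
            annotation,
            meth_features=matrices["methylation"].feature_ids,
            mirna_features=matrices["microRNA"].feature_ids,
            mrna_features=matrices["mRNA"].feature_ids,
            targets=targets,
        )
        kept = filter_terms(sets, min_size=config.min_size)
        logger.info("build-sets: %d/%d terms have members at all three levels",
                    len(kept), len(sets))
        write_level_gmts(kept, outdir)
        return kept

    sets = build()

    # --- score ------------------------------------------------------------
    @_stage("score")
    def score():
        mcc_table = score_all(matrices, sets)
        emit(mcc_table.reset_index(), "mcc.tsv")
        logger.info("score: %d terms scored on %s", len(mcc_table),
                    {lv: matrices[lv].n_samples for lv in LEVELS})
        return mcc_table

    mcc_table = score()

    # --- rank + groups ----------------------------------------------------
    @_stage("rank")
    def rank():
        dysfunction = classify_groups(mcc_table)
        ranking = overall_ranking(dysfunction)
        emit(ranking, "dysfunction.tsv")
        emit(group_counts(dysfunction), "group_counts.tsv")
        emit(compare_levels(mcc_table), "level_comparison.tsv")
        counts = group_counts(dysfunction)["count"]
        logger.info("rank: six-group counts %s sum to %d of %d terms",
                    list(counts), int(counts.sum()), len(dysfunction))
        return ranking

    ranking = rank()

    # --- frequency --------------------------------------------------------
    @_stage("frequency")
    def frequency():
        k = min(config.top_k, len(ranking))
        if k < config.top_k:
            logger.warning("top_k=%d exceeds the %d available terms; using %d",
                           config.top_k, len(ranking), k)
        top = top_k(ranking, k)
        tables = {}
        for cls, name in (("gene_mrna", "frequency_mRNA.tsv"),
                          ("gene_methylation", "frequency_methylation.tsv"),
                          ("microRNA", "frequency_microRNA.tsv")):
            freq = member_frequency(top, sets, cls)
            emit(freq, name)
            tables[cls] = freq
        return top, tables

    top, freq_tables = frequency()

    # high-frequency genes: in either mRNA or methylation sets above threshold
    hf_genes = frozenset(
        high_frequency(freq_tables["gene_mrna"], config.freq_threshold)
        | high_frequency(freq_tables["gene_methylation"], config.freq_threshold)
    )
    hf_mirnas = high_frequency(freq_tables["microRNA"], config.freq_threshold)
    logger.info("frequency: %d high-frequency genes, %d high-frequency microRNAs",
                len(hf_genes), len(hf_mirnas))

    # --- enrich (optional) ------------------------------------------------
    enrichment_p = None
    if config.reference_path:
        @_stage("enrich")
        def enrich():
            reference = io.read_gene_list(config.reference_path)
            universe = frozenset(matrices["mRNA"].feature_ids)
            p = hypergeom_enrichment(hf_genes & universe, reference & universe, universe)
            emit(pd.DataFrame([{"n_high_frequency": len(hf_genes),
                                "n_reference": len(reference & universe),
                                "n_overlap": len(hf_genes & reference),
                                "universe": len(universe),
                                "p_value": p}]), "enrichment.tsv")
            return p
        enrichment_p = enrich()

    # --- validate ---------------------------------------------------------
    @_stage("validate")
    def validate():
        if independent is None:
            raise ValidationError("no independent cohort supplied")
        if not hf_genes:
            raise ValidationError(
                f"no gene exceeds frequency threshold {config.freq_threshold}; lower it"
            )
        m = validate_independent(hf_genes, independent)
        emit(pd.DataFrame([{"n_genes": len(hf_genes),
                            "n_samples": independent.n_samples,
                            "mcc": m}]), "validation.tsv")
        logger.info("validate: independent-cohort MCC %.4f on %d genes", m, len(hf_genes))
        return m

    validation_mcc = validate()

    manifest = {
        "package": "trilevel",
        "version": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_terms": len(sets),
        "top_k_effective": len(top),
        "validation_mcc": validation_mcc,
        "enrichment_p": enrichment_p,
        "outputs": outputs,
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
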