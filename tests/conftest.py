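import pytest

from trilevel import (
    SimulationConfig,
    build_term_sets,
    consensus_targets,
    filter_terms,
    generate_study,
    score_all,
)


@pytest.fixture(scope="session")
def study():
    """A small seeded study with one planted term per level."""
    cfg = SimulationConfig(
        seed=11,
        n_genes=150,
        n_mirnas=40,
        n_terms=15,
        n_tumor=15,
        n_normal=15,
        planted_effects=(
            (0, "mRNA", 3.0),
            (1, "methylation", 2.5),
            (2, "microRNA", 2.5),
        ),
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def study_sets(study):
    targets = consensus_targets(study.predictions, min_tools=3)
    sets = build_term_sets(
        study.annotation,
        meth_features=study.matrices["methylation"].feature_ids,
        mirna_features=study.matrices["microRNA"].feature_ids,
        mrna_features=study.matrices["mRNA"].feature_ids,
        targets=targets,
    )
    return filter_terms(sets, min_size=1)


@pytest.fixture(scope="session")
def study_mcc(study, study_sets):
    return score_all(study.matrices, study_sets)
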