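import pytest

from exotropy.simulate import SimulationConfig, generate_all

# noise <= effect/4 with >= 3 replicates and no missingness: every planted
# protein is separable, so planted-recovery checks are exact
SEPARABLE = {"noise_sd_log2": 0.25, "missing_rate": 0.0}


def small_config(**overrides):
    """Fast, reduced-size simulation config for unit tests."""
    base = dict(
        n_proteins=200,
        planted_common=40,
        planted_up=10,
        planted_down=10,
        n_ligands=60,
        n_receptors=50,
        n_pairs=80,
        n_multimeric_ligands=4,
        n_multimeric_receptors=5,
        n_atlas_genes=300,
        n_tissues=8,
        cohort_sizes={"stage1": 30, "stage4_nonBrM": 30, "stage4_BrM": 30},
        seed=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def separable_bundle():
    """Full-size study-condition fixture set in the separable regime."""
    cfg = SimulationConfig(
        seed=11, planted_organ_pairs={"brain": 5, "liver": 3}, **SEPARABLE
    )
    matrix, annotation, lrdb, atlas, cohort, truth = generate_all(cfg)
    return {
        "config": cfg,
        "matrix": matrix,
        "annotation": annotation,
        "lrdb": lrdb,
        "atlas": atlas,
        "cohort": cohort,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_bundle():
    cfg = small_config(seed=5, **SEPARABLE)
    matrix, annotation, lrdb, atlas, cohort, truth = generate_all(cfg)
    return {
        "config": cfg,
        "matrix": matrix,
        "annotation": annotation,
        "lrdb": lrdb,
        "atlas": atlas,
        "cohort": cohort,
        "truth": truth,
    }
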