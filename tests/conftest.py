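import warnings

import pytest

from broadres import SimulationConfig, compute_scores, select_decile_groups, simulate_panel


def mini_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A small panel that still exercises every downstream stage."""
    defaults = dict(
        n_lines=60,
        n_lineages=3,
        classes={
            "kinase_inhibitor": 20,
            "dna_damaging": 10,
            "unique_moa": 8,
            "epigenetic_modulator": 2,
        },
        n_genes=300,
        n_signature_genes=20,
        n_metabolites=60,
        n_shifted_metabolites=10,
        convergent_set_size=4,
        convergent_coverage=0.5,
        n_perturbagens=40,
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def mini_bundle():
    return simulate_panel(mini_config())


@pytest.fixture(scope="session")
def mini_scores(mini_bundle):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return compute_scores(mini_bundle.drug_response)


@pytest.fixture(scope="session")
def mini_groups(mini_scores):
    return select_decile_groups(mini_scores)


@pytest.fixture(scope="session")
def default_bundle():
    """The standard 200-line study panel (shared, read-only)."""
    return simulate_panel(SimulationConfig(seed=11))
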