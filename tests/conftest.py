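import numpy as np
import pytest

from mirpair.diffexp import call_differential, moderated_t_test
from mirpair.synthetic import DEFAULT_COMPARISONS, SimulationParams, simulate_dataset

N_RECOVERY_SEEDS = 20


@pytest.fixture(scope="session")
def recovery_runs():
    """Generator-default simulations with called DE tables for 20 seeds.

    Shared across the planted-truth recovery tests (DE, pairing, clustering,
    enrichment) so each simulation and moderated-t fit runs once.
    """
    runs = []
    for seed in range(N_RECOVERY_SEEDS):
        params = SimulationParams(seed=seed)
        mirna, mrna, design, targets, gene_sets, truth = simulate_dataset(params)
        de_mirna, de_mrna = {}, {}
        for cmp in DEFAULT_COMPARISONS:
            rm, _ = call_differential(moderated_t_test(mirna, design, cmp))
            rg, _ = call_differential(moderated_t_test(mrna, design, cmp))
            de_mirna[cmp.name] = rm
            de_mrna[cmp.name] = rg
        runs.append(
            {
                "seed": seed,
                "params": params,
                "mirna": mirna,
                "mrna": mrna,
                "design": design,
                "targets": targets,
                "gene_sets": gene_sets,
                "truth": truth,
                "de_mirna": de_mirna,
                "de_mrna": de_mrna,
            }
        )
    return runs


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_matrix(rng):
    from mirpair.core_data import ExpressionMatrix

    vals = rng.normal(7, 1.5, size=(12, 6))
    return ExpressionMatrix(
        [f"f{i}" for i in range(12)], [f"s{j}" for j in range(6)], vals, "log2"
    )


@pytest.fixture
def two_group_design():
    from mirpair.core_data import SampleDesign

    return SampleDesign(
        {"s0": "A", "s1": "A", "s2": "A", "s3": "B", "s4": "B", "s5": "B"},
        ["A", "B"],
    )
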