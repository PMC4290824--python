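import numpy as np
import pytest

from crisprank.io import CountTable, DesignSpec
from crisprank.normalization import median_normalize
from crisprank.sgrna_test import sgrna_test
from crisprank.simulator import SimConfig, simulate_screen
from crisprank.variance_model import fit_mean_variance, sample_moments

DESIGN_2X2 = DesignSpec(("control_1", "control_2"), ("treatment_1", "treatment_2"))


@pytest.fixture
def small_table() -> CountTable:
    return CountTable(
        sgrna_ids=["sg1", "sg2", "sg3", "sg4"],
        gene_ids=["GA", "GA", "GB", "GB"],
        sample_names=["c1", "t1"],
        counts=np.array([[10, 2], [12, 3], [9, 30], [11, 28]]),
    )


def random_table(rng: np.random.Generator, m: int = 20, n: int = 3) -> CountTable:
    return CountTable(
        sgrna_ids=[f"sg{i}" for i in range(m)],
        gene_ids=[f"G{i // 2}" for i in range(m)],
        sample_names=[f"s{j}" for j in range(n)],
        counts=rng.integers(0, 1000, size=(m, n)),
    )


def analysed_null_screen(seed: int, n_genes: int = 500, sgrnas_per_gene: int = 4):
    """Simulate a no-selection screen and run it through the sgRNA test."""
    table, truth = simulate_screen(
        SimConfig(n_genes=n_genes, sgrnas_per_gene=sgrnas_per_gene, seed=seed)
    )
    norm, _ = median_normalize(table)
    model = fit_mean_variance(
        sample_moments(norm, ["control_1", "control_2"])
    )
    results = sgrna_test(norm, DESIGN_2X2, model)
    return table, truth, norm, model, results


@pytest.fixture(scope="session")
def null_screen():
    return analysed_null_screen(seed=11)


@pytest.fixture(scope="session")
def spiked_screen():
    """Screen with 20 of 500 genes depleted 4-fold, analysed for depletion."""
    from crisprank.rra import AlphaConfig, gene_test

    table, truth = simulate_screen(
        SimConfig(
            n_genes=500,
            sgrnas_per_gene=4,
            fraction_neg=0.04,
            effect_size=4.0,
            seed=101,
        )
    )
    norm, _ = median_normalize(table)
    model = fit_mean_variance(sample_moments(norm, ["control_1", "control_2"]))
    results = sgrna_test(norm, DESIGN_2X2, model)
    genes = gene_test(results, AlphaConfig(seed=101), "neg")
    return truth, genes
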