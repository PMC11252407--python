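import numpy as np
import pandas as pd
import pytest

from osmoscreen.synthetic import (
    LabelSwapConfig,
    SyntheticScreenConfig,
    simulate_label_swap,
    simulate_screen,
)


@pytest.fixture(scope="session")
def small_screen():
    """A modest simulated screen with planted hits, shared across tests."""
    cfg = SyntheticScreenConfig(
        n_genes=200,
        alleles_per_gene=5,
        n_hit_genes=5,
        selection_coefficient=0.5,
        doublings=4,
        read_depth=2_000_000,
        seed=11,
    )
    counts, annotation, truth = simulate_screen(cfg)
    return cfg, counts, annotation, truth


@pytest.fixture(scope="session")
def noiseless_label_swap():
    cfg = LabelSwapConfig(n_peptides=40, n_changed=6, true_fold=4.0,
                          noise_sd=0.0, seed=3)
    return cfg, simulate_label_swap(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def plate_intensities():
    """The hand-computed Z-score example: wt {100,110,120}, mutant {80,90}."""
    return pd.DataFrame(
        {
            "row": [0, 0, 0, 1, 1],
            "col": [0, 1, 2, 0, 1],
            "genotype": ["wt", "wt", "wt", "mut", "mut"],
            "is_wt": [True, True, True, False, False],
            "intensity": [100.0, 110.0, 120.0, 80.0, 90.0],
        }
    )
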