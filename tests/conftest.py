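import numpy as np
import pytest

from mosppi.synthetic import (
    SyntheticConfig,
    generate_interactions,
    generate_proteome,
)

# The worked example: a 14-residue peptide and its 7-group digit encoding.
WORKED_SEQ = "AGCRQTSPLGVKSE"
WORKED_DIGITS = "11754332211536"


@pytest.fixture(scope="session")
def worked_example():
    return WORKED_SEQ, WORKED_DIGITS


@pytest.fixture(scope="session")
def random_group_sequences():
    """500 random group sequences, lengths 1..300 (fixed seed)."""
    rng = np.random.default_rng(20240501)
    return [
        rng.integers(1, 8, size=rng.integers(1, 301)) for _ in range(500)
    ]


@pytest.fixture(scope="session")
def small_synthetic_dataset():
    """A small planted-signal dataset shared by classifier tests."""
    cfg = SyntheticConfig(
        seed=11, n_proteins=400, n_pos=800, n_neg=800, effect=0.8
    )
    proteome = generate_proteome(cfg)
    positives, negatives = generate_interactions(proteome, cfg)
    return cfg, proteome, positives, negatives
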