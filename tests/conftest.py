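import numpy as np
import pytest

from cescan import PairCounts, count_pair, simulate_case_control, build_model


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def random_counts_tables(rng):
    """A batch of random 3x3x2 count tables, some with empty cells."""
    tables = []
    for rep in range(1200):
        t = rng.integers(0, 30, size=(3, 3, 2))
        if rep % 3 == 0:
            kill = rng.integers(0, 9, size=rng.integers(1, 4))
            t.reshape(9, 2)[kill] = 0
        tables.append(PairCounts(t))
    return tables


@pytest.fixture(scope="session")
def model1_spec():
    """Model 1 at MAF 0.1 solved for prevalence 0.1 and heritability 0.03."""
    return build_model(1, 0.1, 0.1, 0.03)


@pytest.fixture(scope="session")
def strong_pair_dataset(model1_spec):
    """Small dataset with one embedded strong epistatic pair (columns 3, 7)."""
    strong = build_model(1, 0.2, 0.1, 0.2)
    return simulate_case_control(
        strong, 400, 400, 30, seed=7, causal_indices=(3, 7)
    )


def perfect_model_counts(label_bits, n_low=50, n_high=50):
    """Counts with all controls spread over the low cells, cases over high cells."""
    from cescan import table_of_label

    table = table_of_label(label_bits)
    high = table.values.astype(bool)
    counts = np.zeros((3, 3, 2), dtype=np.int64)
    n_low_cells = int((~high).sum())
    n_high_cells = int(high.sum())
    counts[:, :, 0][~high] = n_low // n_low_cells
    counts[:, :, 1][high] = n_high // n_high_cells
    # distribute remainders deterministically
    low_idx = np.argwhere(~high)
    high_idx = np.argwhere(high)
    for k in range(n_low % n_low_cells):
        counts[low_idx[k][0], low_idx[k][1], 0] += 1
    for k in range(n_high % n_high_cells):
        counts[high_idx[k][0], high_idx[k][1], 1] += 1
    return PairCounts(counts)
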