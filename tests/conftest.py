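import numpy as np
import pytest

from qpcreff import DilutionTable, PrimerEfficiencyModel, default_array_spec, simulate_table

FOUR_LEVELS = np.array([1.0, 0.1, 0.01, 0.001])


def make_table(rows: dict[str, list[float]], levels=FOUR_LEVELS) -> DilutionTable:
    """Build a small table from {primer: ct values}; None marks missing."""
    grid = np.array(
        [[np.nan if v is None else v for v in cts] for cts in rows.values()],
        dtype=float,
    )
    return DilutionTable(tuple(rows), np.asarray(levels, dtype=float), grid)


def exact_curve(efficiency: float, beta0: float, levels=FOUR_LEVELS) -> list[float]:
    """Noise-free CT values for a given true efficiency and intercept."""
    slope = -1.0 / np.log2(efficiency)
    return list(beta0 + slope * np.log2(levels))


def rand_index(labels_a, labels_b) -> float:
    """Plain Rand index: fraction of pairs on which two partitions agree."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = a.size
    agree = 0
    for i in range(n):
        for j in range(i + 1, n):
            agree += (a[i] == a[j]) == (b[i] == b[j])
    return agree / (n * (n - 1) / 2)


@pytest.fixture(scope="session")
def array_fixture():
    """Deterministic default-scale array: 96 primers, 7 groups, defects 3/8/7."""
    return simulate_table(default_array_spec(seed=42))


@pytest.fixture(scope="session")
def array_results(array_fixture):
    table, _ = array_fixture
    return PrimerEfficiencyModel(table).fit()
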