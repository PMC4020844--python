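import numpy as np
import pytest

import toxsig as ts


@pytest.fixture
def golub_example():
    """One gene, class means 2.0 vs 0.0 with sample SDs 0.2 and 0.1."""
    matrix = ts.FoldChangeMatrix.from_arrays(
        np.array([[2.0, 2.2, 1.8, 0.1, -0.1, 0.0]]), ["g1"], list("abcdef")
    )
    labels = ts.CompoundLabelSet(
        {c: ("NGC" if c in "abc" else "NC") for c in "abcdef"}
    )
    return matrix, labels


@pytest.fixture(scope="session")
def small_sim():
    """Modest synthetic dataset with all planted populations (fast tests)."""
    config = ts.SimulationConfig(n_genes=600, seed=0)
    return ts.simulate_tox_dataset(config)


@pytest.fixture(scope="session")
def planted_one_gene():
    """100 near-noise genes plus one hugely separating gene (effect 5 noise SDs)."""
    rng = np.random.default_rng(42)
    genes = [f"g{i:03d}" for i in range(101)]
    compounds = [f"c{i:02d}" for i in range(10)]
    values = rng.normal(0.0, 0.2, size=(101, 10))
    values[0, :5] += 5 * 0.2 + 1.0  # planted in the primary class only
    matrix = ts.FoldChangeMatrix.from_arrays(values, genes, compounds)
    labels = ts.CompoundLabelSet(
        {c: ("NGC" if i < 5 else "NC") for i, c in enumerate(compounds)}
    )
    return matrix, labels, "g000"
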