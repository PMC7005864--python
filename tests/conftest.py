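import numpy as np
import pytest

from scbudget import CountMatrix, GammaPrior, GeneratorSpec, sample_counts


@pytest.fixture
def tiny_counts():
    """2 cells x 3 genes with known totals (100, 300)."""
    values = np.array([[10, 40, 50],
                       [60, 140, 100]])
    return CountMatrix(values, ["c1", "c2"], ["gA", "gB", "gC"])


@pytest.fixture
def gamma_poisson_data():
    """Overdispersed synthetic data with exact truth (20k cells, 4 genes)."""
    spec = GeneratorSpec.single(GammaPrior(2.0, 0.5), depth=2.0, n_genes=4,
                                size_factor_sigma=0.3, seed=11)
    cm, truth = sample_counts(spec, 20000)
    return cm, truth
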