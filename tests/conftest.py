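import numpy as np
import pytest

from heritsim import simdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_count_data(rng):
    """A small integer genotype data set with known structure."""
    spec = simdata.LDStructureSpec("independent", m=8)
    freqs = simdata.draw_allele_freqs(spec.n_base, rng)
    return simdata.sim_genotypes(30, spec, freqs, seed=rng)


def mc_mean_se(values):
    """Replicate mean and its Monte-Carlo standard error."""
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))
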