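"""Shared fixtures: small genotype matrices on disk and reusable ensembles."""

import numpy as np
import pytest

import eigenratio as er


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def random_genotypes(rng):
    """Random 20 x 200 genotype matrix with moderate allele frequencies."""
    freqs = rng.uniform(0.1, 0.5, 200)
    return (rng.random((20, 200)) < freqs).astype(np.int8) + (rng.random((20, 200)) < freqs)


@pytest.fixture()
def npy_pair(tmp_path, rng):
    """Two NPY files sharing 4 individuals: shapes 4x10 and 4x15."""
    a = rng.integers(0, 3, (4, 10)).astype(np.float64)
    b = rng.integers(0, 3, (4, 15)).astype(np.float64)
    pa, pb = tmp_path / "a.npy", tmp_path / "b.npy"
    np.save(pa, a)
    np.save(pb, b)
    return (pa, a), (pb, b)


@pytest.fixture(scope="session")
def shared_ensemble_150():
    """One 150-dim GOE ensemble reused across recovery-rate tests."""
    return er.simulate_ensemble(n=150, rep=1000, seed=424242)
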