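import numpy as np
import pytest

from bcellmap.core_io import IntensityMatrix, SampleDesign


def make_design(pops=("naive", "CB"), reps=2):
    if isinstance(reps, int):
        reps = {p: reps for p in pops}
    return SampleDesign(tuple(pops), reps)


def random_intensity_matrix(rng, n_proteins=30, pops=("A", "B", "C"), reps=3, zero_fraction=0.3):
    """Random non-negative matrix with a controllable share of exact zeros."""
    design = make_design(pops, reps)
    values = np.exp(rng.normal(5, 1, size=(n_proteins, design.n_samples)))
    values[rng.random(values.shape) < zero_fraction] = 0.0
    ids = [f"P{i}" for i in range(n_proteins)]
    return IntensityMatrix(protein_ids=ids, design=design, values=values)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
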