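import numpy as np
import pytest

from gmi import LabeledExpressionMatrix, PlantedMarker, SyntheticSpec, generate


def bct_oracle(values, flags):
    """Independent BCT count: stable descending sort, adjacency scan."""
    values = np.asarray(values, dtype=float)
    flags = np.asarray(flags).astype(bool)
    order = sorted(range(values.size), key=lambda i: (-values[i], i))
    seq = [flags[i] for i in order]
    return sum(a != b for a, b in zip(seq, seq[1:]))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_class_perfect():
    """One gene with all class-1 values 1 and all class-2 values 0."""
    return LabeledExpressionMatrix(
        values=np.r_[np.ones(5), np.zeros(5)][None, :],
        gene_ids=("g1",),
        sample_ids=tuple(f"s{i}" for i in range(10)),
        labels=np.r_[[1] * 5, [2] * 5],
    )


@pytest.fixture
def small_planted():
    """3-class matrix with one dominant level-1 marker plus noise genes."""
    spec = SyntheticSpec(
        class_sizes=(8, 8, 8),
        planted=(PlantedMarker(upper=(2,), noise_sd=0.1),),
        n_noise_genes=30,
        seed=3,
    )
    return generate(spec)
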