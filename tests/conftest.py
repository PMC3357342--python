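import numpy as np
import pandas as pd
import pytest

from mirlink.containers import ExpressionMatrix, GroupDesign


@pytest.fixture
def design8():
    """8 vs 8 two-group design matching the emulated study size."""
    return GroupDesign.from_samples(
        [f"SF{i}" for i in range(8)], [f"C{i}" for i in range(8)]
    )


@pytest.fixture
def design2():
    return GroupDesign.from_samples(["e1", "e2"], ["c1", "c2"])


def make_matrix(values, features=None, samples=None, kind="gene", detected=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"F{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    det = (
        pd.DataFrame(detected, index=features, columns=samples)
        if detected is not None
        else None
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=features, columns=samples), kind, det
    )


@pytest.fixture
def make_expr():
    return make_matrix


def random_matrix(rng, n_features, samples, loc=8.0, scale=1.0, kind="gene"):
    vals = rng.normal(loc, scale, size=(n_features, len(samples)))
    return make_matrix(vals, samples=list(samples), kind=kind)


@pytest.fixture
def random_expr():
    return random_matrix
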