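import numpy as np
import pytest

from pcadea import DEAInstance


@pytest.fixture
def four_accessions():
    """1-input/1-output VRS instance whose frontier is {A, B, C}; D sits
    inside it with a radial score of exactly 2."""
    return DEAInstance(
        accession_ids=("A", "B", "C", "D"),
        X=[[1.0, 2.0, 3.0, 2.0]],
        Y=[[1.0, 3.0, 3.5, 1.5]],
        input_trait_names=("x",),
        output_trait_names=("y",),
        scale="VRS",
    )


@pytest.fixture
def weakly_efficient_pair():
    """Equal outputs, different inputs: accession 2 has theta 1 but a
    positive input slack (weakly efficient)."""
    return DEAInstance(
        accession_ids=("a1", "a2"),
        X=[[1.0, 2.0]],
        Y=[[1.0, 1.0]],
        input_trait_names=("x",),
        output_trait_names=("y",),
        scale="VRS",
    )


def random_instance(rng, s=None, m=None, n=None, scale="VRS", low=0.5, high=10.0):
    """Random strictly positive instance with entries in [low, high]."""
    s = s if s is not None else int(rng.integers(2, 16))
    m = m if m is not None else int(rng.integers(1, 5))
    n = n if n is not None else int(rng.integers(1, 5))
    X = rng.uniform(low, high, size=(m, s))
    Y = rng.uniform(low, high, size=(n, s))
    return DEAInstance(
        accession_ids=tuple(f"a{i}" for i in range(s)),
        X=X,
        Y=Y,
        input_trait_names=tuple(f"x{i}" for i in range(m)),
        output_trait_names=tuple(f"y{j}" for j in range(n)),
        scale=scale,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
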