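import numpy as np
import pytest

from neurocascade import ShiftedGamma, load_best_fit_params, load_observed
from neurocascade.transition import TransitionMatrix


@pytest.fixture(scope="session")
def best_fit():
    return load_best_fit_params()


@pytest.fixture(scope="session")
def observed():
    return load_observed()


def make_toy_chain():
    """A -> B -> C chain with per-stage survival; C-leavers vanish.

    Sub-stochastic rows, so the generic single-offspring Monte-Carlo
    simulator applies and serves as an independent oracle for the
    renewal-equation solver.
    """
    m = np.array(
        [
            [0.0, 0.8, 0.0],
            [0.0, 0.0, 0.6],
            [0.0, 0.0, 0.0],
        ]
    )
    durations = [
        ShiftedGamma(2.0, 3.0, 1.0),
        ShiftedGamma(1.5, 4.0, 0.5),
        ShiftedGamma(3.0, 2.0, 0.0),
    ]
    return TransitionMatrix(
        labels=["A", "B", "C"],
        m=m,
        durations=durations,
        classes=["NSC", "ANP", "NB"],
    )


@pytest.fixture()
def toy_chain():
    return make_toy_chain()
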