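import numpy as np
import pytest

import autograd.numpy as anp

from difi import nn
from difi.models import Classifier, ClassifierSpec


class LinearSoftmax(Classifier):
    """Single-layer linear-softmax model with a closed-form input gradient."""

    input_kind = "vector"

    def __init__(self, weight: np.ndarray, bias: np.ndarray):
        spec = ClassifierSpec("tiny_cnn", n_classes=weight.shape[1],
                              input_shape=(weight.shape[0],))
        super().__init__(spec, [np.asarray(weight, float), np.asarray(bias, float)])

    def forward(self, params, x):
        return anp.dot(x, params[0]) + params[1]


class FakeTapModel(Classifier):
    """Returns a fixed activation tensor at tap 'probe'; for map-shape tests."""

    input_kind = "one_hot"

    def __init__(self, activation: np.ndarray, input_len: int, alphabet: int = 20):
        spec = ClassifierSpec("tiny_cnn", n_classes=2, input_shape=(alphabet, input_len))
        super().__init__(spec, [np.zeros(1)])
        self._activation = np.asarray(activation, float)

    def forward(self, params, x):
        return np.zeros((x.shape[0], 2))

    def forward_with_taps(self, params, x):
        return self.forward(params, x), {"probe": self._activation[None]}


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_model():
    """Small two-layer model over 8 features, 3 classes."""
    from difi.models import make_classifier
    spec = ClassifierSpec("tiny_cnn", n_classes=3, input_shape=(8,), width=4)
    return make_classifier(spec, seed=7)


@pytest.fixture
def linear_model(rng):
    return LinearSoftmax(rng.standard_normal((6, 3)), rng.standard_normal(3))


@pytest.fixture(scope="session")
def small_expression():
    """3-class expression dataset with 2 planted biomarkers per class."""
    from difi.synthetic import SyntheticExpressionSpec, simulate_expression_dataset
    spec = SyntheticExpressionSpec(
        n_classes=3, n_genes=120, n_biomarkers_per_class=2, effect_size=3.0,
        noise_sd=1.0, n_samples_per_class=40, seed=11,
    )
    return simulate_expression_dataset(spec)


@pytest.fixture(scope="session")
def small_sequences():
    """Two-class sequence dataset with a planted 3-site motif."""
    from difi.synthetic import SyntheticSequenceSpec, simulate_sequence_dataset
    spec = SyntheticSequenceSpec(
        n_positive=30, n_negative=30, length_range=(40, 60), seed=5,
    )
    return simulate_sequence_dataset(spec)
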