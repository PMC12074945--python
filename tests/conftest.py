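import numpy as np
import pytest

import fitrx as fx
from fitrx.corpus import synth_teacher_corpus


@pytest.fixture(scope="session")
def teacher_data():
    """Noise-free corpus from a random same-architecture teacher network."""
    rng = np.random.default_rng(3)
    X, Y, teacher = synth_teacher_corpus(300, rng)
    return X, Y, teacher


@pytest.fixture(scope="session")
def teacher_fit(teacher_data):
    """Student trained to convergence on the realizable teacher targets
    (validation = training set, so early stopping cannot cut the tail)."""
    X, Y, _ = teacher_data
    cfg = fx.TrainConfig(alpha=0.0, max_epochs=600, patience=600, error_precision=1e-8)
    net = fx.init_network(fx.LayerSpec(), np.random.default_rng(9))
    return fx.train(net, X[:240], Y[:240], X[:240], Y[:240], cfg)


@pytest.fixture(scope="session")
def teacher_cv(teacher_data):
    """Nested cross-validation on the teacher corpus at reduced scale
    (small grid, 3 inner folds, reduced epoch caps)."""
    X, Y, _ = teacher_data
    grid = fx.GridSpec(eta=(0.01,), beta=(0.9,), alpha=(0.0, 0.001))
    base = fx.TrainConfig(alpha=0.0, max_epochs=120, patience=20, error_precision=1e-9)
    inner = fx.TrainConfig(alpha=0.0, max_epochs=30, patience=10, error_precision=1e-9)
    return fx.nested_cv(X, Y, grid, base, seed=5, n_outer=10, n_inner=3, inner_cfg=inner)


@pytest.fixture(scope="session")
def surface_data():
    """Smooth hand-designed response surface over realistic subject ranges."""
    rng = np.random.default_rng(11)
    return fx.synth_response_surface(400, rng)


@pytest.fixture(scope="session")
def surface_model(surface_data):
    """Network fitted to the noise-free response surface with min-max
    input scaling (raw physiological scales saturate tanh otherwise)."""
    X, Y, _ = surface_data
    cfg = fx.TrainConfig(alpha=0.0, max_epochs=400, patience=80, error_precision=1e-9)
    net = fx.init_network(fx.LayerSpec(), np.random.default_rng(4))
    net.set_input_scaling(X[:320])
    result = fx.train(net, X[:320], Y[:320], X[320:], Y[320:], cfg)
    assert result.history.train_mse.iloc[-1] < 1e-3  # fixture sanity
    return result.state
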