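import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from estrocycle import classifier, preprocess, synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_render_params():
    """Noise-free, untinted renders for oracle tests."""
    return synthetic.CellRenderParams(
        noise_sd=0.0, stain_tints={"other": (1.0, 1.0, 1.0)}
    )


@pytest.fixture(scope="session")
def dataset200(tmp_path_factory):
    """Rendered balanced dataset at the generator's default study scale."""
    out = tmp_path_factory.mktemp("ds200")
    return synthetic.generate_dataset(200, out_dir=out, seed=0)


@pytest.fixture(scope="session")
def split200(dataset200):
    return preprocess.split_dataset(dataset200, seed=0)


@pytest.fixture(scope="session")
def trained200(split200):
    """smallcnn trained with the from-scratch preset, seed 0."""
    cfg = classifier.smallcnn_config(seed=0)
    model = classifier.build_model(cfg)
    return classifier.train(model, split200, cfg)


@pytest.fixture(scope="session")
def heldout200(split200, trained200):
    """Preprocessed held-out (test partition) arrays for the session model."""
    from estrocycle.classifier import _prepare_dataset

    X, y = _prepare_dataset(split200.test, trained200.model, trained200.config)
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
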