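import numpy as np
import pytest

from emghand import acquire, classifier, features, frontend, synth


@pytest.fixture(scope="session")
def default_params():
    return synth.SynthParams(seed=1)


@pytest.fixture(scope="session")
def default_config():
    return frontend.FrontendConfig()


@pytest.fixture(scope="session")
def full_protocol_dataset(default_params, default_config):
    """The full acquisition protocol: 5 gestures x 50 trials -> features.

    Session-scoped because several tests reuse the same deterministic
    dataset; everything downstream of it is pure.
    """
    session = synth.generate_session({"per_class_trials": 50, "points": 500},
                                     default_params)
    digitized = [frontend.full_chain(sig, default_config) for sig, _ in session]
    windowed = acquire.collect_dataset(digitized, per_class=50)
    return windowed, features.batch_extract(windowed)


@pytest.fixture(scope="session")
def trained_lm(full_protocol_dataset):
    """LM-trained 20-15-5 model on the 60/40 split of the default protocol."""
    _, dataset = full_protocol_dataset
    data, scaler = classifier.make_split(dataset, [0.6, 0.4], seed=1)
    model = classifier.init_model(1)
    report = classifier.train(model, data, classifier.TrainHyper(seed=1))
    return report, scaler, data


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
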