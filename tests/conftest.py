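import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tmidr.model import EnsembleConfig, MembraneDisorderEnsemble, TrainingConfig
from tmidr.synthetic import SyntheticScenario, generate_corpus

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_corpus():
    """40-protein corpus under the default study conditions (fixed seed)."""
    return generate_corpus(SyntheticScenario(n_proteins=40, seed=7))


@pytest.fixture(scope="session")
def tiny_ensemble(small_corpus):
    """Quickly trained ensemble for contract tests (routing, persistence,
    prediction plumbing); accuracy-grade training lives in the acceptance
    suite."""
    cfg = EnsembleConfig(
        cnn=TrainingConfig(max_epochs=15, seed=7),
        smoother=TrainingConfig(lr=3e-3, batch_size=256, max_epochs=6, seed=7),
        seed=7,
    )
    model = MembraneDisorderEnsemble(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(small_corpus.proteins, small_corpus.profiles,
                  small_corpus.rsas)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
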