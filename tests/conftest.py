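"""Shared fixtures: one synthetic campaign dataset reused across the suite."""

import warnings

import numpy as np
import pytest

from lipal import chemio, model, synthdata

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic lipid campaign dataset (257 molecules, ~60% positive)."""
    return synthdata.generate_dataset()


@pytest.fixture(scope="session")
def fingerprints(dataset):
    """Count-fingerprint matrix of the session dataset."""
    return chemio.fingerprint_matrix(dataset.records)


@pytest.fixture(scope="session")
def fitted_ensemble(dataset, fingerprints):
    """An ensemble fitted on the first 120 molecules of the session dataset."""
    return model.fit_ensemble(
        fingerprints[:120], dataset.labels[:120], model.EnsembleConfig(base_seed=7)
    )


@pytest.fixture(scope="session")
def posterior(fitted_ensemble, fingerprints):
    """Posterior draws for 60 held-out molecules of the session dataset."""
    return fitted_ensemble.posterior_draws(fingerprints[120:180])


def random_posterior(rng: np.random.Generator, n: int, n_draws: int = 40):
    """A random PosteriorSamples matrix for property sweeps."""
    # beta-distributed probabilities give a mix of confident and uncertain rows
    probs = rng.beta(rng.uniform(0.3, 3), rng.uniform(0.3, 3), size=(n, n_draws))
    return model.PosteriorSamples(probs=probs)
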