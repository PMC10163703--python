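"""Shared fixtures and dataset builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from bmdkit import (
    DoseResponseSpec,
    ExposureModel,
    GeneratorConfig,
    IndividualDataset,
    ModelParameters,
    generate,
)

#: canonical synthetic conditions for fitting simulations
CANON_BETA = -0.05
CANON_SIGMA = 0.5


def linear_truth(beta=CANON_BETA, sigma2=CANON_SIGMA**2, alpha=()):
    return ModelParameters(
        alpha0=1.0,
        alpha=np.asarray(alpha, float),
        drs=DoseResponseSpec.linear(beta),
        sigma2=sigma2,
    )


def uniform_config(n, truth, low=0.0, high=20.0):
    """Single uniform dose column on [low, high]."""
    return GeneratorConfig(
        n=n, truth=truth, exposure=ExposureModel(kind="uniform", low=low, high=high)
    )


def exchangeable_config(n, truth, **kwargs):
    """Four exchangeable log-normal exposures (equal medians)."""
    return GeneratorConfig(
        n=n, truth=truth, exposure=ExposureModel(medians=(5.0, 5.0, 5.0, 5.0)),
        **kwargs,
    )


def noiseless_dataset(spec: DoseResponseSpec, n=100, seed=0, high=20.0,
                      alpha0=1.0) -> IndividualDataset:
    """Deterministic outcome y = alpha0 + f(d) at uniform doses, no noise."""
    from bmdkit import evaluate_f

    d = np.random.default_rng(seed).uniform(0.0, high, n)
    return IndividualDataset(y=alpha0 + evaluate_f(spec, d), dose=d)


@pytest.fixture(scope="session")
def noisy_linear_data():
    """One canonical noisy linear dataset (n=500, beta=-0.05, sigma=0.5)."""
    return generate(uniform_config(500, linear_truth()), seed=0)


@pytest.fixture(scope="session")
def pfas_data():
    """Four-exposure cohort with an equal-potency (summed-index) truth."""
    truth = linear_truth(beta=-0.02, alpha=(0.3,))
    return generate(GeneratorConfig(n=500, truth=truth), seed=0)
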