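"""Shared fixtures.

The expensive end-to-end objects (synthetic recovery ensembles, the paired
method comparison) are session-scoped so that every test interrogating them
shares one computation.  All seeds are fixed constants: the suite is fully
deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

from hopffit import FitConfig, ModelParameters, simulate
from hopffit.synth import (
    NetworkSpec,
    compare_methods,
    run_recovery_experiment,
)

# study-condition ensemble: N=90 WS connectomes at 35% density, T=200 TRs
ENSEMBLE_SEED = 2025
LOSS_ENSEMBLE_SEED = 17


@pytest.fixture(scope="session")
def recovery_ensemble():
    """Ten synthetic subjects fitted end-to-end with the adaptive pipeline."""
    return run_recovery_experiment(
        10, NetworkSpec(), FitConfig(), seed=ENSEMBLE_SEED
    )


@pytest.fixture(scope="session")
def method_comparison(recovery_ensemble):
    """Paired adaptive-vs-traditional comparison on the same ten subjects."""
    return compare_methods(
        10, NetworkSpec(), FitConfig(), seed=ENSEMBLE_SEED,
        adaptive_report=recovery_ensemble,
    )


@pytest.fixture(scope="session")
def loss_agreement_ensemble():
    """Twenty lighter recovery runs for loss-argmin agreement statistics."""
    return run_recovery_experiment(
        20,
        NetworkSpec(n=60),
        FitConfig(max_iters=150),
        seed=LOSS_ENSEMBLE_SEED,
        n_samples=150,
    )


@pytest.fixture(scope="session")
def small_series():
    """A short 12-region simulated series for feature/FCD unit tests."""
    n = 12
    rng = np.random.default_rng(99)
    params = ModelParameters(
        a=rng.uniform(-1, 1, n),
        G=0.0,
        omega=2 * np.pi * rng.uniform(0.01, 0.1, n),
        tr=2.0,
        duration=240.0,
        seed=99,
    )
    from hopffit import WeightedConnectome

    return simulate(params, WeightedConnectome(np.zeros((n, n))))
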