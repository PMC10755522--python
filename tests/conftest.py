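import numpy as np
import pytest

from braingap import BAEConfig, CohortSpec, generate_cohort


def fast_bae_config(seed: int = 0, n_outer: int = 5) -> BAEConfig:
    """Reduced candidate grid for unit tests that exercise the nested-CV
    mechanics rather than model selection breadth."""
    return BAEConfig(
        n_outer_folds=n_outer,
        n_inner_folds=3,
        candidate_algorithms=("SVR",),
        hyperparameter_grid={
            "SVR": [
                {"kernel": "linear", "C": c, "epsilon": 0.1} for c in (0.01, 0.1, 1.0, 100.0)
            ]
        },
        seed=seed,
    )


@pytest.fixture(scope="session")
def cn_cohort():
    """Noisy cognitively-normal cohort, default calibration (MAE ~ 2.5 y)."""
    return generate_cohort(CohortSpec(n_subjects=150, seed=42))


@pytest.fixture(scope="session")
def noiseless_cohort():
    return generate_cohort(CohortSpec(n_subjects=100, noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def fitted_ensemble(cn_cohort):
    from braingap import fit_nested

    return fit_nested(cn_cohort, fast_bae_config(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
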