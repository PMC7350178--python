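import numpy as np
import pytest

from survselect import SimulationScenario, SurvivalDataset, generate_dataset


def brute_force_partial_loglik(beta, X, time, event) -> float:
    """Term-by-term evaluation of the Cox partial log-likelihood (Breslow
    ties): for each event, the subject's linear predictor minus the log-sum
    of exponentiated predictors over everyone still at risk."""
    beta = np.atleast_1d(np.asarray(beta, float))
    X = np.atleast_2d(np.asarray(X, float))
    eta = X @ beta
    total = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            total += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return total


@pytest.fixture
def toy3():
    """Three subjects, distinct event times, a single irrelevant covariate."""
    return SurvivalDataset(
        covariates=np.zeros((3, 1)),
        time=np.array([1.0, 2.0, 3.0]),
        event=np.array([1, 1, 1]),
    )


@pytest.fixture
def toy4():
    """Four subjects, one covariate, one censored."""
    return SurvivalDataset(
        covariates=np.array([[0.5], [-1.0], [2.0], [0.0]]),
        time=np.array([2.0, 5.0, 1.0, 4.0]),
        event=np.array([1, 0, 1, 1]),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A 200 x 50 cohort with 4 active genes; cheap enough for selector tests."""
    return generate_dataset(
        SimulationScenario(n_subjects=200, n_active=4, n_covariates=50, seed=42)
    )


@pytest.fixture(scope="session")
def medium_sim():
    """A 300 x 120 cohort with 12 active genes for path/CV behaviour."""
    return generate_dataset(
        SimulationScenario(n_subjects=300, n_active=12, n_covariates=120, seed=7)
    )
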