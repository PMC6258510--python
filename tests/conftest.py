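import numpy as np
import pytest

from tagm.core import Hyperparameters
from tagm.synthetic import generate_tagm_dataset, make_marker_annotation, separated_means


def make_dataset(K, D, N, separation, epsilon, marker_fraction, seed):
    """Well-separated unit-covariance mixture with a flat t outlier
    component centred on the niche cloud; the standard fixture recipe."""
    means = separated_means(K, D, separation, 1.0, seed=seed)
    covs = np.stack([np.eye(D)] * K)
    between = np.cov(means, rowvar=False) if K > 1 else np.eye(D)
    V = 0.5 * (between + np.eye(D))
    matrix, truth = generate_tagm_dataset(
        K=K, D=D, N=N, pi=np.full(K, 1.0 / K), epsilon=epsilon,
        means=means, covariances=covs, kappa=4.0, M=means.mean(axis=0), V=V,
        seed=seed + 1,
    )
    markers = make_marker_annotation(truth, matrix, marker_fraction, seed=seed + 2)
    return matrix, truth, markers


@pytest.fixture(scope="session")
def small_dataset():
    """K=3, D=4, N=300, very well separated; quick end-to-end checks."""
    return make_dataset(K=3, D=4, N=300, separation=8.0, epsilon=0.05,
                        marker_fraction=0.3, seed=7)


@pytest.fixture(scope="session")
def recovery_dataset():
    """K=4, D=6, N=2000, 6-sigma separation, 5% outliers, 20% markers."""
    return make_dataset(K=4, D=6, N=2000, separation=6.0, epsilon=0.05,
                        marker_fraction=0.2, seed=42)


@pytest.fixture()
def hyper_1d():
    """Hand-pickable one-fraction prior used by arithmetic oracles."""
    return Hyperparameters(
        beta=np.ones(2), mu0=np.zeros(1), lambda0=0.01, nu0=3.0,
        S0=np.eye(1), u=2.0, v=10.0, kappa=4.0, M=np.zeros(1), V=np.eye(1),
    )
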