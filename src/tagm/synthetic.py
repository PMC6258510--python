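"""Synthetic fractionation-profile datasets with known ground truth.

Samples directly from the generative model: each protein draws a niche
label z ~ Categorical(pi) and an outlier indicator phi ~ Bernoulli(1-eps);
non-outliers (phi = 1) draw their profile from the niche Gaussian
N(mu_z, Sigma_z), outliers (phi = 0) from the shared heavy-tailed
Student-t(kappa, M, V). These datasets emulate the structure of
LOPIT/hyperLOPIT quantitation tables (proteins x fractions) and stand in
for real maps in every test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ComponentParams, ExpressionMatrix, Hyperparameters, MarkerAnnotation

__all__ = [
    "SyntheticTruth",
    "generate_tagm_dataset",
    "separated_means",
    "make_marker_annotation",
]


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated dataset.

    phi = 1 rows were drawn from their class Gaussian, phi = 0 rows from
    the t outlier component (z is still drawn for outliers — the label is
    latent but carries no Gaussian membership).
    """

    z: np.ndarray            # (N,) class indices
    phi: np.ndarray          # (N,) binary, 1 = niche member, 0 = outlier
    params: ComponentParams
    hyper: Hyperparameters | None
    seed: int

    @property
    def n_classes(self) -> int:
        return self.params.n_classes


def generate_tagm_dataset(
    K: int,
    D: int,
    N: int,
    pi: np.ndarray,
    epsilon: float,
    means: np.ndarray,
    covariances: np.ndarray,
    kappa: float,
    M: np.ndarray,
    V: np.ndarray,
    seed: int,
    compositional: bool = False,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw N profiles from the t-augmented Gaussian mixture.

    ``compositional=True`` applies a per-row softmax afterwards, mimicking
    the sum-to-one normalisation of relative quantitation; off by default
    because the model itself lives on unconstrained real profiles.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (K,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-10:
        raise ValueError("pi must be a K-simplex")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    params = ComponentParams(
        means=np.asarray(means, dtype=float),
        covariances=np.asarray(covariances, dtype=float),
        weights=pi,
        epsilon=float(epsilon),
    )  # validates simplex/PD
    M = np.asarray(M, dtype=float)
    V = np.asarray(V, dtype=float)
    rng = np.random.default_rng(seed)
    z = rng.choice(K, size=N, p=pi)
    phi = (rng.random(N) >= epsilon).astype(int)  # P(phi=0) = epsilon
    X = np.empty((N, D))
    for k in range(K):
        idx = np.where((z == k) & (phi == 1))[0]
        if idx.size:
            X[idx] = rng.multivariate_normal(params.means[k], params.covariances[k], size=idx.size)
    out_idx = np.where(phi == 0)[0]
    if out_idx.size:
        # t draw: location + normal / sqrt(chi2_kappa / kappa)
        g = rng.chisquare(kappa, size=out_idx.size) / kappa
        normals = rng.multivariate_normal(np.zeros(D), V, size=out_idx.size)
        X[out_idx] = M + normals / np.sqrt(g)[:, None]
    if compositional:
        ex = np.exp(X - X.max(axis=1, keepdims=True))
        X = ex / ex.sum(axis=1, keepdims=True)
    matrix = ExpressionMatrix(
        values=X,
        protein_ids=tuple(f"P{i:05d}" for i in range(N)),
        fraction_ids=tuple(f"F{j + 1}" for j in range(D)),
    )
    truth = SyntheticTruth(z=z, phi=phi, params=params, hyper=None, seed=int(seed))
    return matrix, truth


def separated_means(
    K: int, D: int, separation: float, base_scale: float, seed: int, max_tries: int = 200
) -> np.ndarray:
    """K niche centres in R^D with pairwise distance >= separation * base_scale.

    Rejection-sampled from a Gaussian cloud whose spread grows with each
    failed attempt; raises if no admissible configuration is found within
    ``max_tries``.
    """
    if K < 1 or D < 1:
        raise ValueError("K and D must be >= 1")
    target = separation * base_scale
    rng = np.random.default_rng(seed)
    for attempt in range(max_tries):
        spread = target * (1.0 + 0.25 * attempt) * max(1.0, K ** (1.0 / D))
        means = rng.normal(scale=spread, size=(K, D))
        if K == 1:
            return means
        dists = np.linalg.norm(means[:, None, :] - means[None, :, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        if dists.min() >= target:
            return means
    raise RuntimeError(
        f"could not place {K} means with pairwise separation {target} in {max_tries} tries"
    )


def make_marker_annotation(
    truth: SyntheticTruth,
    matrix: ExpressionMatrix,
    marker_fraction: float,
    seed: int,
    class_names: tuple[str, ...] | None = None,
) -> MarkerAnnotation:
    """Designate a seeded per-class sample of non-outlier proteins as markers.

    Mirrors real marker curation: markers are unambiguous single-location
    proteins, so only phi = 1 rows are eligible and each class contributes
    round(marker_fraction * class size) of them.
    """
    if not 0.0 < marker_fraction <= 1.0:
        raise ValueError("marker_fraction must lie in (0, 1]")
    K = truth.n_classes
    if class_names is None:
        class_names = tuple(f"class_{k + 1}" for k in range(K))
    if len(class_names) != K:
        raise ValueError("class_names length must equal K")
    rng = np.random.default_rng(seed)
    labels: dict[str, str] = {}
    for k in range(K):
        eligible = np.where((truth.z == k) & (truth.phi == 1))[0]
        if eligible.size == 0:
            raise ValueError(f"class {class_names[k]!r} has no non-outlier member to mark")
        n_mark = max(1, int(round(marker_fraction * eligible.size)))
        chosen = rng.choice(eligible, size=n_mark, replace=False)
        for i in chosen:
            labels[matrix.protein_ids[i]] = class_names[k]
    return MarkerAnnotation(labels=labels, classes=class_names)
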