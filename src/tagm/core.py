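"""Core domain types, probability densities and default priors.

The model describes quantitative protein fractionation profiles (a protein
is a point in R^D, one coordinate per collected fraction) as a K-component
Gaussian mixture — one multivariate normal per annotated sub-cellular
niche — augmented with a single heavy-tailed multivariate Student-t
"outlier" component that absorbs proteins not well described by any known
niche (multi-localising or uncharacterised proteins).

Everything downstream (EM, collapsed Gibbs, assessment) shares the types
and the log-density kernels defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "DegenerateCovarianceError",
    "ExpressionMatrix",
    "MarkerAnnotation",
    "Hyperparameters",
    "ComponentParams",
    "mvnormal_logdensity",
    "mvt_logdensity",
    "mvnormal_logdensity_batch",
    "mvt_logdensity_batch",
    "default_hyperparameters",
]


class DegenerateCovarianceError(np.linalg.LinAlgError):
    """A covariance/scale matrix is not positive definite."""


def _cholesky(mat: np.ndarray, what: str = "covariance") -> np.ndarray:
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError as exc:
        raise DegenerateCovarianceError(
            f"{what} matrix is not positive definite"
        ) from exc


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """N x D matrix of relative protein abundances across fractions.

    Row order is the canonical protein index used by every downstream
    structure.
    """

    values: np.ndarray
    protein_ids: tuple[str, ...]
    fraction_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "protein_ids", tuple(str(p) for p in self.protein_ids))
        object.__setattr__(self, "fraction_ids", tuple(str(f) for f in self.fraction_ids))
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        n, d = values.shape
        if n < 1 or d < 1:
            raise ValueError("expression matrix must be at least 1 x 1")
        if len(self.protein_ids) != n:
            raise ValueError("protein_ids length does not match row count")
        if len(self.fraction_ids) != d:
            raise ValueError("fraction_ids length does not match column count")
        if len(set(self.protein_ids)) != n:
            dupes = sorted({p for p in self.protein_ids if self.protein_ids.count(p) > 1})
            raise ValueError(f"duplicate protein ids: {dupes[:5]}")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains missing/non-finite values")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_fractions(self) -> int:
        return self.values.shape[1]

    def index_of(self, protein_id: str) -> int:
        try:
            return self.protein_ids.index(protein_id)
        except ValueError:
            raise KeyError(f"unknown protein id: {protein_id!r}") from None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=list(self.protein_ids), columns=list(self.fraction_ids)
        )

    @classmethod
    def from_dataframe(cls, df) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            protein_ids=tuple(str(i) for i in df.index),
            fraction_ids=tuple(str(c) for c in df.columns),
        )


@dataclass(frozen=True)
class MarkerAnnotation:
    """Curated marker labels: protein id -> sub-cellular class.

    Markers are proteins with unambiguous single annotation; they form the
    labelled set with fixed allocation (and fixed non-outlier status) in
    every inference engine. ``classes`` is the ordered catalogue of the K
    niches and fixes column order everywhere downstream.
    """

    labels: Mapping[str, str]
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", dict(self.labels))
        object.__setattr__(self, "classes", tuple(str(c) for c in self.classes))
        if len(self.classes) < 2:
            raise ValueError("need at least 2 sub-cellular classes")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class names in catalogue")
        catalogue = set(self.classes)
        seen = set()
        for pid, cls in self.labels.items():
            if cls not in catalogue:
                raise ValueError(f"marker {pid!r} has unknown class {cls!r}")
            seen.add(cls)
        missing = [c for c in self.classes if c not in seen]
        if missing:
            raise ValueError(f"classes without any marker: {missing}")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def validate_against(self, X: ExpressionMatrix) -> None:
        known = set(X.protein_ids)
        unknown = sorted(set(self.labels) - known)
        if unknown:
            raise ValueError(f"marker protein(s) absent from expression matrix: {unknown[:5]}")

    def class_index(self, name: str) -> int:
        return self.classes.index(name)

    def label_vector(self, X: ExpressionMatrix) -> np.ndarray:
        """Integer labels aligned to X rows: class index for markers, -1 else."""
        self.validate_against(X)
        z = np.full(X.n_proteins, -1, dtype=int)
        lookup = {c: k for k, c in enumerate(self.classes)}
        for i, pid in enumerate(X.protein_ids):
            cls = self.labels.get(pid)
            if cls is not None:
                z[i] = lookup[cls]
        return z

    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in self.classes}
        for cls in self.labels.values():
            out[cls] += 1
        return out


@dataclass(frozen=True)
class Hyperparameters:
    """Fixed prior quantities of the model.

    beta    Dirichlet concentration on the mixing weights pi (K-vector).
    mu0, lambda0, nu0, S0
            normal-inverse-Wishart prior on each niche's (mean, covariance):
            mu_k | Sigma_k ~ N(mu0, Sigma_k/lambda0), Sigma_k ~ IW(nu0, S0).
    u, v    Beta prior on the outlier fraction epsilon.
    kappa, M, V
            degrees of freedom, location and scale of the fixed Student-t
            outlier component.
    """

    beta: np.ndarray
    mu0: np.ndarray
    lambda0: float
    nu0: float
    S0: np.ndarray
    u: float
    v: float
    kappa: float
    M: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "mu0", np.asarray(self.mu0, dtype=float))
        object.__setattr__(self, "S0", np.asarray(self.S0, dtype=float))
        object.__setattr__(self, "M", np.asarray(self.M, dtype=float))
        object.__setattr__(self, "V", np.asarray(self.V, dtype=float))
        d = self.mu0.shape[0]
        if self.S0.shape != (d, d) or self.V.shape != (d, d) or self.M.shape != (d,):
            raise ValueError("inconsistent hyperparameter dimensions")
        if np.any(self.beta <= 0):
            raise ValueError("beta entries must be positive")
        if self.lambda0 <= 0 or self.u <= 0 or self.v <= 0 or self.kappa <= 0:
            raise ValueError("lambda0, u, v, kappa must be positive")
        if self.nu0 <= d - 1:
            raise ValueError(f"nu0 must exceed D-1 = {d - 1}")
        _cholesky(self.S0, "prior scale S0")
        _cholesky(self.V, "outlier scale V")

    @property
    def n_fractions(self) -> int:
        return self.mu0.shape[0]

    @property
    def n_classes(self) -> int:
        return self.beta.shape[0]


@dataclass(frozen=True)
class ComponentParams:
    """Concrete mixture parameters: per-niche Gaussians, weights, epsilon."""

    means: np.ndarray        # (K, D)
    covariances: np.ndarray  # (K, D, D)
    weights: np.ndarray      # (K,), simplex
    epsilon: float           # prior outlier probability in [0, 1]

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        covs = np.asarray(self.covariances, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "covariances", covs)
        object.__setattr__(self, "weights", w)
        k, d = means.shape
        if covs.shape != (k, d, d):
            raise ValueError("covariances shape must be (K, D, D)")
        if w.shape != (k,):
            raise ValueError("weights shape must be (K,)")
        if abs(w.sum() - 1.0) > 1e-10 or np.any(w < 0):
            raise ValueError("weights must form a probability simplex")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")
        for kk in range(k):
            _cholesky(covs[kk], f"component {kk} covariance")

    @property
    def n_classes(self) -> int:
        return self.means.shape[0]

    @property
    def n_fractions(self) -> int:
        return self.means.shape[1]


# ---------------------------------------------------------------------------
# Densities (log space, Cholesky quadratic forms)
# ---------------------------------------------------------------------------

_LOG_2PI = float(np.log(2.0 * np.pi))


def mvnormal_logdensity_batch(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """log N(x | mean, cov) for every row of X. Returns (n,) array."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean = np.asarray(mean, dtype=float)
    d = mean.shape[0]
    chol = _cholesky(np.asarray(cov, dtype=float))
    dev = X - mean
    # solve L y = dev^T; quadratic form = sum(y^2)
    sol = np.linalg.solve(chol, dev.T)
    quad = np.einsum("ij,ij->j", sol, sol)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * _LOG_2PI + logdet + quad)


def mvnormal_logdensity(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Log-density of the multivariate normal at a single point."""
    return float(mvnormal_logdensity_batch(x, mean, cov)[0])


def mvt_logdensity_batch(
    X: np.ndarray, kappa: float, M: np.ndarray, V: np.ndarray
) -> np.ndarray:
    """log t_kappa(x | M, V) for every row of X. Returns (n,) array."""
    if kappa <= 0:
        raise ValueError("degrees of freedom kappa must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    M = np.asarray(M, dtype=float)
    d = M.shape[0]
    chol = _cholesky(np.asarray(V, dtype=float), "t scale")
    dev = X - M
    sol = np.linalg.solve(chol, dev.T)
    quad = np.einsum("ij,ij->j", sol, sol)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return (
        gammaln(0.5 * (kappa + d))
        - gammaln(0.5 * kappa)
        - 0.5 * d * np.log(kappa * np.pi)
        - 0.5 * logdet
        - 0.5 * (kappa + d) * np.log1p(quad / kappa)
    )


def mvt_logdensity(x: np.ndarray, kappa: float, M: np.ndarray, V: np.ndarray) -> float:
    """Log-density of the multivariate Student-t at a single point."""
    return float(mvt_logdensity_batch(x, kappa, M, V)[0])


# ---------------------------------------------------------------------------
# Data-driven default hyperparameters
# ---------------------------------------------------------------------------


def default_hyperparameters(
    X: ExpressionMatrix, markers: MarkerAnnotation
) -> Hyperparameters:
    """Empirical-Bayes style defaults derived from the full data matrix.

    The Student-t outlier component is fixed with kappa = 4, location at the
    global mean and scale half the global (n-1) covariance of all proteins,
    labelled and unlabelled — heavy-tailed and flat relative to any single
    niche. The NIW prior is centred at the global mean with weak shrinkage
    (lambda0 = 0.01), the smallest degrees of freedom giving a finite
    inverse-Wishart mean (nu0 = D + 2), and a scale shrunk by K^(2/D) so the
    prior niche volume scales with the number of niches. The Dirichlet
    concentration is flat (beta = 1) and the Beta(2, 10) prior on epsilon
    weakly favours a minority outlier fraction. All values are plain
    defaults; every field is overridable.
    """
    vals = X.values
    n, d = vals.shape
    if n < 2:
        raise ValueError("need at least 2 proteins to estimate a global covariance")
    markers.validate_against(X)
    gmean = vals.mean(axis=0)
    gcov = np.cov(vals, rowvar=False, ddof=1).reshape(d, d)
    if np.allclose(vals, vals[0]):
        raise ValueError("degenerate data: all profiles identical")
    # ridge keeps V and S0 positive definite for rank-deficient data
    try:
        np.linalg.cholesky(gcov)
    except np.linalg.LinAlgError:
        gcov = gcov + np.eye(d) * (1e-6 * np.trace(gcov) / d)
    k = markers.n_classes
    return Hyperparameters(
        beta=np.ones(k),
        mu0=gmean.copy(),
        lambda0=0.01,
        nu0=float(d + 2),
        S0=gcov / k ** (2.0 / d),
        u=2.0,
        v=10.0,
        kappa=4.0,
        M=gmean.copy(),
        V=0.5 * gcov,
    )
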