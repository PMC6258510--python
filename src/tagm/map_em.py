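"""MAP inference by expectation-maximisation (TAGM-MAP).

The EM algorithm targets the joint posterior mode of the mixture
parameters (niche means/covariances under a conjugate normal-inverse-
Wishart prior, Dirichlet mixing weights, Beta outlier fraction), treating
the latent niche labels z_i and outlier indicators phi_i of unlabelled
proteins as missing data. Marker proteins enter with their label fixed
and phi = 1. The fitted mode is then plugged into the allocation formula
to give each protein a posterior localisation probability per niche plus
an outlier probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, gammaln, logsumexp
from scipy.stats import invwishart

from .core import (
    ComponentParams,
    ExpressionMatrix,
    Hyperparameters,
    MarkerAnnotation,
    default_hyperparameters,
    mvnormal_logdensity_batch,
    mvt_logdensity_batch,
)

__all__ = ["EMState", "MAPResult", "e_step", "m_step", "fit_map", "predict_map",
           "TAGMMAPClassifier"]


@dataclass
class EMState:
    """Responsibilities of one E-step.

    a[i, k] = p(z_i = k, phi_i = 1 | x_i)  (niche membership)
    b[i, k] = p(z_i = k, phi_i = 0 | x_i)  (outlier, latent label k)
    w = a + b; rows of w sum to 1. Marker rows are clamped one-hot in a.
    ``loglik`` is the observed-data log-likelihood at the parameters the
    responsibilities were computed under (markers contribute their fixed
    complete-data term).
    """

    a: np.ndarray
    b: np.ndarray
    params: ComponentParams
    loglik: float

    @property
    def w(self) -> np.ndarray:
        return self.a + self.b

    @property
    def a_k(self) -> np.ndarray:
        return self.a.sum(axis=0)

    @property
    def b_k(self) -> np.ndarray:
        return self.b.sum(axis=0)

    @property
    def r_k(self) -> np.ndarray:
        return self.w.sum(axis=0)


@dataclass
class MAPResult:
    """Outcome of fit_map: posterior-mode parameters and allocations."""

    params: ComponentParams
    niw_updates: dict[str, np.ndarray]
    converged: bool
    n_iterations: int
    posterior_trace: np.ndarray
    localisation: np.ndarray   # (N, K), p(z=k, phi=1 | x)
    outlier_prob: np.ndarray   # (N,),   p(phi=0 | x)
    markers: MarkerAnnotation
    hyper: Hyperparameters
    protein_ids: tuple[str, ...]


def _joint_logterms(
    vals: np.ndarray, params: ComponentParams, hyper: Hyperparameters
) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalised log joint terms for (k, phi=1) and (k, phi=0), shape (N, K)."""
    n, _ = vals.shape
    K = params.n_classes
    logf = np.empty((n, K))
    for k in range(K):
        logf[:, k] = mvnormal_logdensity_batch(vals, params.means[k], params.covariances[k])
    logg = mvt_logdensity_batch(vals, hyper.kappa, hyper.M, hyper.V)
    with np.errstate(divide="ignore"):
        logpi = np.log(params.weights)
        log1me = np.log1p(-params.epsilon)
        loge = np.log(params.epsilon) if params.epsilon > 0 else -np.inf
    la = logpi[None, :] + log1me + logf
    lb = logpi[None, :] + loge + logg[:, None]
    return la, lb


def e_step(
    X: ExpressionMatrix,
    markers: MarkerAnnotation,
    params: ComponentParams,
    hyper: Hyperparameters,
) -> EMState:
    """Compute responsibilities under the current parameters.

    For each unlabelled protein the 2K joint terms
    pi_k (1-eps) f(x|mu_k, Sigma_k) and pi_k eps g(x|kappa, M, V)
    are normalised jointly (log-sum-exp). Marker rows are fixed to their
    annotated class with a = 1.
    """
    vals = X.values
    n = vals.shape[0]
    K = markers.n_classes
    la, lb = _joint_logterms(vals, params, hyper)
    stacked = np.concatenate([la, lb], axis=1)          # (N, 2K)
    lognorm = logsumexp(stacked, axis=1)
    if not np.all(np.isfinite(lognorm)):
        bad = int(np.argmin(np.isfinite(lognorm)))
        raise FloatingPointError(
            f"all mixture terms underflowed for protein {X.protein_ids[bad]!r}"
        )
    post = np.exp(stacked - lognorm[:, None])
    a = post[:, :K]
    b = post[:, K:]
    z = markers.label_vector(X)
    labelled = z >= 0
    # markers: fixed allocation, never outliers
    a[labelled] = 0.0
    b[labelled] = 0.0
    a[labelled, z[labelled]] = 1.0
    # observed-data log-likelihood: marginal for unlabelled, fixed term for markers
    loglik = float(lognorm[~labelled].sum() + stacked[labelled, z[labelled]].sum())
    return EMState(a=a, b=b, params=params, loglik=loglik)


def _log_prior(params: ComponentParams, hyper: Hyperparameters) -> float:
    """Log prior density of (pi, epsilon, {mu_k, Sigma_k}) at the given point."""
    beta = hyper.beta
    w = params.weights
    with np.errstate(divide="ignore", invalid="ignore"):
        dir_terms = np.where(beta == 1.0, 0.0, (beta - 1.0) * np.log(w))
    log_dir = float(dir_terms.sum() + gammaln(beta.sum()) - gammaln(beta).sum())
    eps = params.epsilon
    log_beta = -betaln(hyper.u, hyper.v)
    log_beta += (hyper.u - 1.0) * (np.log(eps) if eps > 0 else (0.0 if hyper.u == 1 else -np.inf))
    log_beta += (hyper.v - 1.0) * (np.log1p(-eps) if eps < 1 else (0.0 if hyper.v == 1 else -np.inf))
    log_niw = 0.0
    for k in range(params.n_classes):
        cov = params.covariances[k]
        log_niw += float(
            mvnormal_logdensity_batch(params.means[k], hyper.mu0, cov / hyper.lambda0)[0]
        )
        log_niw += float(invwishart.logpdf(cov, df=hyper.nu0, scale=hyper.S0))
    return log_dir + float(log_beta) + log_niw


def m_step(
    state: EMState,
    X: ExpressionMatrix,
    markers: MarkerAnnotation,
    hyper: Hyperparameters,
) -> tuple[ComponentParams, dict[str, np.ndarray]]:
    """Posterior-mode update of all parameters given the responsibilities.

    Conjugate NIW bookkeeping per niche:
    lambda_k = lambda0 + a_k, nu_k = nu0 + a_k,
    m_k = (a_k xbar_k + lambda0 mu0)/lambda_k,
    Psi_k = S0 + (lambda0 a_k/lambda_k)(xbar_k - mu0)(xbar_k - mu0)^T
          + sum_i a_ik (x_i - xbar_k)(x_i - xbar_k)^T,
    with joint mode mu_k = m_k, Sigma_k = Psi_k / (nu_k + D + 2).
    Empty niches (a_k = 0) fall back to the prior-only update.
    """
    vals = X.values
    n, d = vals.shape
    K = markers.n_classes
    a_k, b_k, r_k = state.a_k, state.b_k, state.r_k
    a_tot, b_tot = float(a_k.sum()), float(b_k.sum())
    eps = (hyper.u + b_tot - 1.0) / ((a_tot + b_tot) + (hyper.u + hyper.v) - 2.0)
    eps = float(min(max(eps, 0.0), 1.0))
    pi = (r_k + hyper.beta - 1.0) / (n + hyper.beta.sum() - K)
    if np.any(pi < 0):
        raise ValueError(
            "negative mixing-weight mode (Dirichlet beta < 1 with an empty class)"
        )
    pi = pi / pi.sum()
    lam = hyper.lambda0 + a_k
    nu = hyper.nu0 + a_k
    means = np.empty((K, d))
    covs = np.empty((K, d, d))
    m_all = np.empty((K, d))
    S_all = np.empty((K, d, d))
    for k in range(K):
        if a_k[k] <= 0:
            xbar = hyper.mu0
            psi = hyper.S0.copy()
            m_k = hyper.mu0.copy()
        else:
            xbar = (state.a[:, k] @ vals) / a_k[k]
            m_k = (a_k[k] * xbar + hyper.lambda0 * hyper.mu0) / lam[k]
            dev0 = xbar - hyper.mu0
            dev = vals - xbar
            scatter = (state.a[:, k][:, None] * dev).T @ dev
            psi = hyper.S0 + (hyper.lambda0 * a_k[k] / lam[k]) * np.outer(dev0, dev0) + scatter
        psi = 0.5 * (psi + psi.T)
        means[k] = m_k
        covs[k] = psi / (nu[k] + d + 2.0)
        m_all[k] = m_k
        S_all[k] = psi
    params = ComponentParams(means=means, covariances=covs, weights=pi, epsilon=eps)
    niw = {"lambda": lam, "nu": nu, "m": m_all, "S": S_all}
    return params, niw


def _initial_params(
    X: ExpressionMatrix, markers: MarkerAnnotation, hyper: Hyperparameters
) -> ComponentParams:
    """Deterministic initialisation: prior means for pi and epsilon; niche
    moments from one marker-only M-step (marker sample moments shrunk
    toward the NIW prior)."""
    z = markers.label_vector(X)
    n = X.n_proteins
    K = markers.n_classes
    a = np.zeros((n, K))
    labelled = z >= 0
    a[labelled, z[labelled]] = 1.0
    state = EMState(a=a, b=np.zeros((n, K)), params=None, loglik=np.nan)  # type: ignore[arg-type]
    params, _ = m_step(state, X, markers, hyper)
    pi0 = hyper.beta / hyper.beta.sum()
    eps0 = hyper.u / (hyper.u + hyper.v)
    return ComponentParams(
        means=params.means, covariances=params.covariances, weights=pi0, epsilon=eps0
    )


def fit_map(
    X: ExpressionMatrix,
    markers: MarkerAnnotation,
    hyper: Hyperparameters | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> MAPResult:
    """Run EM to the posterior mode and compute MAP localisation probabilities.

    The trace records the (observed-data) log-posterior — mixture marginal
    likelihood of the unlabelled proteins, complete-data term for markers,
    plus the log prior — at the start of each iteration; EM guarantees it
    is non-decreasing. Convergence when successive trace values differ by
    less than ``tol``.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if not tol > 0:
        raise ValueError("tol must be positive")
    markers.validate_against(X)
    if hyper is None:
        hyper = default_hyperparameters(X, markers)
    params = _initial_params(X, markers, hyper)
    niw: dict[str, np.ndarray] = {}
    trace: list[float] = []
    converged = False
    n_iterations = 0
    prev_q: float | None = None
    for _ in range(max_iter + 1):
        state = e_step(X, markers, params, hyper)
        q = state.loglik + _log_prior(params, hyper)
        if not np.isfinite(q):
            raise FloatingPointError(f"non-finite log-posterior at iteration {n_iterations}")
        trace.append(q)
        if prev_q is not None and abs(q - prev_q) < tol:
            converged = True
            break
        if n_iterations >= max_iter:
            break
        params, niw = m_step(state, X, markers, hyper)
        n_iterations += 1
        prev_q = q
    loc, outp = _allocation_probabilities(X, markers, params, hyper)
    return MAPResult(
        params=params,
        niw_updates=niw,
        converged=converged,
        n_iterations=n_iterations,
        posterior_trace=np.asarray(trace),
        localisation=loc,
        outlier_prob=outp,
        markers=markers,
        hyper=hyper,
        protein_ids=X.protein_ids,
    )


def _allocation_probabilities(
    X: ExpressionMatrix,
    markers: MarkerAnnotation | None,
    params: ComponentParams,
    hyper: Hyperparameters,
) -> tuple[np.ndarray, np.ndarray]:
    la, lb = _joint_logterms(X.values, params, hyper)
    stacked = np.concatenate([la, lb], axis=1)
    lognorm = logsumexp(stacked, axis=1)
    post = np.exp(stacked - lognorm[:, None])
    K = params.n_classes
    loc = post[:, :K]
    outp = post[:, K:].sum(axis=1)
    if markers is not None:
        z = markers.label_vector(X)
        labelled = z >= 0
        loc[labelled] = 0.0
        loc[labelled, z[labelled]] = 1.0
        outp[labelled] = 0.0
    return loc, outp


def predict_map(
    result: MAPResult,
    X_new: ExpressionMatrix,
    hyper: Hyperparameters | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Localisation and outlier probabilities for new profiles at the MAP.

    Proteins whose id matches a training marker are reported with
    probability 1 for their annotated class. Columns of ``X_new`` must
    match the training fractions.
    """
    if hyper is None:
        hyper = result.hyper
    if X_new.n_fractions != hyper.n_fractions:
        raise ValueError(
            f"fraction mismatch: model has {hyper.n_fractions}, data has {X_new.n_fractions}"
        )
    la, lb = _joint_logterms(X_new.values, result.params, hyper)
    stacked = np.concatenate([la, lb], axis=1)
    lognorm = logsumexp(stacked, axis=1)
    post = np.exp(stacked - lognorm[:, None])
    K = result.params.n_classes
    loc = post[:, :K]
    outp = post[:, K:].sum(axis=1)
    lookup = {c: k for k, c in enumerate(result.markers.classes)}
    for i, pid in enumerate(X_new.protein_ids):
        cls = result.markers.labels.get(pid)
        if cls is not None:
            loc[i] = 0.0
            loc[i, lookup[cls]] = 1.0
            outp[i] = 0.0
    return loc, outp


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator, ClassifierMixin  # noqa: E402


class TAGMMAPClassifier(ClassifierMixin, BaseEstimator):
    """Semi-supervised t-augmented Gaussian mixture classifier (MAP/EM).

    Follows the scikit-learn semi-supervised convention: ``fit(X, y)``
    takes the full profile matrix and a label vector in which unlabelled
    proteins carry the value -1 (or None/NaN); labelled entries are the
    marker classes. The model is fitted by EM to the joint posterior mode.

    Parameters
    ----------
    hyperparameters : Hyperparameters or None
        Prior specification; derived from the data when None.
    tol : float
        Convergence threshold on the change in log-posterior.
    max_iter : int
        Maximum number of EM iterations.

    Attributes
    ----------
    classes_ : ndarray of class labels (sorted).
    means_, covariances_, weights_, epsilon_ : posterior-mode parameters.
    converged_, n_iter_, posterior_trace_ : EM diagnostics.
    result_ : the underlying :class:`MAPResult`.
    """

    def __init__(
        self,
        hyperparameters: Hyperparameters | None = None,
        tol: float = 1e-6,
        max_iter: int = 200,
    ):
        self.hyperparameters = hyperparameters
        self.tol = tol
        self.max_iter = max_iter

    @staticmethod
    def _split_labels(y) -> tuple[np.ndarray, np.ndarray]:
        y = np.asarray(y, dtype=object)
        mask = np.array(
            [lab is not None and lab == lab and lab != -1 and lab != "-1" for lab in y]
        )
        return y, mask

    def _as_matrix(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("X must be 2-D")
        return ExpressionMatrix(
            values=arr,
            protein_ids=tuple(f"row{i}" for i in range(arr.shape[0])),
            fraction_ids=tuple(f"col{j}" for j in range(arr.shape[1])),
        )

    def fit(self, X, y):
        mat = self._as_matrix(X)
        y, mask = self._split_labels(y)
        if y.shape[0] != mat.n_proteins:
            raise ValueError("X and y length mismatch")
        if mask.sum() == 0:
            raise ValueError("no labelled proteins in y")
        classes = np.unique(y[mask].astype(str))
        labels = {
            mat.protein_ids[i]: str(y[i]) for i in np.where(mask)[0]
        }
        markers = MarkerAnnotation(labels=labels, classes=tuple(classes))
        self.result_ = fit_map(
            mat, markers, hyper=self.hyperparameters, tol=self.tol, max_iter=self.max_iter
        )
        self.classes_ = classes
        self.means_ = self.result_.params.means
        self.covariances_ = self.result_.params.covariances
        self.weights_ = self.result_.params.weights
        self.epsilon_ = self.result_.params.epsilon
        self.converged_ = self.result_.converged
        self.n_iter_ = self.result_.n_iterations
        self.posterior_trace_ = self.result_.posterior_trace
        return self

    def predict_proba(self, X):
        """Posterior localisation probabilities p(z=k, phi=1 | x), (n, K).

        Rows sum to 1 minus the outlier probability; see
        :meth:`predict_outlier_proba` and :meth:`predict_membership_proba`.
        """
        self._check_fitted()
        loc, _ = predict_map(self.result_, self._as_matrix(X))
        return loc

    def predict_outlier_proba(self, X):
        """Posterior outlier probabilities p(phi=0 | x), shape (n,)."""
        self._check_fitted()
        _, outp = predict_map(self.result_, self._as_matrix(X))
        return outp

    def predict_membership_proba(self, X):
        """Class-membership marginals p(z=k | x) = a + b; rows sum to 1."""
        self._check_fitted()
        mat = self._as_matrix(X)
        la, lb = _joint_logterms(mat.values, self.result_.params, self.result_.hyper)
        stacked = np.concatenate([la, lb], axis=1)
        lognorm = logsumexp(stacked, axis=1)
        post = np.exp(stacked - lognorm[:, None])
        K = len(self.classes_)
        w = post[:, :K] + post[:, K:]
        lookup = {c: k for k, c in enumerate(self.result_.markers.classes)}
        for i, pid in enumerate(mat.protein_ids):
            cls = self.result_.markers.labels.get(pid)
            if cls is not None:
                w[i] = 0.0
                w[i, lookup[cls]] = 1.0
        return w

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted; call fit first")
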