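"""Fully Bayesian inference by collapsed Gibbs sampling (TAGM-MCMC).

The sampler integrates out the niche means and covariances (conjugate
normal-inverse-Wishart) and the mixing weights (Dirichlet-multinomial),
sampling only the per-protein allocations (z_i, phi_i) of unlabelled
proteins plus the outlier fraction epsilon from its conjugate Beta full
conditional. Marker allocations stay clamped. Per retained draw the
Rao-Blackwellised conditional localisation probabilities p_ik(t) are
recorded, and multiple chains are summarised into Monte-Carlo means,
95% equi-tailed intervals and Shannon entropies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .core import (
    ExpressionMatrix,
    Hyperparameters,
    MarkerAnnotation,
    mvt_logdensity_batch,
)

__all__ = [
    "MCMCSettings",
    "Chain",
    "PosteriorSummary",
    "ClassSuffStats",
    "posterior_predictive_logdensity",
    "GibbsState",
    "collapsed_gibbs_sweep",
    "run_chains",
    "gelman_rubin",
    "pool_chains",
    "summarize_posterior",
    "shannon_entropy",
    "classify",
    "TAGMMCMCClassifier",
]


@dataclass(frozen=True)
class MCMCSettings:
    """Chain protocol: length, burn-in, thinning, number of chains, seed."""

    n_chains: int = 6
    n_iter: int = 15000
    burn_in: int = 4000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not (self.n_iter > self.burn_in >= 0):
            raise ValueError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        """floor((n_iter - burn_in)/thin): every thin-th post-burn-in draw."""
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class Chain:
    """Retained samples of one Gibbs chain over the unlabelled proteins."""

    allocation_samples: np.ndarray   # (T', N_U) int class indices
    outlier_samples: np.ndarray      # (T', N_U) int, phi (1 = niche member)
    prob_samples: np.ndarray         # (T', N_U, K) localisation probabilities
    epsilon_samples: np.ndarray      # (T',)
    diagnostics_trace: np.ndarray    # per-iteration count of phi = 1 allocations
    unlabelled_ids: tuple[str, ...]
    classes: tuple[str, ...]

    @property
    def n_retained(self) -> int:
        return self.allocation_samples.shape[0]


@dataclass
class PosteriorSummary:
    """Pooled posterior summaries per unlabelled protein."""

    mean_localisation: np.ndarray  # (N_U, K)
    outlier_prob: np.ndarray       # (N_U,)
    lower95: np.ndarray            # (N_U, K)
    upper95: np.ndarray            # (N_U, K)
    shannon: np.ndarray            # (N_U,)
    n_samples: int
    protein_ids: tuple[str, ...]
    classes: tuple[str, ...]


# ---------------------------------------------------------------------------
# Conjugate sufficient statistics and posterior predictive
# ---------------------------------------------------------------------------


@dataclass
class ClassSuffStats:
    """Gaussian sufficient statistics of one niche's current members.

    Maintains the count, the coordinate sum and the raw second-moment sum
    sum_j x_j x_j^T so that adding and removing a member are exact inverse
    operations.
    """

    count: int
    sum: np.ndarray     # (D,)
    sqsum: np.ndarray   # (D, D)

    @classmethod
    def empty(cls, d: int) -> "ClassSuffStats":
        return cls(count=0, sum=np.zeros(d), sqsum=np.zeros((d, d)))

    @classmethod
    def from_rows(cls, rows: np.ndarray) -> "ClassSuffStats":
        rows = np.atleast_2d(rows)
        return cls(count=rows.shape[0], sum=rows.sum(axis=0), sqsum=rows.T @ rows)

    @property
    def mean(self) -> np.ndarray:
        if self.count == 0:
            raise ValueError("mean undefined for empty statistics")
        return self.sum / self.count

    @property
    def scatter(self) -> np.ndarray:
        """Centred scatter sum_j (x_j - xbar)(x_j - xbar)^T."""
        if self.count == 0:
            return self.sqsum.copy()
        xbar = self.mean
        return self.sqsum - self.count * np.outer(xbar, xbar)

    def add(self, x: np.ndarray) -> None:
        self.count += 1
        self.sum = self.sum + x
        self.sqsum = self.sqsum + np.outer(x, x)

    def remove(self, x: np.ndarray) -> None:
        if self.count <= 0:
            raise ValueError("cannot remove from empty statistics")
        self.count -= 1
        self.sum = self.sum - x
        self.sqsum = self.sqsum - np.outer(x, x)


def _predictive_constants(
    stats: ClassSuffStats, hyper: Hyperparameters
) -> tuple[float, np.ndarray, np.ndarray, float]:
    """(dof, location, Cholesky of scale, additive constant) of the
    Student-t posterior predictive for one niche."""
    d = hyper.n_fractions
    c = stats.count
    lam_n = hyper.lambda0 + c
    nu_n = hyper.nu0 + c
    m_n = (stats.sum + hyper.lambda0 * hyper.mu0) / lam_n
    if c > 0:
        xbar = stats.sum / c
        dev0 = xbar - hyper.mu0
        psi = hyper.S0 + stats.scatter + (hyper.lambda0 * c / lam_n) * np.outer(dev0, dev0)
    else:
        psi = hyper.S0
    psi = 0.5 * (psi + psi.T)
    dof = nu_n - d + 1.0
    if dof <= 0:
        raise ValueError(f"posterior-predictive degrees of freedom {dof} <= 0")
    scale = psi * (lam_n + 1.0) / (lam_n * dof)
    try:
        chol = np.linalg.cholesky(scale)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("degenerate posterior-predictive scale") from exc
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    const = (
        gammaln(0.5 * (dof + d))
        - gammaln(0.5 * dof)
        - 0.5 * d * np.log(dof * np.pi)
        - 0.5 * logdet
    )
    return dof, m_n, chol, float(const)


def _predictive_eval(
    x: np.ndarray, dof: float, m: np.ndarray, chol: np.ndarray, const: float, d: int
) -> float:
    y = np.linalg.solve(chol, x - m)
    quad = float(y @ y)
    return const - 0.5 * (dof + d) * np.log1p(quad / dof)


def posterior_predictive_logdensity(
    x: np.ndarray, suffstats: ClassSuffStats, hyper: Hyperparameters
) -> float:
    """Log NIW posterior-predictive density of ``x`` given a niche's members.

    A multivariate Student-t with dof nu_n - D + 1, location m_n and scale
    S_n (lambda_n + 1)/(lambda_n (nu_n - D + 1)), where (lambda_n, nu_n,
    m_n, S_n) are the conjugate updates for the members in ``suffstats``.
    With zero members this is the prior predictive.
    """
    x = np.asarray(x, dtype=float)
    if suffstats.count < 0:
        raise ValueError("negative member count")
    dof, m, chol, const = _predictive_constants(suffstats, hyper)
    return _predictive_eval(x, dof, m, chol, const, hyper.n_fractions)


# ---------------------------------------------------------------------------
# Gibbs state and sweep
# ---------------------------------------------------------------------------


@dataclass
class GibbsState:
    """Mutable sampler state over the unlabelled proteins.

    ``z`` holds the current class index per unlabelled protein (-1 before
    the first allocation), ``phi`` the outlier indicator (1 = niche
    member). ``alloc_counts`` counts all current z allocations (markers
    included, both phi values) for the Dirichlet-multinomial weights;
    ``stats`` holds the Gaussian sufficient statistics of phi = 1 members
    (markers included). ``last_probs`` stores the Rao-Blackwellised
    localisation probabilities from the most recent sweep.
    """

    x_unlab: np.ndarray
    z: np.ndarray
    phi: np.ndarray
    epsilon: float
    alloc_counts: np.ndarray
    stats: list[ClassSuffStats]
    logg: np.ndarray
    eps_fixed: bool = False
    last_probs: np.ndarray | None = None
    sweeps_done: int = 0
    _cache: list | None = None

    @classmethod
    def initialise(
        cls,
        X: ExpressionMatrix,
        markers: MarkerAnnotation,
        hyper: Hyperparameters,
        epsilon: float | None = None,
    ) -> "GibbsState":
        z_all = markers.label_vector(X)
        unlab = np.where(z_all < 0)[0]
        x_unlab = X.values[unlab]
        K = markers.n_classes
        d = X.n_fractions
        alloc_counts = np.bincount(z_all[z_all >= 0], minlength=K).astype(float)
        stats = []
        for k in range(K):
            rows = X.values[z_all == k]
            stats.append(ClassSuffStats.from_rows(rows) if rows.size else ClassSuffStats.empty(d))
        logg = mvt_logdensity_batch(x_unlab, hyper.kappa, hyper.M, hyper.V) if unlab.size else np.zeros(0)
        eps_fixed = epsilon is not None
        eps = float(epsilon) if eps_fixed else hyper.u / (hyper.u + hyper.v)
        return cls(
            x_unlab=x_unlab,
            z=np.full(unlab.size, -1, dtype=int),
            phi=np.ones(unlab.size, dtype=int),
            epsilon=eps,
            alloc_counts=alloc_counts,
            stats=stats,
            logg=logg,
            eps_fixed=eps_fixed,
        )

    def _rebuild_cache(self, hyper: Hyperparameters, k: int | None = None) -> None:
        K = len(self.stats)
        if self._cache is None or k is None:
            self._cache = [_predictive_constants(self.stats[j], hyper) for j in range(K)]
        else:
            self._cache[k] = _predictive_constants(self.stats[k], hyper)


def collapsed_gibbs_sweep(
    state: GibbsState,
    X: ExpressionMatrix,
    markers: MarkerAnnotation,
    hyper: Hyperparameters,
    rng: np.random.Generator,
) -> GibbsState:
    """One full Gibbs sweep: resample (z_i, phi_i) for every unlabelled
    protein from its 2K-outcome conditional, then resample epsilon.

    Conditional weights for protein i (after removing it from the state):
    (k, phi=1): (n_k^(-i) + beta_k) (1 - eps) * posterior-predictive(x_i | niche k)
    (k, phi=0): (n_k^(-i) + beta_k) eps * t(x_i | kappa, M, V),
    normalised by log-sum-exp. The normalised phi = 1 block is recorded as
    the Rao-Blackwellised localisation probability p_ik of this sweep.
    """
    K = markers.n_classes
    d = hyper.n_fractions
    n_u = state.z.shape[0]
    if state._cache is None:
        state._rebuild_cache(hyper)
    cache = state._cache
    beta = hyper.beta
    probs_out = np.empty((n_u, K))
    log_eps = np.log(state.epsilon) if state.epsilon > 0 else -np.inf
    log_1me = np.log1p(-state.epsilon) if state.epsilon < 1 else -np.inf
    for i in range(n_u):
        x = state.x_unlab[i]
        zi, phii = state.z[i], state.phi[i]
        if zi >= 0:
            state.alloc_counts[zi] -= 1.0
            if phii == 1:
                state.stats[zi].remove(x)
                own = _predictive_constants(state.stats[zi], hyper)
            else:
                own = None
        else:
            own = None
        # log predictive per class, using cached constants except the
        # protein's own (just-downdated) class
        lpred = np.empty(K)
        for k in range(K):
            dof, m, chol, const = own if (own is not None and k == zi) else cache[k]
            lpred[k] = _predictive_eval(x, dof, m, chol, const, d)
        logn = np.log(state.alloc_counts + beta)
        lw1 = logn + log_1me + lpred
        lw0 = logn + log_eps + state.logg[i]
        lw = np.concatenate([lw1, lw0])
        mx = lw.max()
        w = np.exp(lw - mx)
        tot = w.sum()
        p = w / tot
        probs_out[i] = p[:K]
        choice = int(np.searchsorted(np.cumsum(p), rng.random(), side="right"))
        choice = min(choice, 2 * K - 1)
        new_z, new_phi = (choice, 1) if choice < K else (choice - K, 0)
        state.alloc_counts[new_z] += 1.0
        if new_phi == 1:
            state.stats[new_z].add(x)
        state.z[i] = new_z
        state.phi[i] = new_phi
        # refresh caches for niches whose membership changed
        if phii == 1 and zi >= 0:
            if new_phi == 1 and new_z == zi:
                pass  # removed then re-added: stats restored exactly
            else:
                state._rebuild_cache(hyper, zi)
                if new_phi == 1:
                    state._rebuild_cache(hyper, new_z)
        elif new_phi == 1:
            state._rebuild_cache(hyper, new_z)
    if not state.eps_fixed and n_u > 0:
        n_out = int(np.sum(state.phi == 0))
        state.epsilon = float(rng.beta(hyper.u + n_out, hyper.v + (n_u - n_out)))
    state.last_probs = probs_out
    state.sweeps_done += 1
    # periodic full refresh guards against numerical drift in the running sums
    if state.sweeps_done % 1000 == 0:
        _refresh_stats(state, X, markers, hyper)
    return state


def _refresh_stats(
    state: GibbsState, X: ExpressionMatrix, markers: MarkerAnnotation, hyper: Hyperparameters
) -> None:
    z_all = markers.label_vector(X)
    unlab = np.where(z_all < 0)[0]
    K = markers.n_classes
    d = X.n_fractions
    counts = np.bincount(z_all[z_all >= 0], minlength=K).astype(float)
    stats = []
    for k in range(K):
        rows = [X.values[j] for j in np.where(z_all == k)[0]]
        rows += [state.x_unlab[i] for i in range(state.z.size)
                 if state.z[i] == k and state.phi[i] == 1]
        stats.append(
            ClassSuffStats.from_rows(np.array(rows)) if rows else ClassSuffStats.empty(d)
        )
        counts[k] += float(np.sum(state.z == k))
    state.alloc_counts = counts
    state.stats = stats
    state._rebuild_cache(hyper)


def run_single_chain(
    X: ExpressionMatrix,
    markers: MarkerAnnotation,
    hyper: Hyperparameters,
    n_iter: int,
    burn_in: int,
    thin: int,
    rng: np.random.Generator,
    epsilon: float | None = None,
) -> Chain:
    """Run one chain; retain iteration t (1-indexed) when t > burn_in and
    (t - burn_in) is a multiple of thin."""
    state = GibbsState.initialise(X, markers, hyper, epsilon=epsilon)
    z_all = markers.label_vector(X)
    unlab_idx = np.where(z_all < 0)[0]
    n_u = unlab_idx.size
    K = markers.n_classes
    n_keep = (n_iter - burn_in) // thin
    alloc = np.empty((n_keep, n_u), dtype=np.int32)
    outl = np.empty((n_keep, n_u), dtype=np.int8)
    probs = np.empty((n_keep, n_u, K))
    eps_s = np.empty(n_keep)
    diag = np.empty(n_iter)
    j = 0
    for t in range(1, n_iter + 1):
        collapsed_gibbs_sweep(state, X, markers, hyper, rng)
        diag[t - 1] = float(np.sum(state.phi == 1))
        if t > burn_in and (t - burn_in) % thin == 0 and j < n_keep:
            alloc[j] = state.z
            outl[j] = state.phi
            probs[j] = state.last_probs
            eps_s[j] = state.epsilon
            j += 1
    return Chain(
        allocation_samples=alloc,
        outlier_samples=outl,
        prob_samples=probs,
        epsilon_samples=eps_s,
        diagnostics_trace=diag,
        unlabelled_ids=tuple(X.protein_ids[i] for i in unlab_idx),
        classes=markers.classes,
    )


def run_chains(
    X: ExpressionMatrix,
    markers: MarkerAnnotation,
    hyper: Hyperparameters,
    settings: MCMCSettings,
    epsilon: float | None = None,
) -> list[Chain]:
    """Run ``settings.n_chains`` independent chains with sub-seeds derived
    deterministically from ``settings.seed``."""
    markers.validate_against(X)
    children = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    chains = []
    for child in children:
        rng = np.random.default_rng(child)
        chains.append(
            run_single_chain(
                X, markers, hyper, settings.n_iter, settings.burn_in, settings.thin,
                rng, epsilon=epsilon,
            )
        )
    return chains


# ---------------------------------------------------------------------------
# Diagnostics, pooling, summaries
# ---------------------------------------------------------------------------


def gelman_rubin(chains: list[np.ndarray]) -> float:
    """Potential scale reduction factor of a monitored scalar.

    Classic between/within-chain variance construction: with m chains of
    length n, W the mean within-chain variance and B/n the variance of the
    chain means, R-hat = sqrt(((n-1)/n W + B/n) / W). The degenerate
    convention returns 1 when every chain has zero within-chain variance.
    """
    traces = [np.asarray(c, dtype=float).ravel() for c in chains]
    if len(traces) < 2:
        raise ValueError("need at least 2 chains")
    n = min(t.size for t in traces)
    if n < 2:
        raise ValueError("chains must have length >= 2")
    arr = np.stack([t[:n] for t in traces])
    within = arr.var(axis=1, ddof=1)
    w = float(within.mean())
    means = arr.mean(axis=1)
    b_over_n = float(means.var(ddof=1))
    if w == 0.0:
        return 1.0
    vhat = (n - 1) / n * w + b_over_n
    return float(np.sqrt(vhat / w))


def pool_chains(
    chains: list[Chain], extra_discard: int = 0, keep: set[int] | None = None
) -> Chain:
    """Concatenate kept chains after discarding ``extra_discard`` further
    retained samples from the start of each."""
    if keep is None:
        keep = set(range(len(chains)))
    keep_idx = sorted(keep)
    if not keep_idx:
        raise ValueError("empty keep set")
    for i in keep_idx:
        if extra_discard >= chains[i].n_retained:
            raise ValueError(
                f"extra_discard {extra_discard} leaves no samples in chain {i}"
            )
    kept = [chains[i] for i in keep_idx]
    ref = kept[0]
    return Chain(
        allocation_samples=np.concatenate([c.allocation_samples[extra_discard:] for c in kept]),
        outlier_samples=np.concatenate([c.outlier_samples[extra_discard:] for c in kept]),
        prob_samples=np.concatenate([c.prob_samples[extra_discard:] for c in kept]),
        epsilon_samples=np.concatenate([c.epsilon_samples[extra_discard:] for c in kept]),
        diagnostics_trace=np.concatenate(
            [c.outlier_samples[extra_discard:].sum(axis=1) for c in kept]
        ),
        unlabelled_ids=ref.unlabelled_ids,
        classes=ref.classes,
    )


def shannon_entropy(prob: np.ndarray) -> float:
    """Shannon entropy -sum p log p (natural log, 0 log 0 = 0).

    A 1-D input is one allocation distribution; a 2-D input is a stack of
    Monte-Carlo samples of one, and the per-sample entropies are averaged.
    """
    p = np.asarray(prob, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if np.any(p.sum(axis=-1) > 1.0 + 1e-10):
        raise ValueError("probabilities must sum to at most 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=-1)
    return float(h.mean())


def summarize_posterior(pooled: Chain) -> PosteriorSummary:
    """Monte-Carlo means, 95% equi-tailed intervals and averaged Shannon
    entropies from a pooled chain."""
    probs = pooled.prob_samples
    if probs.shape[0] == 0:
        raise ValueError("empty chain")
    mean_loc = probs.mean(axis=0)
    outlier_per_draw = 1.0 - probs.sum(axis=2)
    outlier_prob = outlier_per_draw.mean(axis=0)
    lower = np.quantile(probs, 0.025, axis=0, method="linear")
    upper = np.quantile(probs, 0.975, axis=0, method="linear")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log(probs), 0.0)
    shannon = (-terms.sum(axis=2)).mean(axis=0)
    return PosteriorSummary(
        mean_localisation=mean_loc,
        outlier_prob=outlier_prob,
        lower95=lower,
        upper95=upper,
        shannon=shannon,
        n_samples=probs.shape[0],
        protein_ids=pooled.unlabelled_ids,
        classes=pooled.classes,
    )


def classify(
    summary: PosteriorSummary,
    threshold: float = 0.95,
    markers: MarkerAnnotation | None = None,
) -> list[str]:
    """Hard labels at a probability threshold.

    A protein is called an outlier when its posterior outlier probability
    exceeds the threshold and dominates every niche probability, otherwise
    its argmax niche when that mean probability exceeds the threshold,
    otherwise 'unassigned'. Proteins appearing in ``markers`` always
    receive their annotation.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = []
    for i, pid in enumerate(summary.protein_ids):
        if markers is not None and pid in markers.labels:
            out.append(markers.labels[pid])
            continue
        k = int(np.argmax(summary.mean_localisation[i]))
        top = summary.mean_localisation[i, k]
        if summary.outlier_prob[i] > threshold and summary.outlier_prob[i] >= top:
            out.append("outlier")
        elif top > threshold:
            out.append(summary.classes[k])
        else:
            out.append("unassigned")
    return out


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator, ClassifierMixin  # noqa: E402

from .core import default_hyperparameters  # noqa: E402


class TAGMMCMCClassifier(ClassifierMixin, BaseEstimator):
    """Transductive Bayesian TAGM classifier via collapsed Gibbs sampling.

    ``fit(X, y)`` runs the chains with the unlabelled rows of X (label -1
    or None) as prediction targets; posterior summaries for those rows are
    available immediately after fitting via ``summary_`` and the predict
    methods. The model is transductive: predictions exist only for the
    unlabelled proteins (and markers, clamped to their class) seen at fit
    time.
    """

    def __init__(
        self,
        hyperparameters: Hyperparameters | None = None,
        n_chains: int = 4,
        n_iter: int = 1000,
        burn_in: int = 200,
        thin: int = 5,
        random_state: int = 0,
    ):
        self.hyperparameters = hyperparameters
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.random_state = random_state

    def fit(self, X, y):
        from .map_em import TAGMMAPClassifier

        mat = TAGMMAPClassifier._as_matrix(self, X)
        y, mask = TAGMMAPClassifier._split_labels(y)
        if y.shape[0] != mat.n_proteins:
            raise ValueError("X and y length mismatch")
        classes = np.unique(y[mask].astype(str))
        labels = {mat.protein_ids[i]: str(y[i]) for i in np.where(mask)[0]}
        markers = MarkerAnnotation(labels=labels, classes=tuple(classes))
        hyper = self.hyperparameters or default_hyperparameters(mat, markers)
        settings = MCMCSettings(
            n_chains=self.n_chains,
            n_iter=self.n_iter,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=self.random_state,
        )
        self.chains_ = run_chains(mat, markers, hyper, settings)
        self.pooled_ = pool_chains(self.chains_)
        self.summary_ = summarize_posterior(self.pooled_)
        self.rhat_ = (
            gelman_rubin([c.diagnostics_trace[settings.burn_in:] for c in self.chains_])
            if self.n_chains >= 2
            else np.nan
        )
        self.classes_ = classes
        self.markers_ = markers
        self.matrix_ = mat
        self.hyper_ = hyper
        self._id_row = {pid: i for i, pid in enumerate(self.summary_.protein_ids)}
        z_fit = markers.label_vector(mat)
        self._unlab_matrix_rows = np.where(z_fit < 0)[0]
        return self

    def _rows_for(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Map query rows onto fitted unlabelled proteins (by id or value)."""
        from .map_em import TAGMMAPClassifier

        mat = TAGMMAPClassifier._as_matrix(self, X)
        unlab_vals = self.matrix_.values[self._unlab_matrix_rows]
        rows = np.empty(mat.n_proteins, dtype=int)
        marker_rows: dict[int, str] = {}
        for i, pid in enumerate(mat.protein_ids):
            if pid in self._id_row:
                rows[i] = self._id_row[pid]
            elif pid in self.markers_.labels:
                rows[i] = -1
                marker_rows[i] = self.markers_.labels[pid]
            else:
                hits = np.where(np.all(np.isclose(unlab_vals, mat.values[i]), axis=1))[0]
                if hits.size == 0:
                    raise ValueError(
                        f"protein {pid!r} was not an unlabelled protein at fit time "
                        "(the MCMC classifier is transductive)"
                    )
                rows[i] = int(hits[0])
        return rows, np.array(
            [marker_rows.get(i, "") for i in range(mat.n_proteins)], dtype=object
        )

    def predict_proba(self, X):
        """Posterior mean localisation probabilities, shape (n, K)."""
        self._check_fitted()
        rows, marker_cls = self._rows_for(X)
        out = np.zeros((rows.size, len(self.classes_)))
        lookup = {c: k for k, c in enumerate(self.summary_.classes)}
        for i, r in enumerate(rows):
            if r < 0:
                out[i, lookup[marker_cls[i]]] = 1.0
            else:
                out[i] = self.summary_.mean_localisation[r]
        return out

    def predict_membership_proba(self, X):
        """Posterior mean class-membership marginals p(z=k|x); rows sum to 1.

        Per draw the 2K conditional splits its phi = 0 mass across classes
        by the Dirichlet-multinomial weights; the membership marginal is
        obtained by renormalising the localisation block, averaged over
        draws.
        """
        self._check_fitted()
        rows, marker_cls = self._rows_for(X)
        probs = self.pooled_.prob_samples  # (T, N_U, K)
        row_sums = probs.sum(axis=2, keepdims=True)
        member = np.divide(probs, row_sums, out=np.full_like(probs, np.nan), where=row_sums > 0)
        member_mean = np.nanmean(member, axis=0)
        out = np.zeros((rows.size, len(self.classes_)))
        lookup = {c: k for k, c in enumerate(self.summary_.classes)}
        for i, r in enumerate(rows):
            if r < 0:
                out[i, lookup[marker_cls[i]]] = 1.0
            else:
                out[i] = member_mean[r]
        return out

    def predict_outlier_proba(self, X):
        self._check_fitted()
        rows, _ = self._rows_for(X)
        out = np.zeros(rows.size)
        for i, r in enumerate(rows):
            out[i] = 0.0 if r < 0 else self.summary_.outlier_prob[r]
        return out

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def _check_fitted(self):
        if not hasattr(self, "summary_"):
            raise RuntimeError("estimator is not fitted; call fit first")
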