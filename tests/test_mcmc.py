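"""Collapsed Gibbs sampler: conjugate predictives, sweep correctness
against exhaustive enumeration, chain protocol, diagnostics and summaries."""

import numpy as np
import pytest
from scipy import integrate
from scipy.special import gammaln
from scipy.stats import invgamma, multivariate_t, norm

from tagm.core import ExpressionMatrix, Hyperparameters, MarkerAnnotation
from tagm.mcmc import (
    Chain,
    ClassSuffStats,
    MCMCSettings,
    classify,
    gelman_rubin,
    pool_chains,
    posterior_predictive_logdensity,
    run_chains,
    run_single_chain,
    shannon_entropy,
    summarize_posterior,
)


def _hyper_1d(lambda0=1.0, nu0=3.0, mu0=0.0, s0=1.0, kappa=4.0, M=0.0, V=1.0,
              u=2.0, v=10.0):
    return Hyperparameters(
        beta=np.ones(2), mu0=np.array([mu0]), lambda0=lambda0, nu0=nu0,
        S0=np.array([[s0]]), u=u, v=v, kappa=kappa, M=np.array([M]),
        V=np.array([[V]]),
    )


# ---------------------------------------------------------------------------
# posterior predictive
# ---------------------------------------------------------------------------


class TestPosteriorPredictive:
    def test_zero_members_equals_prior_predictive(self):
        h = _hyper_1d(lambda0=0.7, nu0=4.0, mu0=1.0, s0=2.0)
        stats = ClassSuffStats.empty(1)
        dof = h.nu0 - 1 + 1
        scale = h.S0 * (h.lambda0 + 1) / (h.lambda0 * dof)
        oracle = multivariate_t(loc=h.mu0, shape=scale, df=dof).logpdf([0.3])
        val = posterior_predictive_logdensity(np.array([0.3]), stats, h)
        assert val == pytest.approx(float(oracle), abs=1e-10)

    @staticmethod
    def _quadrature_predictive(members, x, h):
        """Marginal-likelihood ratio p(members + x)/p(members) by dense
        Simpson integration of the normal likelihood against the normal-
        inverse-gamma prior over (mu, sigma^2), parameterised as
        (w, log sigma^2) with mu = mu0 + sigma w so the integrand keeps an
        O(1) width at every variance scale."""
        lam0, nu0 = h.lambda0, h.nu0
        mu0, s0 = float(h.mu0[0]), float(h.S0[0, 0])

        def log_ml(data):
            w = np.linspace(-40.0, 40.0, 1601)
            t = np.linspace(-16.0, 34.0, 2001)  # log sigma^2
            W, T = np.meshgrid(w, t, indexing="ij")
            S2 = np.exp(T)
            MU = mu0 + np.exp(0.5 * T) * W
            logf = np.zeros_like(MU)
            for d in data:
                logf += norm.logpdf(d, loc=MU, scale=np.sqrt(S2))
            logf += norm.logpdf(MU, loc=mu0, scale=np.sqrt(S2 / lam0))
            # + T for d(sigma^2), + T/2 for d(mu) jacobians
            logf += invgamma.logpdf(S2, a=nu0 / 2.0, scale=s0 / 2.0) + 1.5 * T
            m = logf.max()
            val = integrate.simpson(
                integrate.simpson(np.exp(logf - m), x=t, axis=1), x=w
            )
            return m + np.log(val)

        return log_ml(list(members) + [x]) - log_ml(list(members))

    def test_two_member_quadrature_oracle(self):
        h = _hyper_1d(lambda0=1.0, nu0=3.0, mu0=0.0, s0=1.0)
        stats = ClassSuffStats.from_rows(np.array([[0.0], [1.0]]))
        val = posterior_predictive_logdensity(np.array([0.5]), stats, h)
        oracle = self._quadrature_predictive([0.0, 1.0], 0.5, h)
        assert val == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_instances_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = _hyper_1d(
            lambda0=float(rng.uniform(0.3, 2.0)),
            nu0=float(rng.uniform(2.5, 6.0)),
            mu0=float(rng.uniform(-1.0, 1.0)),
            s0=float(rng.uniform(0.5, 2.0)),
        )
        members = rng.normal(size=rng.integers(1, 4))
        x = float(rng.normal())
        stats = ClassSuffStats.from_rows(members[:, None])
        val = posterior_predictive_logdensity(np.array([x]), stats, h)
        oracle = self._quadrature_predictive(members, x, h)
        assert val == pytest.approx(oracle, abs=1e-6)

    def test_add_remove_restores_value(self):
        h = _hyper_1d()
        rng = np.random.default_rng(1)
        stats = ClassSuffStats.from_rows(rng.normal(size=(5, 1)))
        x = np.array([0.37])
        before = posterior_predictive_logdensity(x, stats, h)
        y = np.array([2.5])
        stats.add(y)
        stats.remove(y)
        after = posterior_predictive_logdensity(x, stats, h)
        assert after == pytest.approx(before, abs=1e-12)

    def test_nonpositive_dof_rejected(self):
        h = Hyperparameters(
            beta=np.ones(2), mu0=np.zeros(3), lambda0=1.0, nu0=2.5,
            S0=np.eye(3), u=2.0, v=10.0, kappa=4.0, M=np.zeros(3), V=np.eye(3),
        )
        # nu0 - D + 1 = 0.5 > 0 is fine; force failure via negative count
        stats = ClassSuffStats(count=-1, sum=np.zeros(3), sqsum=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            posterior_predictive_logdensity(np.zeros(3), stats, h)


# ---------------------------------------------------------------------------
# enumeration oracle for the sweep
# ---------------------------------------------------------------------------


def _log_ml_1d(data, h):
    """Closed-form NIW marginal likelihood of 1-D data, written directly
    from the normalising-constant ratio (independent of the sampler)."""
    data = np.asarray(data, dtype=float)
    n = data.size
    if n == 0:
        return 0.0
    lam0, nu0 = h.lambda0, h.nu0
    mu0, s0 = float(h.mu0[0]), float(h.S0[0, 0])
    lam_n = lam0 + n
    nu_n = nu0 + n
    xbar = data.mean()
    sn = s0 + np.sum((data - xbar) ** 2) + lam0 * n / lam_n * (xbar - mu0) ** 2
    return (
        -n / 2.0 * np.log(np.pi)
        + gammaln(nu_n / 2.0) - gammaln(nu0 / 2.0)
        + nu0 / 2.0 * np.log(s0) - nu_n / 2.0 * np.log(sn)
        + 0.5 * (np.log(lam0) - np.log(lam_n))
    )


def _enumerate_tiny(markers_a, markers_b, x, eps, h):
    """Exact posterior over the 16 (z1, phi1, z2, phi2) configurations of
    two unlabelled 1-D proteins given two markers per class."""
    beta = h.beta
    n_mark = np.array([len(markers_a), len(markers_b)], dtype=float)
    t_out = multivariate_t(loc=h.M, shape=h.V, df=h.kappa)
    marker_ml = [_log_ml_1d(markers_a, h), _log_ml_1d(markers_b, h)]
    marker_data = [list(markers_a), list(markers_b)]
    configs = []
    logw = []
    for z1 in (0, 1):
        for p1 in (0, 1):
            for z2 in (0, 1):
                for p2 in (0, 1):
                    lw = 0.0
                    # Dirichlet-multinomial allocation prior (sequential Polya)
                    lw += np.log(n_mark[z1] + beta[z1])
                    lw += np.log(n_mark[z2] + beta[z2] + (1.0 if z1 == z2 else 0.0))
                    lw += (np.log(eps) if p1 == 0 else np.log1p(-eps))
                    lw += (np.log(eps) if p2 == 0 else np.log1p(-eps))
                    members = [list(marker_data[0]), list(marker_data[1])]
                    for xi, zi, pi_ in ((x[0], z1, p1), (x[1], z2, p2)):
                        if pi_ == 1:
                            members[zi] = members[zi] + [xi]
                        else:
                            lw += float(t_out.logpdf([xi]))
                    for k in (0, 1):
                        lw += _log_ml_1d(members[k], h) - marker_ml[k]
                    configs.append((z1, p1, z2, p2))
                    logw.append(lw)
    logw = np.asarray(logw)
    w = np.exp(logw - logw.max())
    return configs, w / w.sum()


def _tiny_instance(markers_a, markers_b, x):
    vals = np.array(list(markers_a) + list(markers_b) + list(x))[:, None]
    ids = tuple(f"p{i}" for i in range(vals.shape[0]))
    matrix = ExpressionMatrix(vals, ids, ("f1",))
    labels = {ids[i]: "a" for i in range(len(markers_a))}
    labels.update({ids[len(markers_a) + i]: "b" for i in range(len(markers_b))})
    return matrix, MarkerAnnotation(labels, ("a", "b"))


@pytest.mark.parametrize("seed", range(5))
def test_sweep_matches_enumeration(seed):
    """Gibbs allocation frequencies on a two-protein instance agree with
    exhaustive 16-configuration enumeration."""
    rng = np.random.default_rng(100 + seed)
    markers_a = list(rng.normal(loc=0.0, scale=0.5, size=2))
    markers_b = list(rng.normal(loc=3.0, scale=0.5, size=2))
    x = [float(rng.uniform(0.0, 3.0)), float(rng.uniform(0.0, 3.0))]
    eps = 0.15
    h = _hyper_1d(lambda0=0.5, nu0=3.0, mu0=1.5, s0=1.0, M=1.5, V=4.0)
    matrix, markers = _tiny_instance(markers_a, markers_b, x)
    configs, probs = _enumerate_tiny(markers_a, markers_b, x, eps, h)
    n_sweeps = 20000
    chain = run_single_chain(
        matrix, markers, h, n_iter=n_sweeps, burn_in=500, thin=1,
        rng=np.random.default_rng(seed), epsilon=eps,
    )
    samples = np.column_stack([
        chain.allocation_samples[:, 0], chain.outlier_samples[:, 0],
        chain.allocation_samples[:, 1], chain.outlier_samples[:, 1],
    ])
    T = samples.shape[0]
    for cfg, p in zip(configs, probs):
        freq = np.mean(np.all(samples == cfg, axis=1))
        se = max(np.sqrt(p * (1 - p) / T), 1e-4)
        assert abs(freq - p) <= 3 * se, f"config {cfg}: {freq} vs {p}"


def test_symmetric_single_protein_uniform_allocation():
    """With symmetric markers and epsilon = 0, one unlabelled protein at
    the centre allocates uniformly over the two classes."""
    matrix, markers = _tiny_instance([-2.0, -1.0], [1.0, 2.0], [0.0])
    h = _hyper_1d(mu0=0.0, s0=1.0, M=0.0, V=4.0)
    chain = run_single_chain(
        matrix, markers, h, n_iter=10000, burn_in=100, thin=1,
        rng=np.random.default_rng(0), epsilon=0.0,
    )
    freq = np.mean(chain.allocation_samples[:, 0] == 0)
    se = np.sqrt(0.25 / chain.n_retained)
    assert abs(freq - 0.5) <= 3 * se
    assert np.all(chain.outlier_samples == 1)  # epsilon 0: never outliers


def test_interval_contains_enumerated_marginal():
    """The 95% equi-tailed interval of the sampled localisation probability
    brackets the enumeration-exact marginal in most tiny instances."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(200 + seed)
        markers_a = list(rng.normal(0.0, 0.5, size=2))
        markers_b = list(rng.normal(3.0, 0.5, size=2))
        x = [float(rng.uniform(0.5, 2.5)), float(rng.uniform(0.5, 2.5))]
        eps = 0.15
        h = _hyper_1d(lambda0=0.5, nu0=3.0, mu0=1.5, s0=1.0, M=1.5, V=4.0)
        matrix, markers = _tiny_instance(markers_a, markers_b, x)
        configs, probs = _enumerate_tiny(markers_a, markers_b, x, eps, h)
        exact = sum(p for cfg, p in zip(configs, probs) if cfg[0] == 0 and cfg[1] == 1)
        chain = run_single_chain(
            matrix, markers, h, n_iter=3000, burn_in=200, thin=1,
            rng=np.random.default_rng(seed), epsilon=eps,
        )
        summary = summarize_posterior(chain)
        if summary.lower95[0, 0] - 0.02 <= exact <= summary.upper95[0, 0] + 0.02:
            hits += 1
    assert hits >= 8


# ---------------------------------------------------------------------------
# chain protocol
# ---------------------------------------------------------------------------


class TestChainProtocol:
    def test_settings_validation(self):
        with pytest.raises(ValueError):
            MCMCSettings(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            MCMCSettings(thin=0)

    def test_retained_count_convention(self):
        assert MCMCSettings(n_iter=15000, burn_in=4000, thin=10).n_retained == 1100
        assert MCMCSettings(n_iter=11, burn_in=0, thin=3).n_retained == 3

    def test_chains_differ_and_reproduce(self, small_dataset):
        matrix, truth, markers = small_dataset
        from tagm.core import default_hyperparameters

        h = default_hyperparameters(matrix, markers)
        settings = MCMCSettings(n_chains=2, n_iter=30, burn_in=10, thin=2, seed=9)
        chains = run_chains(matrix, markers, h, settings)
        assert chains[0].n_retained == settings.n_retained == 10
        assert not np.array_equal(
            chains[0].allocation_samples, chains[1].allocation_samples
        )
        chains2 = run_chains(matrix, markers, h, settings)
        for c1, c2 in zip(chains, chains2):
            np.testing.assert_array_equal(c1.allocation_samples, c2.allocation_samples)
            np.testing.assert_array_equal(c1.epsilon_samples, c2.epsilon_samples)

    def test_markers_never_sampled(self, small_dataset):
        matrix, truth, markers = small_dataset
        from tagm.core import default_hyperparameters

        h = default_hyperparameters(matrix, markers)
        settings = MCMCSettings(n_chains=1, n_iter=20, burn_in=5, thin=1, seed=3)
        chain = run_chains(matrix, markers, h, settings)[0]
        assert set(chain.unlabelled_ids).isdisjoint(markers.labels)
        sums = chain.prob_samples.sum(axis=2)
        assert np.all(sums <= 1 + 1e-10) and np.all(chain.prob_samples >= 0)


class TestPoolChains:
    @staticmethod
    def _dummy_chain(t, n_u=3, k=2, seed=0):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(k + 1), size=(t, n_u))[:, :, :k]
        return Chain(
            allocation_samples=rng.integers(0, k, size=(t, n_u)),
            outlier_samples=rng.integers(0, 2, size=(t, n_u)),
            prob_samples=probs,
            epsilon_samples=rng.random(t),
            diagnostics_trace=np.zeros(t),
            unlabelled_ids=tuple(f"u{i}" for i in range(n_u)),
            classes=("a", "b"),
        )

    def test_standard_protocol_arithmetic(self):
        chains = [self._dummy_chain(1100, seed=i) for i in range(6)]
        pooled = pool_chains(chains, extra_discard=500, keep={0, 1, 2, 3, 5})
        assert pooled.n_retained == 5 * 600 == 3000

    def test_discard_everything_rejected(self):
        chains = [self._dummy_chain(10, seed=i) for i in range(2)]
        with pytest.raises(ValueError):
            pool_chains(chains, extra_discard=10)
        with pytest.raises(ValueError):
            pool_chains(chains, keep=set())


class TestGelmanRubin:
    def test_iid_chains_converged(self):
        rng = np.random.default_rng(11)
        chains = [rng.normal(size=600) for _ in range(5)]
        assert gelman_rubin(chains) < 1.1

    def test_shifted_chain_flagged(self):
        rng = np.random.default_rng(12)
        chains = [rng.normal(size=600) for _ in range(4)]
        chains.append(rng.normal(loc=10.0, size=600))
        assert gelman_rubin(chains) > 1.1

    def test_constant_equal_chains_degenerate_convention(self):
        assert gelman_rubin([np.ones(10), np.ones(10)]) == 1.0

    def test_too_few_chains_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin([np.ones(10)])


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


class TestSummaries:
    def test_constant_chain_zero_width(self):
        probs = np.tile(np.array([[0.7, 0.2]]), (50, 1))[:, None, :]
        chain = Chain(
            allocation_samples=np.zeros((50, 1), dtype=int),
            outlier_samples=np.ones((50, 1), dtype=int),
            prob_samples=probs,
            epsilon_samples=np.full(50, 0.1),
            diagnostics_trace=np.ones(50),
            unlabelled_ids=("u0",),
            classes=("a", "b"),
        )
        s = summarize_posterior(chain)
        np.testing.assert_allclose(s.mean_localisation[0], [0.7, 0.2])
        np.testing.assert_allclose(s.lower95, s.upper95)
        assert s.outlier_prob[0] == pytest.approx(0.1)

    def test_alternating_samples_quantiles(self):
        vals = np.tile([0.2, 0.8], 500)
        probs = np.stack([vals, 1.0 - vals], axis=1)[:, None, :]
        chain = Chain(
            allocation_samples=np.zeros((1000, 1), dtype=int),
            outlier_samples=np.ones((1000, 1), dtype=int),
            prob_samples=probs,
            epsilon_samples=np.zeros(1000),
            diagnostics_trace=np.ones(1000),
            unlabelled_ids=("u0",),
            classes=("a", "b"),
        )
        s = summarize_posterior(chain)
        assert s.mean_localisation[0, 0] == pytest.approx(0.5)
        assert s.lower95[0, 0] == pytest.approx(0.2)
        assert s.upper95[0, 0] == pytest.approx(0.8)
        assert s.lower95[0, 0] <= s.mean_localisation[0, 0] <= s.upper95[0, 0]

    def test_mean_rows_normalise(self, small_dataset):
        matrix, truth, markers = small_dataset
        from tagm.core import default_hyperparameters

        h = default_hyperparameters(matrix, markers)
        chain = run_chains(
            matrix, markers, h, MCMCSettings(n_chains=1, n_iter=30, burn_in=10, thin=1, seed=4)
        )[0]
        s = summarize_posterior(chain)
        np.testing.assert_allclose(
            s.mean_localisation.sum(axis=1) + s.outlier_prob, 1.0, atol=1e-10
        )
        assert np.all(s.shannon >= 0)


class TestShannonEntropy:
    def test_one_hot_is_zero(self):
        assert shannon_entropy(np.array([1.0, 0.0, 0.0])) == 0.0

    def test_uniform_14_classes(self):
        assert shannon_entropy(np.full(14, 1 / 14)) == pytest.approx(np.log(14), abs=1e-12)

    def test_half_half(self):
        assert shannon_entropy(np.array([0.5, 0.5])) == pytest.approx(np.log(2), abs=1e-12)

    def test_sample_average(self):
        samples = np.array([[1.0, 0.0], [0.5, 0.5]])
        assert shannon_entropy(samples) == pytest.approx(0.5 * np.log(2))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            shannon_entropy(np.array([-0.1, 1.1]))


class TestClassify:
    @staticmethod
    def _summary(mean, outlier):
        mean = np.asarray(mean, dtype=float)
        n, k = mean.shape
        from tagm.mcmc import PosteriorSummary

        return PosteriorSummary(
            mean_localisation=mean, outlier_prob=np.asarray(outlier, dtype=float),
            lower95=mean, upper95=mean, shannon=np.zeros(n), n_samples=1,
            protein_ids=tuple(f"u{i}" for i in range(n)), classes=("a", "b"),
        )

    def test_zero_threshold_argmax(self):
        s = self._summary([[0.6, 0.3], [0.1, 0.2]], [0.1, 0.7])
        assert classify(s, threshold=0.0) == ["a", "outlier"]

    def test_confident_class_called(self):
        s = self._summary([[0.96, 0.02]], [0.02])
        assert classify(s, threshold=0.95) == ["a"]

    def test_outlier_called_above_threshold(self):
        s = self._summary([[0.02, 0.02]], [0.96])
        assert classify(s, threshold=0.95) == ["outlier"]

    def test_uncertain_unassigned(self):
        s = self._summary([[0.5, 0.4]], [0.1])
        assert classify(s, threshold=0.95) == ["unassigned"]
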