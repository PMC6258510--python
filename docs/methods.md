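# Methods

## The model

Protein profiles **x**<sub>i</sub> ∈ ℝ<sup>D</sup> (D fractions, replicates
concatenated) are modelled as a K-component Gaussian mixture augmented with
one multivariate Student-t outlier component:

p(**x**<sub>i</sub>) = Σ<sub>k</sub> π<sub>k</sub> [ (1−ε) f(**x**<sub>i</sub> | **μ**<sub>k</sub>, Σ<sub>k</sub>) + ε g(**x**<sub>i</sub> | κ, **M**, V) ],

where f is the multivariate normal density and g the multivariate
Student-t. The latent pair (z<sub>i</sub>, φ<sub>i</sub>) carries the niche
label and the outlier indicator; the niche label is drawn for every protein
(including outliers), so an outlier retains a latent "nearest niche" while
contributing nothing to any Gaussian. Marker proteins have z fixed to their
annotation and φ = 1 throughout.

Assumptions worth stating plainly: each niche is unimodal and elliptical in
profile space; outliers are exchangeable draws from a single flat
heavy-tailed component rather than structured sub-populations; profiles are
real-valued with no missing entries (normalisation and imputation are
upstream concerns); and one label per protein — multi-localisation appears
only indirectly, as probability spread across niches or outlier mass.

## Priors and default hyperparameters

All priors are conjugate: Dirichlet(β) on **π**, Beta(u, v) on ε, and
normal-inverse-Wishart (μ<sub>0</sub>, λ<sub>0</sub>, ν<sub>0</sub>,
S<sub>0</sub>) on each (**μ**<sub>k</sub>, Σ<sub>k</sub>). Data-driven
defaults (`default_hyperparameters`), all overridable:

| parameter | default | rationale |
|---|---|---|
| κ | 4 | heavy tails; variance exists (κ > 2) so the component mimics a broad Gaussian |
| **M** | global mean over all proteins | centres the outlier component on the data cloud |
| V | ½ × global (n−1) covariance | "flat" relative to any single niche; full matrix preserves fraction correlation |
| μ<sub>0</sub> | global mean | neutral centring |
| λ<sub>0</sub> | 0.01 | weak mean shrinkage; markers dominate immediately |
| ν<sub>0</sub> | D + 2 | smallest integer giving a finite inverse-Wishart mean |
| S<sub>0</sub> | global covariance / K<sup>2/D</sup> | prior niche volume shrinks as the number of niches grows |
| β | 1 (all k) | flat on the weight simplex |
| u, v | 2, 10 | prior mean ε ≈ 0.17, weakly favouring a minority outlier fraction |

The sample (n−1) covariance convention is used everywhere. If the global
covariance is rank-deficient a ridge of 10⁻⁶·tr/D is added. These are
standard mixture-model heuristics, declared as configurable defaults rather
than derived quantities.

## MAP inference (EM)

The E-step computes, for each unlabelled protein, the 2K joint
responsibilities a<sub>ik</sub> ∝ π<sub>k</sub>(1−ε)f and b<sub>ik</sub> ∝
π<sub>k</sub>εg, normalised jointly by log-sum-exp (all density work is in
log space with Cholesky quadratic forms; D up to ~40 is safe). The M-step
is the closed-form NIW/Dirichlet/Beta posterior-mode update; the quantity
the update treats as the inverse-Wishart scale is

Ψ<sub>k</sub> = S<sub>0</sub> + Σ<sub>i</sub> a<sub>ik</sub>(**x**<sub>i</sub>−x̄<sub>k</sub>)(**x**<sub>i</sub>−x̄<sub>k</sub>)ᵀ + (λ<sub>0</sub>a<sub>k</sub>/λ<sub>k</sub>)(x̄<sub>k</sub>−μ<sub>0</sub>)(x̄<sub>k</sub>−μ<sub>0</sub>)ᵀ,

with joint mode **μ̂**<sub>k</sub> = m<sub>k</sub>, Σ̂<sub>k</sub> =
Ψ<sub>k</sub>/(ν<sub>k</sub>+D+2). An empty niche (a<sub>k</sub> = 0) falls
back to the prior-only update; β < 1 with an empty niche would give a
negative weight mode and raises instead.

*Initialisation* is deterministic: π and ε at their prior means, niche
moments from one M-step on the markers alone. This uses the labelled data
exactly as the model intends and makes every fit reproducible without
restarts. *Convergence trace*: the recorded trace is the observed-data
log-posterior (mixture marginal likelihood of unlabelled proteins +
complete-data term for markers + log priors), which EM provably never
decreases — the quantity whose per-iteration differences drive the
stopping rule |ΔQ| < δ (default δ = 10⁻⁶, max 200 iterations). The
expected complete-data objective shares its stationary points but is not
monotone draw-by-draw, so the observed-data posterior is the honest
monitor. Only differences of the trace are meaningful.

## Fully Bayesian inference (collapsed Gibbs)

The sampler marginalises **π** (Dirichlet-multinomial counts) and each
(**μ**<sub>k</sub>, Σ<sub>k</sub>) (NIW posterior predictive — a Student-t
with dof ν<sub>n</sub>−D+1, location m<sub>n</sub>, scale
S<sub>n</sub>(λ<sub>n</sub>+1)/(λ<sub>n</sub>(ν<sub>n</sub>−D+1))), and
samples only (z<sub>i</sub>, φ<sub>i</sub>) per unlabelled protein plus ε
from its conjugate Beta full conditional. ε is kept explicit rather than
marginalised because it is scientifically interpretable and its full
conditional is trivial; the stationary distribution of the reported
summaries is unchanged either way. Recorded localisation probabilities are
the **conditional** (Rao-Blackwellised) probabilities rather than indicator
draws, reducing Monte-Carlo variance at no cost.

Implementation notes: per-niche sufficient statistics are the count,
coordinate sum and raw second-moment sum, so removal and reinsertion are
exact inverses; predictive Cholesky factors are cached per niche and
rebuilt only when membership changes, with a full recomputation every 1000
sweeps as a drift guard. Allocation counts include outliers (their latent
z is still a draw from **π**); Gaussian statistics include only φ = 1
members. The first sweep seats proteins sequentially from an empty state,
which doubles as initialisation.

*Chain protocol.* `run_chains` derives independent sub-seeds from the
master seed (identical settings + seed ⇒ bitwise-identical chains).
Retention keeps 1-indexed iteration t when t > burn-in and (t − burn-in)
is a multiple of the thinning interval, so a 15000-iteration chain with
4000 burn-in and thin 10 retains exactly 1100 draws. `pool_chains` never
drops a chain silently: the caller passes the set to keep (after
inspecting per-chain traces and the Gelman-Rubin statistic) and an
optional extra discard. The monitored scalar for Gelman-Rubin is the
per-iteration count of φ = 1 allocations; the statistic is the classic
between/within-variance PSRF, with the degenerate convention that
all-constant chains return 1. Empirical interval endpoints use the
inclusive linear-interpolation quantile definition (numpy's default),
fixed because endpoints are part of the contract. Shannon entropies are
computed per retained draw on the K localisation probabilities
(0·log 0 = 0) and averaged.

## Classifier assessment

Markers are split per class into 80% train / 20% test by a seeded shuffle
(rounded per class, both partitions kept non-empty), repeated R times.
TAGM methods train semi-supervised — training markers labelled, everything
else (test markers plus genuinely unannotated proteins) unlabelled — and
are scored on the test markers. For the quadratic loss the TAGM
probability vector is the class-membership marginal p(z = k | x) =
a<sub>ik</sub> + b<sub>ik</sub>, which sums to 1 over niches; test markers
are genuinely one of the K classes, so this is the comparable quantity
(the localisation probability sums to 1 − P(outlier) and would penalise
the model for honest outlier mass). Macro-F1 uses the argmax label, with
per-class F1 from tp/fp/fn and zero contribution for empty denominators.
The KNN baseline applies Laplace smoothing
(N<sub>ik</sub> + α d<sub>k</sub> C)/(K + α C) with α = 0.5 — the unique
reading of the smoothing rule under which rows sum to 1 — with K chosen by
internal 5-fold cross-validation. The SVM baseline is consumed from
scikit-learn (RBF, internal 5-fold grid over cost and kernel width, Platt
probabilities) and degrades gracefully when unavailable. Pairwise
method comparisons use two-sided unpaired t-tests with Benjamini-Hochberg
correction, exposed as a reporting utility.

## Synthetic data

`generate_tagm_dataset` samples exactly from the generative model:
z ∼ Categorical(π), φ ∼ Bernoulli(1−ε), then the niche Gaussian or the
shared t. Niche centres come from `separated_means` (rejection sampling to
a guaranteed pairwise distance); markers are a seeded per-class sample of
non-outlier proteins, mirroring real curation where markers are
unambiguous single-location proteins. Profiles are unconstrained real
vectors — matching the model — with an optional per-row softmax
"compositional mode" for realism experiments. What these fixtures do *not*
emulate: non-Gaussian niche shapes, correlated replicate noise, missing
values, class imbalance beyond the chosen π, and structured (rather than
exchangeable) outliers. Passing tests on synthetic data therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not robustness to real-data violations of them.

Benchmark problem sizes were chosen to exercise each property at
comfortable margins: monotonicity across 100 datasets at K=4, D=6, N=500;
recovery at K=4, D=6, N=2000 with 6σ separation, ε=0.05, 20% markers
(MCMC: 2 chains × 300 iterations, burn-in 100, thin 4 — well past mixing
for separated data, as the Gelman-Rubin values ≈ 1.00 confirm); sampler
exactness on two-protein instances where the 16-configuration posterior is
enumerable; and 20 assessment rounds.

## Numerical choices and degenerate inputs

- Non-positive-definite covariance/scale matrices raise a dedicated
  degenerate-covariance error at construction or first factorisation.
- All mixture normalisations are log-sum-exp; a protein whose 2K terms all
  underflow raises with the protein id (never observed in practice).
- EM trace monotonicity is asserted to 10⁻⁸; the add/remove inverse of
  sampler sufficient statistics holds to 10⁻¹²; responsibilities and
  probability rows normalise to 10⁻¹⁰.
- Hard classification at threshold τ: outlier if the outlier probability
  exceeds τ *and* dominates every niche probability; otherwise the argmax
  niche if above τ; otherwise "unassigned". Markers always keep their
  annotation. The dominance clause makes the τ = 0 limit coincide with
  plain argmax over the K+1 outcomes.
- Probabilities are serialised with 6 significant digits; run manifests
  are flat key = value text recording every resolved hyperparameter, seed
  and version, so a run is reconstructible from its manifest alone.

## Known limitations

Single-label model (no explicit multi-localisation); one shared t
component with fixed κ; the MCMC classifier is transductive (predictions
exist only for proteins present at fit time); no missing-value handling;
chain execution is sequential (determinism over parallel speed); and the
assessment SVM's probability calibration is whatever scikit-learn's Platt
implementation provides, not a re-derivation.
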