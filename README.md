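# tagm — probabilistic protein sub-cellular localisation

`tagm` assigns proteins to sub-cellular niches from quantitative
fractionation profiles (LOPIT, hyperLOPIT, organellar maps and similar
workflows) using a **T-augmented Gaussian mixture model**, and — unlike
hard classifiers — quantifies the uncertainty of every assignment.

In these experiments each protein *i* is measured as a profile
**x**<sub>*i*</sub> ∈ ℝ<sup>D</sup> across D gradient fractions, and each
of the K annotated niches (nucleus, ER, mitochondrion, …) produces a
characteristic profile shape. A curated set of *marker* proteins with
unambiguous single localisation provides labels; the task is to infer the
localisation of the remaining proteins, many of which multi-localise or
belong to no annotated compartment at all.

## Model

Each niche *k* is a multivariate Gaussian N(**μ**<sub>k</sub>,
Σ<sub>k</sub>); an extra heavy-tailed multivariate Student-t component
t(κ, **M**, V) absorbs outliers. With niche label z<sub>i</sub> and
outlier indicator φ<sub>i</sub> (φ = 1: niche member),

> **x**<sub>i</sub> | z<sub>i</sub>=k, φ<sub>i</sub> ∼
> N(**μ**<sub>k</sub>, Σ<sub>k</sub>)<sup>φ<sub>i</sub></sup> ·
> t(κ, **M**, V)<sup>1−φ<sub>i</sub></sup>,
> P(z<sub>i</sub>=k) = π<sub>k</sub>, P(φ<sub>i</sub>=0) = ε.

Priors are conjugate throughout: Dirichlet(β) on **π**, Beta(u, v) on ε
and normal-inverse-Wishart (μ<sub>0</sub>, λ<sub>0</sub>, ν<sub>0</sub>,
S<sub>0</sub>) on each (**μ**<sub>k</sub>, Σ<sub>k</sub>). The t component
is fixed with κ = 4, **M** the global mean and V half the global
covariance, making it flat relative to any single niche. Two inference
engines share this model:

- **TAGM-MAP** (`fit_map`, `TAGMMAPClassifier`) — EM to the joint
  posterior mode; MAP parameters are plugged into the allocation rule to
  give each protein a probability per niche plus an outlier probability.
- **TAGM-MCMC** (`run_chains`, `TAGMMCMCClassifier`) — a collapsed Gibbs
  sampler that integrates out **π**, **μ**<sub>k</sub> and Σ<sub>k</sub>
  analytically and samples only the allocations (z, φ) and ε, yielding
  the full posterior distribution of localisation probabilities,
  Monte-Carlo means, 95% equi-tailed intervals and per-protein Shannon
  entropies, with multi-chain Gelman-Rubin diagnostics.

An assessment harness (`tagm.assessment`) implements class-stratified
80/20 marker resampling with macro-F1 and quadratic-loss scoring, a
Laplace-smoothed probabilistic KNN baseline, an off-the-shelf SVM
baseline, and contingency-table comparison between classifiers.
`tagm.synthetic` samples datasets from the generative model with known
ground truth.

## Worked example

Simulate a 5-niche, 8-fraction map of 800 proteins (5% outliers), fit
both engines and inspect the outputs:

```bash
tagm simulate --k 5 --d 8 --n 800 --epsilon 0.05 --seed 11 --out demo
tagm fit-map  --quant demo/quantitation.tsv --markers demo/markers.tsv --out demo/map
tagm fit-mcmc --quant demo/quantitation.tsv --markers demo/markers.tsv \
              --chains 4 --iter 400 --burnin 100 --thin 5 --seed 2 --out demo/mcmc
```

which prints

```
wrote synthetic dataset to demo
wrote demo/map/tagm_map_results.tsv (converged=True, iterations=5)
wrote demo/mcmc/tagm_mcmc_results.tsv (R-hat=0.9996)
```

The MAP table gives one row per protein — localisation probability per
niche, outlier probability and the classification at the 0.95 threshold:

```
protein_id  class_1      class_2       class_3   ...  outlier_prob  classification
P00000      3.45435e-21  2.52394e-158  2.82497e-67    1             outlier
P00001      5.78788e-76  7.91713e-122  0.999965       3.51904e-05   class_3
```

P00000 sits far from every niche and is confidently flagged as an
outlier; P00001 is assigned to niche 3 with probability ≈ 1. The MCMC
table adds, per niche, the 0.025/0.975 quantiles of the sampled
localisation probabilities and the Monte-Carlo-averaged Shannon entropy —
near 0 for confidently placed proteins, approaching log K for proteins
the posterior cannot place. `demo/mcmc/diagnostics.txt` records the
Gelman-Rubin statistic of the monitored niche-membership count
(0.9996 here, comfortably below the conventional 1.1 cut-off) and the
retained-sample bookkeeping (4 chains × 60 retained = 240 pooled draws).

The same analyses are available as a library, scikit-learn style:

```python
from tagm import TAGMMAPClassifier
clf = TAGMMAPClassifier().fit(X, y)   # y: marker class or -1 if unlabelled
proba = clf.predict_proba(X)          # (n, K) localisation probabilities
out = clf.predict_outlier_proba(X)    # (n,) outlier probabilities
```

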