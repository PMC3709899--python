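# bayescnax

Bayesian integration of DNA copy-number (aCGH) and RNA expression data for
breast-cancer cohorts: inference on *differential gene behaviour* between
tumour subtypes (triple negative versus ER+/HER2+) with Bayesian FDR
control, and prediction of *pathological complete response* (pCR) for
patients whose outcome is unknown, borrowing strength across the two
genomic platforms.

## The problem

Copy-number aberrations (CNAs) and transcriptional changes carry related
but distinct information about a tumour. Analysing each platform alone
discards the biological coupling — more DNA copies tend to mean more
transcript — and with small clinical cohorts that coupling is exactly
where extra power lives. This package models both platforms jointly:

- **Mixture layer.** Each aCGH log2 ratio `Y_bt` (probe *b*, sample *t*)
  and each expression value `Z_gt` (gene *g*) is a three-component
  Gaussian mixture indexed by a trinary latent state: copy loss / neutral
  / gain, i.e. `e_bt ∈ {−1, 0, +1}`, and under- / normal- / over-expression
  `λ_gt ∈ {−1, 0, +1}`. Neutral observations are `N(centre, σ²)`; aberrant
  components are mean-shifted and variance-inflated (`κ σ²`, κ ≥ 1),
  capturing the heavy tails of real array data. The expression side also
  has gene effects `α_g` and zero-sum sample effects `β_t`.
- **Probit-score layer.** Each trinary state is the thresholding of a
  latent Gaussian score at fixed cutpoints ±c (c = 1): `w_bt` for DNA,
  `v_gt` for RNA. The scores regress on structure of interest:

  ```
  w_bt = μ_b + a_δ δ_b x_t + ε,            ε ~ N(0, 1)
  v_gt = ν_g + a_γ γ_g x_t + a_ρ ρ_g w̄_gt + ε
  ```

  where `x_t` is the subtype indicator, `w̄_gt` is the mean DNA score of
  the probes of gene *g*, and `δ_b, γ_g, ρ_g ∈ {−1, 0, +1}` are sparse
  trinary indicators for differential CNA, differential expression, and
  cross-platform interaction. The probe baselines `μ_b` follow an AR(1)
  chain along the chromosome (partial correlation η, restarting at
  chromosome boundaries).
- **Prediction variant.** For outcome prediction the subtype regression is
  replaced by sparse outcome regressions
  `w_bt = μ_b + ζ_b b_b u_t + ε` and
  `v_gt = ν_g + ξ_g b_g u_t + ρ_g^{link} w̄_gt + ε`,
  with binary inclusion indicators `ζ_b, ξ_g` whose prior keeps only a
  handful of units active. Patients with unknown pCR get `u_t ~
  Bernoulli(π)` and are imputed inside the sampler; their posterior
  imputation probability is the prediction.

Inference is a blocked Gibbs sampler (exact finite-support enumeration for
all discrete quantities, truncated-normal score updates drawn jointly with
their states, conjugate Gaussian/inverse-gamma blocks, one Metropolis step
for η). Gene lists are selected by the Bayesian expected-FDR rule, and
predictive accuracy is summarized by a kernel-smoothed ROC curve.

## Worked example

Simulate a cohort from the model itself (200 genes with two probes each,
50 samples, the first 10 genes carrying joint differential behaviour in
the 10-sample subgroup) and fit the integrated model:

```python
from bayescnax import SimDesign, simulate_design2, DifferentialBehaviourModel

design = SimDesign(n_genes=200, probes_per_gene=2, n_samples=50,
                   n_signal_genes=10, signal_position="head",
                   x_split=10, seed=5)
data, truth = simulate_design2(design)

model = DifferentialBehaviourModel(data)
res = model.fit(n_iter=4000, burn_in=2000, seed=7)
print(res.summary(alpha=0.10))
```

```
Differential behaviour model (integrated)
genes: 200   probes: 400   samples: 50   retained draws: 2000
----------------------------------------------------------------
list                           selected   expected FDR
over+amplified-TN                     0         0.0000
under+deleted-TN                      0         0.0000
over-given-aberration-TN              1         0.0000
under-given-aberration-TN             0         0.0000
positive-interaction                 13         0.0718
----------------------------------------------------------------
posterior means: sigma2_Y=0.254 sigma2_Z=0.242 eta=0.517 a_delta=2.38 a_gamma=0.74 a_rho=1.80
```

The positive-interaction list recovers the planted signal: 13 genes are
selected at expected FDR ≤ 0.10 (realized 0.072 at the cut) and the five
most probable genes are all true signal genes with posterior probability
1.0. The posterior means also recover the generating values: observation
variances 0.25, chain correlation η = 0.5, and the differential-CNA
magnitude a_δ ≈ 2. Note how the sampler attributes the expression shift
of the signal genes to the interaction channel (a_ρ ≈ 1.8, a_γ small):
with a strong DNA→RNA link, the subtype effect on expression is explained
through the elevated DNA scores — the two channels are confounded by
design, which is why ranking (not attribution) is the inferential target.

For prediction, mask the outcomes of a test set and fit:

```python
from bayescnax import PcrPredictionModel, split_train_test

train, test = split_train_test(data.covariates, test_size=20, seed=0)
pred = PcrPredictionModel(data, platform="integrated", holdout=test)
res = pred.fit(n_iter=30000, burn_in=2000, thin=5, seed=0)
res.pcr_probabilities        # posterior predictive P(pCR = 1) per patient
res.roc(true_outcomes).auc   # smoothed ROC against the known truth
```

A command-line interface mirrors the library
(`bayescnax simulate|load|split|fit-differential|fit-predict|select-genes
via fit-differential|roc`); see `bayescnax --help`.

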