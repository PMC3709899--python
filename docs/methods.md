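# Methods

## Model

### Sampling layer

Observations are three-component Gaussian mixtures indexed by trinary
latent states. For aCGH log2 ratios `Y_bt` with copy-number state
`e_bt ∈ {−1, 0, +1}`:

| state | mean            | variance        |
|-------|-----------------|-----------------|
| −1    | `shift⁻_Y` (<0) | `κ⁻_Y σ²_Y`     |
| 0     | 0               | `σ²_Y`          |
| +1    | `shift⁺_Y` (>0) | `κ⁺_Y σ²_Y`     |

Expression `Z_gt` is analogous with expression state `λ_gt`, platform
parameters `(σ²_Z, κ_Z, shift_Z)`, and every component mean offset by a
gene effect `α_g` plus a sample effect `β_t` constrained to `Σ_t β_t = 0`.
The aCGH side carries no such effects because a log2 ratio of tumour to
diploid reference already cancels them. Aberrant components are rendered
as *mean-shifted, variance-inflated Gaussians*: the variance inflation
κ ≥ 1 supplies the tail over-dispersion relative to normality expected of
aberrant measurements while keeping every update conjugate. The shift
priors are anchored at the theoretical single-copy log2 ratios ±1.

### Probit-score layer

Each state is the thresholding of a latent Gaussian score at fixed
symmetric cutpoints ±c:
`state = −1 if score < −c, +1 if score > c, else 0`, with c = 1 and unit
score variance fixed for identifiability (a probit layer is only
identified up to location/scale, so the scale and cutpoints cannot float).

Differential-behaviour mode:

    w_bt = μ_b + a_δ δ_b x_t + ε_bt
    v_gt = ν_g + a_γ γ_g x_t + a_ρ ρ_g w̄_gt + ε_gt

with `x_t` the subtype covariate (1 = triple negative), `w̄_gt` the
per-gene mean of the probe scores, and `δ_b, γ_g, ρ_g` trinary indicators
with prior mass (0.05, 0.90, 0.05) — the null dominating so that
non-null calls are sparse. The indicators carry direction only; the
positive magnitudes `a_δ, a_γ, a_ρ` are shared across units, keeping genes
comparable and the indicator enumeration exact. Setting every `ρ_g = 0`
(`couple=False`) gives the *marginal model* in which the platforms are
analysed independently.

Prediction mode replaces the subtype regression with sparse outcome
regressions:

    w_bt = μ_b + ζ_b b_b u_t + ε_bt
    v_gt = ν_g + ξ_g b_g u_t + ρ_g^link w̄_gt + ε_gt

`ζ_b, ξ_g ∈ {0,1}` have prior inclusion probability `1 − p_zero` with
`p_zero = 0.99`, so only a small subgroup of units links to the clinical
outcome. The platform-link coefficient `ρ_g^link` is a free real
coefficient with a `N(0, 1)` prior (not the trinary ρ of the differential
model): in the prediction model it belongs to the regression parameters
with informative normal priors. Unknown outcomes get `u_t ~ Bernoulli(π)`
with π fixed at the observed training proportion (clipped to
[0.001, 0.999]); patients with missing outcome in training are handled
identically to new patients.

### Markov dependence along the chromosome

Probe baselines follow a first-order autoregression in genomic order
(chromosomes sorted naturally, then position, then probe id; the chain
restarts at every chromosome boundary):

    μ_first ~ N(0, τ²),   μ_b | μ_{b−1} ~ N(η μ_{b−1}, τ² (1 − η²))

η is directly a partial correlation between adjacent probes, and this
parameterization makes every marginal variance exactly τ², so the prior
bound η ≤ η_max = 0.9 bounds the marginal variance by construction. A
scalar η (adjacent probes equally correlated) is the default; the prior
evaluation accepts a per-edge vector as a configuration hook for
distance-dependent correlation, which is not fitted.

## Priors and defaults

| parameter | prior | default hyperparameters |
|---|---|---|
| σ²_Y, σ²_Z | inverse gamma | shape 3, rate 1 |
| τ² | inverse gamma | shape 3, rate 2 |
| η | uniform on [0, η_max] | η_max 0.9 |
| shifts ± | normal truncated to sign | centre ±1, sd 0.5 |
| κ (4 of them) | fixed | 3.0 |
| α_g, β_t, ν_g | normal | sd 2, 1, 2 |
| a_δ, a_γ, a_ρ | normal truncated to (0, ∞) | centre 1, sd 1 |
| δ, γ, ρ | trinary | (0.05, 0.90, 0.05) |
| ζ, ξ | Bernoulli | 1 − p_zero = 0.01 |
| b_ζ, b_ξ | normal | sd estimated from data (below) |
| ρ^link | normal | sd 1 |

Two deliberate deviations from textbook choices:

- **Truncated-normal rather than gamma priors for the shared magnitudes.**
  A gamma prior on a Gaussian regression magnitude is not conjugate and
  would force an extra Metropolis step inside an otherwise fully conjugate
  sweep; a positive-truncated normal gives the same support and an exact
  conditional.
- **κ fixed rather than sampled.** The tail-inflation factors are weakly
  identified from the small aberrant fractions of a cohort; fixing them at
  3 keeps the variance updates conjugate and the component labelling
  stable. They are configuration values.

**Empirical-Bayes slab scale.** The prior sd of the outcome effects
`b_ζ, b_ξ` is estimated from the data as twice the 90th percentile of the
absolute per-unit two-group mean differences (positive vs negative
observed pCR), floored at 1. The upper tail is used deliberately: a slab
prior should match the scale of *active* effects, and the bulk of the
per-unit differences is null noise that would shrink the slab to the
point where true effects cannot enter the model.

## Gibbs sampler

All full conditionals are exact; η is the single Metropolis step
(random-walk on the logit of η/η_max with the Jacobian correction).
Enumerations are computed in log space with max-subtraction.

Block structure per sweep (differential mode):

1. **(e_bt, w_bt) jointly**: the state is drawn from its 3-point
   conditional — component likelihood of `Y_bt` times the probability mass
   the score regression places on the state's interval — then the score is
   drawn from the regression truncated to that interval. Because `w̄`
   enters the v-regression, the w-update folds in the v-likelihood
   analytically (the product of the two Gaussians in `w_bt` is again
   Gaussian); probes are processed in within-gene rank groups so each gene
   is touched once per vectorized pass.
2. **(λ_gt, v_gt) jointly**, same construction without downstream terms.
3. **(δ_b, w_b·) jointly**: the trinary indicator is drawn with its score
   row integrated out over the current state intervals (closed form,
   including the v-coupling marginal), then the scores are redrawn.
   Single-site indicator updates conditioned on the scores are
   catastrophically sticky — a large effect can only switch on after the
   scores have drifted toward it, and the scores cannot drift while the
   indicator pins their mean — so the collapsed block is essential for
   mixing, not a refinement.
4. **(γ_g, ρ_g, v_g·) jointly**: 9-point enumeration of the indicator pair
   with the v row integrated out, then v redrawn. This also resolves the
   γ/ρ confounding (both can explain a subtype shift when the gene also
   has differential CNA).
5. Shared magnitudes `a_δ, a_γ, a_ρ` from truncated-normal conditionals.
6. μ chain by odd/even blocks (neighbours are of opposite parity, so each
   half is conditionally independent); τ² conjugate; η Metropolis.
7. ν, α conjugate normals. **β is drawn exactly under the zero-sum
   constraint**: sample the unconstrained conjugate posterior, then
   condition the Gaussian on `1'β = 0` (for equal precisions this is
   centring). Post-hoc re-centring alone is not an exact Gibbs step and
   fails joint-distribution validation.
8. σ² (both platforms) from inverse-gamma conditionals with
   κ-weighted sums of squares; shifts from sign-truncated normals.

Prediction mode replaces steps 3–5 with:

- a **marginal-likelihood inclusion move** for ζ_b (and ξ_g) in which the
  Gaussian coefficient is integrated out analytically against the current
  scores — a spike-slab flip evaluated at a prior-drawn coefficient
  essentially never activates, whereas the marginalized odds respond to
  the residual pattern itself;
- the **score-collapsed inclusion move** (coefficient fixed, score row
  integrated out), the mirror image; alternating the two moves gives
  mixing that neither achieves alone;
- conjugate updates of the outcome effects and of ρ^link;
- exact two-point imputation of every unknown `u_t` from the prior π times
  the joint density of the sample's score columns under u = 0 and u = 1.

Predictive pCR probabilities are Rao-Blackwellized: the exact per-sweep
conditional `P(u_t = 1 | rest)` is stored and averaged over retained
draws, which has strictly lower Monte-Carlo variance than averaging the
binary imputations (both are available).

Defaults: 4,000 iterations with 2,000 burn-in for differential runs
(convergence on simulated data is reached within roughly 2,000
iterations), 30,000 iterations with burn-in 2,000 and thinning 5 for
prediction runs. A single seeded PRNG stream per chain makes runs
bit-reproducible; parallel chains should use distinct seeds.

### Validation

The sampler is validated three ways (all in the test suite):

- every discrete full conditional equals exhaustive enumeration of the
  joint density on a 4-probe/2-gene/6-sample fixture to 1e-10;
- the collapsed blocks match quadrature oracles in distribution;
- a Geweke-style joint-distribution test: moments of
  successive-conditional draws (Gibbs transition alternated with data
  redraws) match marginal-conditional draws (independent prior/data draws)
  within 4 Monte-Carlo standard errors across 16 functionals. The
  functionals use logs of variances and bounded transforms of locations;
  raw second moments of inverse-gamma variates have unreliable
  standard-error estimates.

## Gene lists and FDR control

Five lists are formed from the retained draws, per gene:

1/2. *over-expressed & amplified* (resp. *under-expressed & deleted*) in
the TN subgroup: `γ_g = ±1` **and** a strict majority of the probes in the
gene show `δ_b = ±1`, within the same draw. Majority vote is the
symmetric, order-free reduction of probe-level indicators to a gene-level
call; ties (possible with an even probe count) count as not aberrant,
which is conservative.

3/4. *over (under)-expressed conditional on CNA aberration*: the frequency
of `γ_g = ±1` among the draws in which the gene's majority-vote CNA state
is non-zero (0 if there are no such draws). This conditional-draw reading
is one of several possible renderings of "conditional on aberration" and
is flagged as such.

5. *positive interaction*: `ρ_g = +1`.

Selection at level α sorts the posterior probabilities decreasingly and
takes the largest k whose expected FDR, `(1/k) Σ_{i≤k} (1 − p_(i))`, stays
≤ α (possibly empty). Tied probabilities at the boundary are kept or
dropped as a block, so selection is independent of input order. The
default α is 0.10, a configuration value.

## Smoothed ROC

The ROC of the predictive probabilities is estimated by kernel smoothing
of the two score distribution functions:
`ROC(t) = 1 − F̂_pos(F̂_neg^{−1}(1 − t))` on a 512-point grid, with
Gaussian kernels, quantile inversion by bisection to 1e-8, and trapezoidal
AUC. The bandwidth is a reference rule at the `n^{−1/3}` rate
(`1.3 · scale · n^{−1/3}`, robust scale = min(sd, IQR/1.349)): distribution
functions want substantially less smoothing than densities, and the
density-rate rule (`n^{−1/5}`) leaves visible AUC bias and breaks
invariance under monotone transforms of the scores. Degenerate constant
scores in both groups return the chance diagonal with a warning.

## Synthetic data

Three generators make the whole pipeline testable without any external
download. All are deterministic given the seed and return containers
that satisfy the I/O layer's invariants unchanged.

- **Design 1 (empirical planting).** 1,000 genes with exactly two probes
  each, 50 samples of which the first 10 form the x = 1 subgroup; gene
  and (zero-sum) sample effects from their priors; observations Gaussian
  (sd 0.5) around 0 (log2 ratios) and α + β (expression). The last 50
  genes receive an expression shift of 2 and a log2-ratio shift of 1 in
  the x = 1 subgroup only. This design deliberately does *not* follow the
  model's latent structure.
- **Design 2 (ancestral).** Exact top-down sampling through the model: AR
  baseline chain (η = 0.5, τ² = 1), signal genes (the first block) given
  `δ = γ = ρ = +1` with shared latent magnitude 2 — the one recoverable
  generating value, used as the default signal size — probit scores,
  thresholded states, then mixture observations (σ² = 0.25, shifts ±1,
  κ = 3).
- **Prediction cohorts.** Outcomes Bernoulli(π); of the linked genes, half
  carry the outcome effect (latent magnitude 2) on their probes' DNA
  scores only and half on their RNA scores only, so each platform holds a
  complementary part of the signal and integration is rewarded — the
  premise of the integrated-versus-marginal comparison.

What these generators do *not* emulate: probe-level genomic irregularity
(real inter-probe distances, chromosome structure beyond a single chain),
platform normalization artefacts, outliers beyond the κ-inflated
components, and the marginal distributions of any real cohort. Passing
tests therefore demonstrate correctness of the inference machinery under
the model's own assumptions (and, for design 1, mild misspecification),
not performance on real arrays.

## Problem sizes used in the checks

The shipped validation uses a 200-gene / 400-probe / 50-sample version of
the design-2 study (10 signal genes, preserving the 5% signal fraction)
with 2,000 burn-in + 2,000 retained sweeps; prediction comparisons use
40-gene / 70-patient cohorts with 6 outcome-linked genes, ten replicates,
and balanced 20-patient test splits drawn by the package's own constrained
splitter. These sizes were chosen to keep the full validation suite to a
few minutes while leaving the conclusions unchanged at larger sizes.

## Known limitations

- The γ/ρ attribution is confounded when a gene has both differential CNA
  and differential expression; rankings are reliable, individual-channel
  attribution is not.
- Shared effect magnitudes assume comparable effect sizes across genes;
  strongly heterogeneous effects would be compressed toward the common
  scale.
- The u-imputation for a test patient conditions on scores that were
  themselves sampled under the current imputation, so prediction chains
  mix more slowly than differential chains; the long default run (30,000
  iterations) and Rao-Blackwellization compensate.
- π is a plug-in, not modelled; cohorts whose training prevalence is far
  from the target population's will miscalibrate the absolute predictive
  probabilities (the ranking, and hence the ROC, is unaffected).
- No distance-dependent inter-probe correlation is fitted; η is shared.
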