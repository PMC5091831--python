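# Methods

## Model

Let y_ij be the feather δ²H value (‰, VSMOW-SLAP) of individual i of
species j, for S species observed in one region. The model is a single
multivariate normal over all n individuals:

    y ~ MVN(Xβ, Σ)
    Σ[ii']  = σ_j²                      same individual (s(i) = j)
    Σ[ii']  = σ_j σ_k t_jk λ            i ≠ i', s(i) = j, s(i') = k

with t_jj = 1, so two distinct conspecific individuals have covariance
λσ_j². Equivalently Σ = D[(1−λ)Iₙ + λG]D with D = diag(σ_s(i)) and G the
individual-level expansion of the species correlation matrix. This is the
hierarchical model "species-level random effect with variance λσ_j²,
phylogenetically correlated across species through t_jk, plus independent
residual (1−λ)σ_j²" written marginally.

t_jk is the shared evolutionary path length between species j and k — the
root-to-MRCA distance on an ultrametric tree — divided by total tree depth,
so the species matrix has unit diagonal and λ acts as a pure off-diagonal
multiplier: λC + (1−λ)I. Both endpoints behave as they should (λ = 0:
identity, traits independent of phylogeny; λ = 1: the Brownian-motion
correlation itself).

A tree *sample* is pooled by averaging per-tree correlation matrices
elementwise after rescaling each tree to unit depth (default). The
alternative order — average MRCA node heights across trees first, then
normalize — is exposed as `method="mean_heights"`; with unit-depth
rescaling the two coincide on our generator's trees, and the choice is a
config switch rather than a claim about which a given source used. The
constant of proportionality in "t proportional to shared path length" is
fixed here by unit-depth normalization, which is what makes the object a
correlation matrix; with unnormalized path lengths the same family is
obtained with σ_j rescaled, so fits are equivalent up to the meaning of σ.

### Candidate set

Sixteen fixed-effect structures (intercept-only; species; forage substrate
collapsed to ground vs non-ground; diet; nest substrate; land cover at the
station; dominant land cover within 100 m; wetland area; latitude; mass;
mass + mass²; sex; and the interactions ForSub×Diet, ForSub×Land100m,
NestSub×Diet, ForSub×Diet×NestSub, each with main effects) are crossed with
two variance structures (single σ; per-species σ_j), λ estimated in every
candidate — including the null — giving 32 models. Factors are
treatment-coded against the alphabetically first observed level; linearly
dependent columns (empty or aliased interaction cells) are removed by a
greedy rank filter so every design has full column rank, and the parameter
count k = p + (1 or S) + 1 uses the post-reduction p.

All candidates are compared on the identical record set; records missing
any covariate used by any candidate must be dropped up front by the caller
(the design builder refuses missing values, naming the offending records),
which keeps AICc comparable across candidates.

## Estimation

β is profiled by GLS at any (σ, λ): β̂ = (XᵀΣ⁻¹X)⁻¹XᵀΣ⁻¹y. Under the
homoscedastic model σ² is also profiled in closed form (σ̂² = rᵀV⁻¹r/n),
leaving a one-dimensional maximization over logit λ. Under the
heteroscedastic model the S + 1 parameters (log σ₁…log σ_S, logit λ) are
maximized by L-BFGS-B with analytic gradients:

    ∂ℓ/∂log σ_j = −n_j + Σ_{i∈j} α_i r_i,     α = Σ⁻¹r
    ∂ℓ/∂λ       = −½ tr(Σ⁻¹B) + ½ αᵀBα,       B = D(G − I)D

(the envelope theorem makes these the gradients of the profiled
likelihood). Multi-start (default 4 starts, λ₀ stratified over
{0.25, 0.6, 0.05, 0.9}, σ₀ from per-species OLS residual SDs with log-normal
jitter), ftol 1e-8 on the log-likelihood, logit λ bounded to
λ ∈ (2e-6, 1−2e-6). The log/logit parameterization enforces the bounds
without constrained optimization. All likelihood evaluations go through a
Cholesky factorization; a singular covariance raises an error identifying
the conspecific blocks rather than returning a silent wrong answer.

AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), defined only for n > k + 1; ΔAICc is
against the best candidate and Akaike weights are normalized over the full
candidate set supplied (the 32 candidates in the standard pipeline). Exact
ties are broken by smaller k, then model label.

### Data cloning

`DataCloningRegressor` targets the same MLE by MCMC: a random-walk
Metropolis chain on (β, log σ, logit λ) whose target is K·ℓ(θ) plus proper
diffuse priors (N(0, 10⁶) on β, N(0, 10²) on log σ, N(0, 4²) on logit λ —
their influence vanishes as K grows). The proposal is diagonal Gaussian
with a global scale adapted toward 30 % acceptance during burn-in; a chain
whose final acceptance rate leaves [0.05, 0.8] is flagged as non-mixing.
Posterior means are reported as the estimates, and K × posterior variance
per parameter — on the sampling scale, where the cloned posterior is
closest to Gaussian — is the stabilization diagnostic: as K grows it
approaches the asymptotic ML variance, so clone-scaled posterior SDs at
K = 4 and K = 16 should agree. The direct optimizer is the primary
estimator; data cloning is retained purely as an independent cross-check
of it.

## Identifiability: λ under species-saturated means

When the fixed effects include species (structure 1), the species means
absorb the entire species-level covariance block, and λ is not identified —
in fact the profile likelihood is maximized at λ = 0 for any data. Sketch:
profile out the free species means; what remains is (a) the within-species
contrasts, which depend only on c_j = (1−λ)σ_j², and (b) a penalty
−½ log det Σ̄ for the species-mean block with Σ̄ = diag(c_j(u + 1/n_j)) +
off-diagonal u√(c_j c_k)t_jk, u = λ/(1−λ). Since d/du log det(uT + N⁻¹) =
tr((uT + N⁻¹)⁻¹T) ≥ 0 whenever the species correlation T is positive
semidefinite, that penalty is non-decreasing in u, so the likelihood is
maximized at u = 0, i.e. λ̂ = 0, with σ̂_j² estimating (1−λ_true)σ_j².
This is a property of the model family (fixed species effects confounded
with an exchangeable species-level random effect), not of the optimizer,
and it is why the parameter-recovery study estimates (σ, λ) with the mean
known (zero-column design; the covariance parameters are then fully
identified and recovered within a few percent), while β is recovered from
the full fit, where it is identified and exactly unbiased. Under mean
structures that do not saturate species (traits, station covariates,
intercept-only), λ is identified through the between-species dispersion.
A practical corollary: a fitted λ of 0 in a species-means candidate carries
no evidence about phylogenetic signal.

## Synthetic data

The generator inverts the model: it draws y ~ MVN(Xβ, Σ) with Σ built by
the same covariance expansion the likelihood uses, so simulated data have
exactly the assumed structure. Defaults and fixtures reflect the study
system:

- **Trees** — pure-birth (Yule) trees rescaled to unit depth, with the
  clock run past the final birth event by an Exp(S·rate) draw so terminal
  branches are non-degenerate. Only the shared-path structure matters
  downstream, so the pure-birth stand-in is adequate for a genetic
  pseudo-posterior sample.
- **Effect sizes** — species mean δ²H_f spanning −162 to −127 ‰ (the
  reported range across the 15 retained species) and per-species SDs
  spanning 4 to 22 ‰ (the reported minimum, Mourning Warbler, and maximum,
  Song Sparrow).
- **Covariates** — sex, body mass and station are drawn independently of
  the response unless the chosen structure puts them in β, matching the
  null structure of non-selected covariates. Year is a label; the
  year × species experiment shifts species means between two year labels by
  configured offsets (the observed +4, +9, +12, −6 ‰ pattern by default in
  the power study).
- **Study tables** — the packaged species table (21 species: sample size,
  forage substrate, diet, nest substrate) and station table (coordinates,
  EOSD land cover, wetland area, per-station δ²H summaries) are verbatim
  transcriptions of the published tables; the species n column sums to 279,
  and removing the six flagged species leaves 192 records across 15
  species. The individual-level expansion
  (`make_synthetic_records`) is synthetic: per-species means and SDs are
  anchors consistent with the reported summaries, because the
  individual-level data were not deposited.
- **Designed trait table for the selection study** — 8 species mapping to
  6 distinct (forage, diet, nest) combinations, emulating the coarseness of
  the real table (15 species → 14 combinations). With traits drawn
  uniformly at random, the three-way interaction can saturate species and
  alias the species-means candidate exactly.

What the generator does *not* emulate: isotope measurement error as a
separate term (it is folded into σ_j), spatial autocorrelation between
stations, isoscape surfaces, and any real phylogeny. Passing tests
therefore demonstrate correctness of the estimator under the model's own
assumptions at realistic effect sizes — not robustness to the ways real
feather data violate those assumptions.

## Screening and ANOVA

Screening keeps ASY (after-second-year) birds, drops species below a
minimum of nine individuals, and drops species flagged as non-local
molters. The flagging rule operationalizes a qualitative judgement: a
species is flagged when its mean δ²H_f lies strictly above a configurable
upper bound, default −110 ‰, chosen between the highest local species mean
(≈ −127 ‰) and the lowest mean among the migratory-molt candidates
(≈ −97 ‰). Boundary means are not flagged (strict inequality). Screening is
idempotent.

The year × species test is a two-way fixed-effects ANOVA with interaction,
Type-II sums of squares (the design is unbalanced across species). Because
an unbalanced design makes an externally reported F ambiguous between the
interaction row and the full-model regression F, both rows are emitted.
The simulated detection rate at the observed offsets (n = 15/cell,
σ = 8 ‰, α = 0.001) is validated against the exact noncentral-F power,
which is 0.76 at those settings.

Transfer functions (δ²H_p → δ²H_f regressions per forage guild) are
supplied by configuration — intercept, slope, residual SD and label — and
species means are classified against the point prediction ± residual-SD
band.

## Problem sizes and numerical choices

The validation studies run at: parameter recovery S = 15 × 30
individuals/species × 20 replicates; model-selection recovery S = 8 × 10
individuals/species × 100 replicates × 32 candidates; data cloning S = 3 ×
10 individuals with K ∈ {4, 16} and 30 000 Metropolis iterations. These
sizes give Monte-Carlo error comfortably below the tolerances being
checked while keeping the full suite inside a few minutes. The
data-cloning instance is fixed at parameters whose λ MLE is interior
(λ̂ ≈ 0.6) — agreement between two estimators is only defined at a regular
point. Ultrametricity is enforced with a relative tip-depth spread of
1e-6; covariance PSD checks tolerate −1e-8 relative eigenvalue error;
β-recovery unbiasedness is asserted at the ~5 % familywise level across
the 16 coefficients (max |z| ≤ 3 with Monte-Carlo SEs over 20 replicates).

## Known limitations

- No REML: variance estimates carry the usual ML downward bias at small
  per-species n.
- The "independent conspecifics" covariance switch is valid only for small
  λ·n_j (the implied matrix loses positive-definiteness when between-species
  correlation exceeds what independent conspecifics allow); the default
  literal expansion is always PSD.
- No measurement-error term for the ±2 ‰ analytical error; no spatial
  covariance between stations; no model averaging of β across candidates.
- λ near 1 with multiple conspecific individuals makes Σ singular in the
  limit; the optimizer works on logit λ and cannot reach the boundary, but
  fixed-λ fits at λ = 1 require one individual per species.
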