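# plumage

Phylogenetic multivariate-normal mixed models for feather stable-hydrogen
isotope (δ²H_f) data, with heteroscedastic species variances, Pagel's λ,
AICc multimodel inference, and a synthetic-data generator.

## The problem

Feather δ²H values are widely used to assign migratory songbirds to a molt
(breeding) origin via precipitation isoscapes. Before assignment, one needs
to understand how much δ²H_f varies *within a single region* — among
species, years, habitats and individuals — because that variance propagates
directly into assignment error. `plumage` implements the modelling pipeline
for such a study: individual-level δ²H_f records from many species captured
in one region are screened (after-second-year birds only, minimum sample per
species, exclusion of species whose enriched feather values betray molt on
the wintering grounds), and competing explanations for the remaining
variation — species identity, foraging substrate, diet, nest substrate,
land cover, latitude, body mass, sex, phylogeny — are compared by
small-sample-corrected AIC over a 32-candidate model set.

## The model

For individual *i* of species *j*, the response y_ij (δ²H_f, ‰ VSMOW-SLAP)
is multivariate normal with mean **X**β (one of 16 fixed-effect structures)
and covariance

    var(y_ij)       = σ_j²
    cov(y_ij, y_ik) = σ_j σ_k t_jk λ

where t_jk is the species-level phylogenetic correlation — the shared
root-to-MRCA path length on a unit-depth ultrametric tree, averaged over a
tree sample — and λ ∈ [0, 1] is Pagel's multiplier on the off-diagonal
(λ = 0: phylogenetic independence; λ = 1: Brownian-motion expectation).
The formula is applied literally at j = k, so distinct conspecific
individuals share covariance λσ_j² (an exchangeable species-level random
effect). Each of the 16 mean structures is fit with a single σ
(homoscedastic subset) and with per-species σ_j (heteroscedastic subset),
λ estimated throughout: 32 candidates, ranked by AICc with Akaike weights.

Estimation is exact maximum likelihood: β is profiled by GLS, σ is
additionally profiled in closed form under the homoscedastic model, and the
remaining parameters are maximized on (log σ, logit λ) by multi-start
L-BFGS-B with analytic gradients. A data-cloning estimator (random-walk
Metropolis on the K-fold cloned likelihood) is included as an independent
cross-check: its posterior means converge to the MLE and K × posterior
variance to the asymptotic ML variance as K grows.

The package is organized as scikit-learn-style estimators
(`PhyloMVNRegressor`, `DataCloningRegressor` with `fit`/`predict` and
underscore-suffixed fitted attributes); `fit_ml`/`fit_dataclone` are thin
record-table wrappers around them.

## Worked example

Simulate a study of 8 species × 10 individuals under the species-means
heteroscedastic structure (λ = 0.6, σ_j from 4 to 22 ‰), fit all 32
candidates and rank them:

```python
import numpy as np
from plumage import (ModelSpec, correlation_from_trees, fit_ml,
                     rank_models, simulate_tree_set)
from plumage.selection import format_ranking
from plumage.simulate import (SimulationConfig, make_synthetic_stations,
                              simulate_dataset, species_means_beta)
from plumage.validation import (SELECTION_MEANS, SELECTION_SIGMA,
                                selection_trait_table)

trees = simulate_tree_set(8, 100, seed=1)
corr = correlation_from_trees(trees)
traits = selection_trait_table()
stations = make_synthetic_stations(seed=1)
cfg = SimulationConfig(species_count=8, n_per_species=10,
                       beta=species_means_beta(SELECTION_MEANS),
                       sigma=SELECTION_SIGMA, lam=0.6, seed=1)
records = simulate_dataset(cfg, traits, stations, corr)
fits = [fit_ml(ModelSpec(fid, var), records, traits, stations, corr)
        for var in ("hom", "het") for fid in range(16)]
print(format_ranking(rank_models(fits).head(5)))
```

prints

```
model           fixed_effects  k  loglik   aicc delta_aicc waicc
 Het1                 Species 17 -249.76 543.39       0.00 0.994
Het14          NestSub x Diet 14 -260.45 555.35      11.97 0.003
 Hom1                 Species 10 -266.41 556.01      12.62 0.002
Het15 ForSub x Diet x NestSub 15 -260.45 558.39      15.01 0.001
Het11                     Sex 11 -266.37 558.62      15.23 0.000
```

The generating candidate (species means with per-species variances, `Het1`)
receives essentially all the Akaike weight; the heteroscedastic subset
dominates its homoscedastic twin (`Hom1`, ΔAICc = 12.6). The fitted λ of the
top model is 0: with species means in the fixed effects, the species-level
covariance block is absorbed by the means and λ collapses — see
`docs/methods.md` for why this is a property of the model family, not of
the optimizer.

A command-line pipeline mirrors the analysis stages
(`plumage simulate | screen | fit | rank | anova | run-all`); `run-all`
takes a JSON configuration naming the input tables, tree file, screening
settings and output directory, and writes the screening report, 32 fitted
models, ranking table, ANOVA table and a reproducibility manifest.

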