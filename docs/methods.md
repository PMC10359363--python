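# Methods

`avishift` implements an attribution analysis for two-era occupancy
atlases: given presence/absence of many species on a ~50-km grid at two
survey eras roughly three decades apart, it asks how much of the
observed colonisation and local-extinction dynamics is explained by
climate suitability and its change, by land cover, by spatial structure
(proximity to persisting populations), and by species traits.  This
note documents the models, the choices made where the design was open,
and what the synthetic validation does and does not establish.

## Data model

An **occupancy atlas** is a grid table (cell centroid, country,
ecoregion unit, altitudinal range, protected area, and a
sampling-effort comparability flag) plus a presence map over
(species, cell, era) with exactly two eras.  All event analyses run on
the comparable-cell subset; the mask exists because historical surveys
cover some regions only qualitatively.  The roster filter removes
introduced species, irregular breeders, marine species, and species
occupying fewer than five cells; the era to which the five-cell rule
applies is configurable (`any`, default, or `era1`/`era2`/`both`),
since either convention is defensible when the rule is stated without
an era.

## Bioclimatic variables

Eight variables summarise monthly temperature and precipitation over a
climatic window (default windows 1968–1988 and 1997–2017): annual
means, monthly extremes, temperature seasonality as the population SD
of the 12 monthly means (plain °C, no ×100 convention), and
precipitation seasonality as the coefficient of variation (defined as 0
for zero mean).  Variables are computed on the window-mean climatology;
a per-year variant (`bioclim_average="per_year"`) is available because
the two conventions differ for extremes.  Both choices are monotone
transformations apart, and downstream models z-score their inputs, so
the distinction rarely matters in practice.

## Variable selection

All subsets of size 3–5 of the eight variables (182 combinations) are
screened to require at least one thermal and one hydric member (10
discarded) and to exclude any pair with |Pearson r| > 0.7 across study
cells (strict inequality; computed on era-1 values over comparable
cells).  Survivors are ranked per species by the AIC of an unpenalised
binomial B-spline GAM (6 basis functions per term) fitted on all cells
— screening precedes the blocked cross-validation, so no blocking here.
AIC is computed from clipped fitted probabilities with the basis
dimension as the parameter count; under quasi-separation the raw
likelihood is −∞ and would otherwise poison the ranking.  Ties break
lexicographically.  The consensus combination is the one most often in
species' top AIC quartiles, with the quartile as ceil(n/4).

## Ensemble SDMs with ecoregion-block cross-validation

Ecoregion units (contiguous patches of a climate-cluster "ecoregion")
are grouped into ten blocks by a greedy pass that keeps each block's
mean z-scaled bioclimate close to the global mean, with a cell-count
balance penalty; units are assigned whole so that held-out data are
spatially segregated from training data.  Four techniques are fitted
per species, each ten times leaving one block out:

- **GLM** — polynomial logistic regression; per-variable degree ∈ {1, 2}
  chosen by mean held-out AUC over the full degree grid.
- **GAM** — B-spline smooths (df 6); predictions are clamped to the
  training support (constant extrapolation), the usual convention when
  projecting to a shifted climate.  A perfectly separable fold falls
  back to a quadratic GLM, which predicts such folds perfectly.
- **GBM** — gradient boosting; tree complexity ∈ {1..4} chosen by the
  minimum summed held-out Bernoulli deviance (the "error" matching the
  fitting objective); learning rate 0.001 and 5000 trees by default.
- **RF** — random forests; mtry ∈ {1..3}, trees grown from 1000 in
  steps of 500 until the relative AUC gain falls below 1%.

This yields 40 models per species.  Held-out AUC uses the rank-statistic
form; a held-out block containing a single class records an undefined
AUC (excluded from summaries, weight zero in ensembles).  Ensemble
prediction is the AUC-weighted mean with weights max(AUC − 0.5, 0)
(raw-AUC weights available); *baseline* suitability is the per-cell
median of the 40 era-1 projections and *change* is median(era2) −
median(era1).  Both the median and the weighted-mean variants are kept,
since both are defensible summaries of an ensemble.

`SDMConfig.desk()` is the configuration used for the small synthetic
grids in the tests and the reproduction script (boosting: learning rate
0.01, 200 trees, complexity 1–3; forests: 100–300 trees): on a few
hundred cells the full-size search adds runtime without changing the
selected models' behaviour.

## Range-shift statistics

The centre of gravity (COG) of a weighted cell set is the weighted mean
of centroid unit vectors on the sphere, renormalised — no projection
choice, exact for symmetric toys; a planar equal-area variant would
differ negligibly at the study extent.  Shifts are haversine distances
on a 6371-km sphere with initial bearings in (−180°, 180°], 0 = north;
rates divide by the era separation (default 30 years).  Observed shifts
weight the COG by presence; predicted shifts weight it by the ensemble
suitability surface of each window.

Cohort comparison uses the **Watson–Wheeler** k-sample test on bearings
(uniform scores of pooled circular ranks; χ² with 2(k−1) df when every
group has ≥ 10 angles, otherwise a seeded permutation null with ≥ 9999
permutations; mid-ranks with a warning on ties) and the **Wilcoxon
signed-rank** test on paired distances (V = sum of positive-difference
ranks, exact p for n ≤ 25 without ties).

## Event models

For each species, comparable cells are classified by the 2×2 presence
truth table: colonisation, extinction, continually occupied, never
occupied.  Colonisation failures are sampled from never-occupied cells
(uniformly, or with probability ∝ 1/distance to the nearest continually
occupied cell), extinction failures from continually occupied cells,
matched one-to-one to the success count.  The distance covariate of a
continually occupied cell is its distance to the nearest *other*
continual cell — with self-distance zero the covariate would separate
extinction successes from failures by construction.  Distances are
z-scored in raw km (log-distance available as a config option).
Covariates: baseline/change climate suitability, baseline/change
favourable land cover (mean over three habitat-to-class aggregation
schemes), Shannon habitat diversity, altitudinal range, protected area,
the two distance covariates, and the species traits; all continuous
covariates z-scored over the assembled table; species with missing
mandatory traits are dropped listwise with counts logged.

The model is a logistic mixed model on the latent scale with fixed
effects Xβ and random intercepts for phylogeny (covariance σ²ₚA),
species, cell and country, plus a residual with variance fixed at 1
(non-identifiable in binary models).  A is the Brownian-motion
expectation: shared root-path length over tree depth, unit diagonal for
ultrametric trees.  Variance components carry inverse-gamma(ν/2, νV/2)
priors with V = 1, ν = 0.002, floored at 1e−10.

Sampling is Gibbs with Pólya-Gamma augmentation: ω_i ~ PG(1, ψ_i) makes
β, every random-effect vector and every variance conditionally
conjugate.  PG variates use the truncated sum-of-gammas series (32
terms) plus the deterministic mean of the dropped tail, which keeps
E[ω] exact; the residual truncation bias is far below the Monte-Carlo
noise at the chain lengths used.  The full protocol is 220,000
iterations, burn-in 20,000, thinning 200 (1000 retained draws);
`desk()` (22,000/2,000/20) and `quick()` (4,400/400/4) keep the same
retained count at reduced cost for the synthetic tables, whose few
thousand rows mix far faster than a continental dataset.  Split-chain
R̂ > 1.1 on any coefficient raises a warning.

Posteriors from ten trees × ten absence resamples are pooled with equal
weight (100 runs).  Marginal R² per draw is var(Xβ) / (var(Xβ) + Σ
random variances + 1 + π²/3), the standard latent-scale decomposition
for logit GLMMs.  Per-predictor variance shares are var(x_k β_k)
normalised over predictors per draw — an independent-contribution
convention, chosen because no exact partition exists for correlated
predictors; it is reported as a percentage with median/IQR/95% bands.

## Synthetic studies

The generator builds a geographically real grid (default 24×24 cells of
nominal 50 km near 10–26°E, 40–51°N, so geodesy sees true curvature),
fifty years of monthly climate (latitudinal gradient, seasonal
sinusoid, smooth spatial random fields, interannual noise) with a
linear trend sized to give a +1.5 °C difference between the two
climatic windows, Dirichlet land-cover mosaics with small spatially
correlated drift, pure-birth trees (depth normalised to 1) with
Brownian traits, and 60 Gaussian-niche species.  Era-1 occupancy is
Bernoulli in niche suitability; era-2 occupancy is generated cell-wise
from a known logistic event model with coefficients (on z-scored
covariates) β = (−2.0, +1.5, +0.75, −1.0) for colonisation and
(−2.0, −1.5, −0.75, +1.0) for extinction — intercept, baseline
suitability, suitability change, distance to the nearest occupied cell
— plus phylogenetically correlated species intercepts (variance 0.25).
These defaults give event rates, prevalences and effect sizes of the
order seen in continental atlas comparisons.  The distance-ablation
analysis uses a variant with the distance coefficients at ∓2.5 and the
suitability effects at ±1.0/±0.5: a regime where dispersal dominates,
which is the condition under which removing the distance covariates
must visibly degrade the fixed-effect fit.  Ecoregion units come from
k-means on location + climate split into contiguous components; all
randomness flows from one root seed through per-component spawned
streams, so regeneration is bit-identical.

What the generator does **not** emulate: observation error or
detectability differences between eras beyond the comparability mask,
range dynamics with temporal autocorrelation inside an era, biotic
interactions, and the real collinearity structure of continental
climate.  Passing tests therefore demonstrate that the pipeline's
estimators recover the truth of this generative family — not that the
pipeline's conclusions transfer to any particular real atlas.

## Numerical choices and degenerate inputs

- AUC is undefined (NaN, never an exception) when a class is absent.
- An all-zero-weight ensemble falls back to equal weights with a warning.
- Collinearity screening of a constant variable is a hard error naming it.
- Z-scaling a zero-variance covariate is a hard error naming the column.
- A species whose continual set is empty (or a singleton, for
  extinction models) is excluded from distance-dependent models and
  logged.
- AIC ties and block-assignment ties break deterministically
  (lexicographic / seeded order).
- The phylogenetic covariance gets 1e−8 jitter before inversion.

## Problem sizes in the validation suite

The test suite and the reproduction script run on scaled-down studies:
16×16 or 12×12 grids for SDM ensembles (six to eight species per
cohort), the default 24×24/60-species study for event-model recovery
(ten replicates at the `quick` chain length), and an 8×8 study for the
100-run posterior combination.  These sizes were chosen so each check
isolates one property at a precision its assertion needs.
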