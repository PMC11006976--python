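# Methods

## Index arithmetic

The germination index of a dish is `GI = Σ_d n_d / t_d` with `t_d` the
1-based day of counting; a dish terminated early simply has a shorter
count sequence, and a dish with no germination has GI = 0. GI is a count
scaled by speed, not a fraction: it is deliberately **not** divided by the
number of seeds per dish, so indices are comparable only between
experiments that used the same dish size (50 seeds by default). Scaling
every count by k scales GI and all indices by k.

Each tolerance index is `Σ_i GI_i w_i / 5` over the five treatment levels
with severity weights `1 + |W|` (drought, MPa), `T1/T` (cold, °C, reference
25 °C) and `S/10` for stressed saline levels with the control fixed at 1.
All weights are ≥ 1, so an index is bounded below by the unweighted mean
GI. The saline index is computed structurally like the other two (the
control's GI enters with weight 1); an alternative reading that drops the
control term is available via `gsti_interpretation="literal"` in
`compute_indices` — the symmetric form is the default because the three
experiments are otherwise identical in design and the control level is
explicitly the reference in all three.

Indices are computed per replicate by default, pairing replicate r across
the five levels of each experiment. This preserves within-population
replication for the ANOVA downstream. A `population_mean` mode averages GI
per level over replicates first; for balanced data the two differ only in
whether replicate spread is retained, since the index is linear in GI.
Weights are bound to the stress type (water potential → drought weight,
temperature → cold weight, concentration → saline weight), not to an
experiment number.

## Trait descriptives

Per trait: minimum, maximum, Max/Min, mean, and CV = 100 · sample SD
(n − 1 denominator) / mean, computed over all population × replicate
values; traits must be strictly positive for CV to be meaningful. The
one-way ANOVA treats the populations as fixed groups with replicates as
observations (21 groups → df = 20), computed via `scipy.stats.f_oneway`;
the replicate seed lots of a population are treated as exchangeable
observations rather than nested quadrats. Summaries are rounded to 2
decimals for reporting only; full precision is kept internally.

## Gradient and environmental regressions

Gradient fits are ordinary least squares of one trait on one of latitude,
longitude or altitude, by default on population means (one point per
population, n = 21); significance classes are assigned at 0.05/0.01/0.001
from the slope t-test. A constant response is treated as a degenerate fit
(slope 0, R² 0, p 1) rather than an error so flat synthetic traits do not
halt a panel; a constant gradient is an error.

Environmental attribution regresses each trait on all six predictors
(MAT, MAP, SOC, AN, AP, pH) simultaneously — no stepwise selection — with
both response and predictors z-scored (sample SD), so coefficients are
standardized effect sizes comparable across predictors and traits.
Significance classes add the marginal p < 0.1 tier used for display. A
raw-units mode is available behind a flag. Rank-deficient designs raise a
collinearity error naming the dependent columns.

## Mixed models

The random-intercept model `y = Xβ + Zb + e` is estimated by REML,
profiling over the single variance ratio λ = σ²_pop/σ²_resid: fixed
effects are the GLS solution at each λ, the residual variance has a
closed form, and the criterion is minimized over log₁₀ λ ∈ [−8, 8]
(bounded scalar optimization, xatol 1e-8) with the λ = 0 boundary checked
explicitly. Boundary fits report zero population variance, flagged but
not an error. Per-group Woodbury identities keep each criterion
evaluation O(n·p²). Fixed-effect p-values use t statistics on
n − p − g + 1 residual degrees of freedom — a simple approximation;
Satterthwaite/Kenward-Roger corrections are out of scope, so p-values
near the 0.05 boundary should be read cautiously in small samples.

The block effect decomposition splits the fixed-effect (marginal)
explained variation between the morphology block (length, width, LWR,
TGW) and the nutrient block (CSP, CSS, CS, CCF) by commonality analysis
on GLS-whitened data at the fitted λ: each block keeps its unique R² plus
half of the shared portion, normalized so the two shares sum to one.
"Effect decomposition" has no single canonical definition for mixed
models; the commonality partition was chosen because it reproduces
block-level "% explained" semantics and degrades gracefully under
collinearity. A cruder normalized-|β| alternative is available via
`method="abs_beta"`. When the marginal R² is essentially zero the shares
default to 0.5/0.5 and should not be interpreted.

## Path model

Block composites are first-principal-component scores of z-scored
variables, with the component oriented so its loading sum is positive
(first loading breaks ties) — this makes scores deterministic and
readable as "more of the block". The structural model is fully recursive
(acyclic) over observed composites and indices, so per-equation OLS on
z-scored variables gives the maximum-likelihood estimates; no iterative
covariance fitting is needed. The implied covariance is assembled as
Σ = (I − B)⁻¹ Ω (I − B)⁻ᵀ with the exogenous block (climate, soil) fixed
at its sample covariance and diagonal endogenous residual variances
(n − 1 denominators throughout, so a saturated model reproduces the
sample covariance exactly and χ² = 0 at df = 0).

Fit statistics: `F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p`, χ² = (n−1)·F_ML,
`GFI = 1 − tr[(Σ⁻¹S − I)²]/tr[(Σ⁻¹S)²]`, CFI against the independence
baseline (all covariances zero, variances free — the conventional
default), and `RMSEA = sqrt(max(χ²−df, 0)/(df(n−1)))`, defined as 0 when
df = 0. Direct effects are the path coefficients; total effects are
(I − B)⁻¹ − I, indirect their difference, so total = direct + indirect
holds exactly. The default edge set sends soil to morphology, climate and
soil to nutrients, climate to all three indices, morphology to GDTI and
GSTI, and soil and nutrients to GCTI; any acyclic edge list can be
supplied as JSON.

## Synthetic data generator

The generator's defaults encode the study design: 21 populations with
sites uniform in 35.83–38.32 °N, 90.86–102.76 °E, 1,866–3,832 m; MAT
falling with altitude and latitude (clipped to −1.5…8.3 °C) and MAP
rising eastward (clipped to 67…427 mm); 3 replicates; 50-seed dishes;
15 daily counts. Soil chemistry loads on a latent soil axis driven by the
climate composite; morphology and nutrient traits load on latent block
axes driven by the soil/climate composites with population- and
replicate-level Gaussian noise (traits mapped to realistic units and
resampled, with a warning, in the rare case a draw is non-positive; LWR
is computed as length/width). Direct trait-on-geography effects default
to zero — gradient patterns emerge through the environment — but a
`gradient_effects` map can inject known slopes for calibration tests.

Germination is a discrete daily-hazard process, matching daily counting:
each dormant seed germinates on a given day with probability
`base_hazard · exp(tolerance_scale · latent) · exp(−sensitivity · severity)`
clipped to [0, 1], where severity is the level's normalized harshness
(|W|/1.2, (25−T)/20, S/200) and the per-population latent tolerance is a
linear function of the climate/soil/morphology/nutrient composites. Daily
counts are binomial draws over the surviving seeds. The latent enters the
hazard, never the index arithmetic, so index computations are tested
against data they did not generate. The optional 5-consecutive-zero-days
stopping rule is off by default (rectangular fixtures) and available for
variable-length testing. Defaults (base hazard 0.35, tolerance scale 0.5,
sensitivities 2.5/2.0/2.0) give control-dish germination mostly within
the first week and strong but incomplete suppression at the harshest
levels.

What the generator does *not* emulate: spatial autocorrelation beyond the
linear climate trends, non-Gaussian trait distributions, seed dormancy or
viability loss, and between-dish micro-environment effects. Passing tests
therefore demonstrate the correctness of the estimators under the assumed
linear-Gaussian causal structure, not the field realism of any particular
coefficient value.

## Test and verification scale

Unit and property tests run at the study design size (21 × 3). Recovery
checks scale up where precision demands it: standardized environmental
effects at 500 populations against coefficients derived in closed form
from the generator's own equations (using a high-signal configuration so
the sampling SD per coefficient is well inside the tolerance band),
mixed-model fixed effects as a mean over 200 simulated studies, path
effects at n = 2000, and the null false-positive calibration of the
gradient tests over 500 generated studies (a smaller batch estimates a
~2% family-wise rate too coarsely to compare against a 5% bound). Profile
REML is verified against closed-form balanced variance components, a
101-point grid search over λ, and `statsmodels` MixedLM.

## Known limitations

- Mixed-model p-values are approximate (no Satterthwaite df).
- The path model handles observed composites only — no latent-variable
  measurement model, bootstrap errors, or modification indices.
- Indices are dish-size dependent by construction; compare only across
  equal designs.
- With only replicate-level trait noise inside populations, the random
  intercept absorbs most population-level index variation, so
  fixed-effect estimates in the mixed model are driven by
  within-population contrasts and can be weak on small synthetic studies.
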