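# Methods

`heliosel` implements the statistical chain used to ask whether proximity to
a mass-flowering crop alters natural selection on a wild relative: paired
near/far common-garden populations, Lande–Arnold phenotypic selection
analysis within each population, mixed-model ANCOVA across populations,
variance-ratio tests of selection homogeneity, and multigroup piecewise
structural equation models that attribute selection to mutualists
(pollinators) and antagonists (seed predators). A synthetic-data generator
reproduces the design with known ground truth so every stage is testable
without field data.

## Data model and derived variables

A plant contributes: mean seeds per bagged inflorescence and total
inflorescence count (their product is the whole-plant seed estimate `W`, the
lifetime-fitness measure for an annual); stem height (cm) and basal diameter
(mm), combined into stem volume `pi r^2 h`, computed in mm^3 (heights are
converted to mm — the raw measurements mix cm and 0.1-mm scales and a single
volume unit avoids silent factor-of-ten errors); four inflorescence traits
(disk diameter DD, ray length RL, ray width RW, ray number NR); up to five
disk flowers with eight corolla measurements each, reduced to five
per-plant composites (CS = CL x CW, DTW, DTL, PTS = PTL x PTW,
TS = TL x TW). Products are taken per flower *before* averaging across a
plant's flowers: the mean of products is the unbiased plant-level size of a
two-dimensional structure, and it differs from the product of means whenever
flowers are heterogeneous. Seed-predator damage by the moth *Isophrictis*
(ISO) and the midge *Neolasioptera* (NEO) is the proportion of examined
seeds (~80 per plant) destroyed by each taxon. Pollen deposition is
mean grains per stigma x 100 flowers per inflorescence x inflorescence
count, with the per-inflorescence flower number treated as a constant.

Relative fitness is `w = W / mean(W)` within each population, so the
population mean of `w` is 1 by construction. The analysis response is
`log(w + c)` with offset `c = 1` by default: zero-seed plants are real
(inflorescence counts run to zero) and must stay in the analysis, and
`log(w + 1)` keeps them at a finite value while preserving monotonicity.
`c = 0` gives the classical log relative fitness and is used wherever
estimates must sit on the exact log-fitness scale (see parameter recovery
below); with `c = 0` zero-fitness plants are dropped with a warning. Raw
relative fitness is available by configuration for the textbook covariance
definition of the differential.

Traits are standardized within population (mean 0, SD 1, sample SD with
n−1). `transform_policy = "auto"` applies `log1p` to a variable whose
absolute skewness exceeds 1 and an arcsine-square-root to proportions;
thresholds are fixed and every applied transform is recorded, because
"transform as necessary" is otherwise unreproducible. Missing values
propagate: a plant lacking one trait leaves only that trait's analyses, so
per-trait sample sizes may differ. Plants whose seed bag was lost (no
per-inflorescence seed count) are excluded from fitness-based analyses by
default; a configuration switch counts them as zero seeds instead, since
the right choice is a judgment call the data cannot settle.

## Selection analysis

The selection differential `s'` of a trait is the covariance (n−1
denominator) between the standardized trait and the fitness response —
total selection, direct plus that transmitted through correlated traits.
Its p-value is the Pearson correlation test of trait against fitness.
The selection gradient `beta` is the trait's partial coefficient in a
single OLS regression of fitness on all covariates simultaneously: the nine
floral traits, ISO, NEO, and stem volume (volume absorbs size-mediated
selection that would otherwise masquerade as floral selection). Standard
identities hold and are enforced by tests: with standardized traits
`s' = r x SD(fitness)`, and on an exactly orthogonal design gradients equal
differentials trait by trait.

Per-trait p-values are reported descriptively without multiple-comparison
correction; the summary instead counts significant cases against
`round(alpha x n_cases)` expected by chance, overall and within trait
classes (inflorescence, disk flower, antagonist). Collinearity is screened
with VIFs (`1/(1−R²)` of each covariate on the rest) and condition indices
(ratios of singular values of the unit-column-scaled design, intercept
included). Defaults flag VIF > 5 (warn; triggers a refit dropping the
highest-VIF covariate and checks that surviving gradients stay inside the
original 95% CIs), and fail at VIF > 10 or condition index > 30. Population
exclusion for assumption violations is reported, never automatic.

## Proximity ANCOVA

Whether selection differs near versus far from the crop is tested with a
linear mixed model at the plant level: response = (log) relative fitness,
random intercept per population, fixed effects site x proximity x trait
(plus year and its interactions for multiyear data). For total selection
the model takes one trait at a time; for direct selection a single model
carries all twelve covariates, each crossed with the design factors. The
trait x proximity term tests a consistent near/far difference in selection;
higher-order interactions with proximity flag context-dependent
differences, and `classify_effects` encodes exactly that rule.

Term tests are marginal (Type III) Wald F tests under sum-to-zero
contrasts, because interactions are interpreted in the presence of main
effects. Denominator df use a containment-style between/within split:
terms whose design columns are constant within populations are tested
against the number of populations minus the between-population columns;
plant-level terms against N − m − (within columns). This is the convention
of the nested mixed-ANOVA lineage (`nlme::lme`) that this analysis style
descends from; a residual-df alternative is available by configuration and
the method used is recorded in every result. At the designs involved
(hundreds to ~1000 denominator df) the choice is numerically immaterial.
A singular or non-converged random-intercept fit falls back to pooled OLS
with a logged warning — the exact zero-variance limit of the mixed model,
and a property test verifies the F statistics agree with an independent
normal-equations computation there.

## Homogeneity of selection

Whether selection is more heterogeneous in one arm is tested with
variance-ratio F-tests on the per-population selection coefficients:
`F = var(far) / var(near)` with (n−1) df per arm. For the pooled all-trait
test, coefficients are first recentered to mean zero within each trait
across all populations (both arms pooled; per-arm recentering available by
flag), so that traits differing in their typical direction of selection do
not inflate apparent heterogeneity; traits are stacked unweighted.
Per-trait tests use raw coefficients. P-values are two-sided,
`2 x min(P(F' <= F), P(F' >= F))` capped at 1 — reciprocal-symmetric
(`p(F, d1, d2) = p(1/F, d2, d1)`) and equal to 1 at F = 1 with equal df.
Degrees of freedom are always derived from the data at hand and printed
with the result. Recentering estimates one mean per trait from the pooled
arms, which in principle could distort the null distribution of the pooled
F statistic; the null-calibration simulation in the verification suite
(recentre, stack, test, at 11 traits x 12 populations per arm) shows the
rejection rate stays at the nominal level for tables of this size.

## Piecewise SEM and the multigroup analysis

The a priori causal model sends composite floral traits to interactor
activity and interactor activity to fitness: {inflorescence_PC, flower_PC}
-> {ISO, NEO, pollen}, {ISO, NEO, pollen} -> w, {volume, n_inflorescences}
-> w, with the pollen node present only where deposition was measured. The
composites are first principal components of the correlation matrix of each
trait block, computed on the population-pair's combined (site-year) data;
loadings are sign-flipped so every constituent trait correlates
nonnegatively with the scores, making positive trait -> interactor paths
read as "bigger flowers, more visits", and scores are re-standardized.

Goodness of fit is Shipley's d-separation test. The basis set contains one
claim per non-adjacent variable pair, conditioned on the union of both
variables' parents, with the regression response chosen so it is never an
ancestor of the predictor; claim order is canonical (topological, then
lexicographic). Each claim is tested as the two-sided t-test of the
predictor's partial coefficient in a linear regression, and Fisher's
`C = −2 Σ ln p` is referred to chi-square with 2k df; `p > 0.05` means the
data do not contradict the claimed absent paths. An exhaustive oracle test
verifies the basis set against brute-force d-separation on *every* DAG with
up to four nodes and on random 5–6-node DAGs. Exogenous-exogenous pairs are
included in the basis set (strict DAG semantics); note that a model whose
exogenous variables are really correlated — composite trait blocks usually
are — will therefore be penalized unless the correlation is modeled as an
edge.

The multigroup analysis walks the paths in canonical order. For each path,
the response is regressed on its parents, a group indicator, and
parent x group interactions for the focal path and every same-response path
already freed; a focal interaction p below alpha (0.05) frees the path.
Free paths report per-group coefficients, constrained paths a pooled
coefficient with the group main effect retained. Fisher's C in the
multigroup setting tests a claim within each group when a freed path
touches either of the claim's variables, and on the pooled data otherwise;
this rule (one of several defensible ones — the multigroup literature does
not fix it) is deterministic and configurable in the code.

All endogenous responses are modeled linear-Gaussian; proportion responses
are transformed upstream by the standardization policy rather than with
link functions, since every variable is standardized before the SEM.

## The synthetic generator

The generator is the package's definition of the study conditions: one near
and one far population per site x year x seed-source cell (default
2 x 2 x 2), each with 80–155 plants. Nine floral traits are multivariate
normal with a block correlation structure (0.4 among inflorescence traits,
0.5 among disk-flower traits, 0.2 between blocks) — morphological
integration is stronger within organ classes. Default ground-truth
gradients put moderate positive selection on the display traits
(DD 0.20, RL 0.15, NR 0.15, RW 0.10) and weak selection on disk-flower
dimensions, the pattern such experiments are designed to detect. Attack
counts are beta-binomial (precision 30) out of 80 examined seeds, with
logit-scale links to traits and a x1.5 far-arm rate multiplier; pollen
arrival is Poisson with a log-normal plant effect, trait links, and a x1.3
near-arm multiplier — far arms see more seed predators, near arms more
pollinators. Expected seeds are log-linear in the standardized traits, stem
size and realized damage proportions, with environmental noise
(SD 0.3) and a negative-binomial realization (k = 10, overdispersed counts).
The fitness penalty acts on the realized measured damage proportion — the
destroyed seeds are what cost fitness — which also makes the ground-truth
coefficient vector the exact estimand of the gradient regression. Per-plant
inflorescence counts and per-inflorescence seed means are then chosen to
reproduce the realized totals, so the generated raw tables round-trip
through the same derivation code as field data.

Randomness is one `numpy` Generator per population, seeded from the global
seed and a CRC-32 hash of the population id: populations are independent
of generation order, and a fixed seed reproduces byte-identical CSVs.

What the generator does not emulate: spatial structure within plots,
pollinator foraging behavior, phenology, trait measurement error beyond
flower-to-flower noise, environment–fitness covariance, and real
trait–attack effect sizes (the field values are unknown; defaults are
chosen for testability). Passing tests therefore demonstrate correctness
and calibration of the statistical machinery under the declared generative
model, not fidelity of any particular field estimate.

## Verification strategy and problem sizes

Parameter recovery is evaluated on the exact log-fitness scale
(offset c = 0), because the ground-truth gradients are defined there; the
default c = 1 offset is a deliberate, documented distortion that buys
robustness to zero-seed plants. Across 200 replicated 120-plant
populations, per-trait mean bias of the gradient estimates stays within
0.02 and nominal 95% intervals cover truth at 93–97%. Null calibration of
the ANCOVA trait x proximity test uses 1000 simulated paired experiments
(2 sites, 80 plants per population, identical selection in both arms); the
pooled homogeneity test uses 1000 simulated coefficient tables at the field
scale (11 traits, 12 populations per arm). Multigroup power and specificity
use 200 replicates of a four-node model with a 0.5 coefficient difference
on one path at n = 100 per group. These sizes give Monte-Carlo standard
errors a few times smaller than the acceptance bands while keeping the
whole verification run in minutes on one core.

## Known limitations

- Nonlinear (quadratic) and correlational selection are out of scope, as
  the per-population sample sizes that motivate this design cannot support
  them.
- The mixed ANCOVA fits random intercepts only; random slopes for
  trait x population are not implemented.
- The SEM is local-estimation piecewise only: no latent variables, no
  covariance-based global fit, no bidirected edges — correlated exogenous
  blocks must be handled by adding an edge or accepting the fit penalty.
- Containment df are an approximation; they are exact for balanced nested
  designs and immaterial at these sample sizes, but small unbalanced
  designs would warrant a Satterthwaite-style method not implemented here.
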