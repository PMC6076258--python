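# Methods

## Model and scope

The package predicts the *direction* of plasma metabolite changes implied
by a liver gene-expression contrast, on top of a constraint-based
metabolic model. It deliberately does not estimate absolute metabolite
concentrations, fit fluxes from isotope-labeling data, or call
differential expression from reads — expression contrasts, measured
fluxes and boundary rates all arrive as summary tables.

The central quantity is a weighted flux-minimization production cost per
metabolite. The intuition: if treatment up-regulates the enzymes along
the routes that make a metabolite, then producing it at near-maximal rate
requires less "transcriptional effort" under treatment weights than under
control weights, and its plasma level is predicted to rise.

## Pipeline stages and their assumptions

**Expression → weights.** Per gene, the log2 fold change is shrunk
multiplicatively by significance, $r_g = \log_2\mathrm{FC}\,(1-\mathrm{FDR})$,
which uses every measured gene without a significance cut-off: certain
changes pass through, hopeless ones are zeroed, and the shrinkage is
continuous in between. GPR aggregation treats AND as the limiting subunit
(child of minimum magnitude) and OR as the dominant isozyme (maximum
magnitude). The weight pair $w_{control} = 2^{+r_j/2}$,
$w_{treatment} = 2^{-r_j/2}$ was chosen for three properties:
antisymmetry ($w_c(r) = w_t(-r)$), unit product before clipping (neither
condition is globally cheaper), and boundedness after clipping to
$[1/8, 8]$ (a single extreme gene cannot dominate the whole objective).
Base, scale and clip bounds are exposed as arguments of
`compute_reaction_weights`; the OR rule can be swapped for a magnitude
sum by replacing `reaction_expression`. Model genes absent from the
expression table count as unchanged ($r_g = 0$); table genes absent from
the model are counted and ignored.

**Constraints.** Uptake rates are *fixed* (both bounds of the exchange
reaction set to $-u$, with an optional fractional tolerance, default 0);
secretion rates set lower bounds only; explicitly unconstrained
metabolites (O2, CO2, vitamins) stay fully open; every other exchange is
closed to uptake but open to secretion. Identical boundary conditions are
applied to control and treatment — the contrast comes from the weights
alone. Measured fluxes constrain mapped reactions to
$[\text{mean} - k\,\text{SD}, \text{mean} + k\,\text{SD}]$ intersected
with existing bounds ($k = 1$ by default, exposed as `sd_multiplier`);
an empty intersection is an error rather than a silent widening.
Relative flux sets (reference enzyme = 100) must be rescaled to absolute
units explicitly — units are a mandatory declaration, never assumed.
Short-fast (5 h) flux sets are extrapolated as 1.2× the measured 10-h
glucose output, split by literature fractional contributions.
`chi2_ssr_acceptance` returns the central chi-square interval used to
judge whether a flux fit's sum of squared residuals is consistent with
the measurement error model (at 22 degrees of freedom and 99% confidence
this is [8.6, 42.8]).

**Scoring.** $v_{max}$ is the LP maximum of the metabolite's exchange
flux; metabolites with $v_{max}$ at or below a capability floor (1e-6)
are *unscored* and excluded from the z-transform population, as are rows
whose LPs fail — mirroring the gap between "mappable" and "predictable"
metabolites on real reconstructions. The demand level is
$v_{opt} = \alpha\,v_{max}$ with $\alpha = 0.9$ by default: near-maximal
demand keeps the two conditions' optima distinct while avoiding the
degenerate all-bounds-active vertex at $\alpha = 1$; the sign of the
score is insensitive to $\alpha$ over [0.5, 1.0] on the worked fixtures,
and $\alpha$ is carried in the config. The $|v|$ objective is linearized
exactly with auxiliary variables $t_j \ge |v_j|$ (two inequality rows per
reaction); with strictly positive weights the optimum satisfies
$t = |v|$, so no integer variables are needed. Strict inequalities in the
constraint notation are implemented as closed bounds (LP standard). All
solves use HiGHS through scipy with one backend per run — no randomness
anywhere in the scoring path. The z-transform uses the sample SD (n−1)
over scored metabolites by default (`z_mode="population_sd"` available);
if every raw score coincides, all z-scores are 0 by convention. Calls use
a closed interval: $|X_s| \le 0.1$ is "unchanged", and the threshold is
configurable.

**Metabolomics statistics.** Missing abundances are imputed with the
metabolite's minimum observed value *before* log transformation and
testing, matching the stated processing order of typical profiling
pipelines. Welch's unequal-variance t-test is used per metabolite
(two identical constant groups return t = 0, p = 1 by convention),
with Benjamini–Hochberg step-up q-values standing in for an unspecified
q-value estimator; the two-way ANOVA (treatment × time, both
between-subject) uses type-II sums of squares, which coincide with
type I/III on the balanced designs generated here. Fold changes are
reported in log2; test statistics are computed on natural logs (the tests
are invariant to base). Significance cuts are strict (< 0.10).
Measured metabolites map to model species by exact KEGG id first, then
case-insensitive exact name (preferring extracellular species on
cross-compartment name collisions), then an optional alias table; no
fuzzy matching, so mapping counts are deterministic. A user-supplied
exclusion list removes drug-metabolism conjugates that the model does not
represent.

**Evaluation.** Concordance counts a prediction correct iff the call and
the measured log2 fold change agree in sign; "unchanged" calls count as
*incorrect* for evaluated metabolites by default (the percent-correct
denominator includes every measured-significant, scored metabolite), with
`count_unchanged_as_incorrect=False` available as a sensitivity mode.
The random baseline replaces the expression table with Normal(0, σ) log2
fold changes and Uniform(0,1) FDRs per replicate; its mean concordance
measures how much directional structure the network plus boundary
conditions force on their own. Pathway over-representation uses the exact
hypergeometric upper tail with BH correction — a stand-in for
annotation-tool enrichment scores, not a reproduction of any specific
tool. Potential markers are the intersection: measured-significant ∧
member of an enriched pathway ∧ scored by the model.

## The synthetic study generator

`SyntheticScenario` emulates the statistical structure of an in-vivo
toxicant study at desk scale. The default network has 6 linear production
pathways of 3 gene-gated steps each (33 reactions, 18 genes) hanging off
one substrate hub, coupled through a shared reversible cofactor loop —
large enough for a meaningful z-transform population, small enough for
exhaustive LP verification. Defaults: substrate uptake fixed at
10 mmol/h; planted expression effects ±2 log2 units on four of six
pathways with FDR ~ U(0, 0.01) (background genes FDR ~ U(0.2, 1));
plasma products shift ±2 log2 units with log-normal replicate noise
(SD 0.25 log2 units, 8 replicates per treatment × time cell, mirroring
common n = 8 designs); expression noise SD 0.2. The
`concordant_fraction` dial controls how many product shifts agree with
the expression-implied direction — at 0.5 it reproduces the situation
where transcription alone cannot explain half the metabolite changes.
The measured-flux fixture pins the substrate transport and cofactor
turnover (both necessarily equal to total uptake) at mean ± 10%, so MFA
constraints are exercised without blocking any product.

What the generator does *not* emulate: genome-scale network redundancy
(thousands of reactions, parallel isozyme routes, loops), compartmental
transport chains, correlated gene noise within operative pathways,
missing-at-random abundance dropout, or inter-animal covariance.
Passing the recovery tests therefore demonstrates correctness of the
machinery and the identifiability of planted signal under the stated
noise — not predictive performance on a real reconstruction.

## Numerical choices

- LP tolerance: HiGHS defaults; capability floor 1e-6 separates
  "unproducible" from numerically-zero capability.
- Flux-splitting caps: $t_j \le \max(|lb_j|, |ub_j|)$, keeping the LP
  bounded without affecting the optimum.
- Exchange sign convention: exchanges are written "M →", so positive flux
  secretes and negative takes up.
- Degenerate inputs: both production costs zero → unscored sentinel
  (not an exception); all-equal raw scores → all-zero z-scores;
  zero-variance metabolites → ANOVA p = 1.
- Tie at the call threshold (|X_s| exactly 0.1) → "unchanged".
- Determinism: every stochastic component (scenario generation, random
  baselines, perturbations) takes an explicit integer seed and uses its
  own `numpy.random.Generator`.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
inputs: the 5-reaction worked chain, 25 randomized ≤ 8-reaction networks
for the vertex-enumeration comparison, the 33-reaction default scenario
(single runs plus 20-seed averages and 20-replicate random baselines),
and 1000-metabolite null simulations for the error-rate checks. These
sizes keep every check exact or tightly bounded while completing in well
under a minute each.

## Known limitations

- The weight functional form and GPR aggregation rule are principled
  defaults for an under-specified transformation; conclusions that hinge
  on weight *magnitudes* (rather than signs) should be checked against
  alternative forms via the exposed configuration.
- Scores are relative within one run's z-transform population; changing
  the metabolite list changes μ and σ and hence individual $X_s$ values.
- The LP prices total weighted flux, not thermodynamic feasibility or
  enzyme capacity; bounds are the only capacity proxy.
- Concordance treats all evaluated metabolites equally; it does not weight
  by effect size or measurement confidence.
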