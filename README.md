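# metresponse

Predicts directional changes in plasma metabolite levels from liver gene
expression, using a constraint-based metabolic model as the bridge between
the two data types. The intended users are systems-biology and toxicology
groups who have a differential-expression contrast (e.g. toxicant vs.
control), a genome-scale metabolic reconstruction with gene–protein–reaction
(GPR) rules, and — ideally — plasma metabolomics to validate against.

## The method

For a metabolic network with stoichiometric matrix $S$, flux bounds
$v_{lb} \le v \le v_{ub}$ and per-reaction weights $W > 0$, the *production
cost* of a plasma metabolite is the weighted flux minimum

$$X_{met} = \min_v \sum_j W_j\,|v_j| \quad \text{s.t.}\quad S v = 0,\;
v_X \ge v_{opt},\; v_{lb} \le v \le v_{ub}$$

where $v_X$ is the metabolite's exchange (secretion) flux and
$v_{opt} = \alpha\, v_{max}$ is a near-maximal demand ($\alpha = 0.9$ by
default, $v_{max}$ the maximum feasible secretion). Gene expression enters
through the weights: each gene's log2 fold change is shrunk by its FDR
($r_g = \log_2\mathrm{FC} \cdot (1 - \mathrm{FDR})$), aggregated over the
reaction's GPR tree (AND = limiting subunit, OR = dominant isozyme), and
mapped to a weight pair $w_{control} = 2^{+r_j/2}$,
$w_{treatment} = 2^{-r_j/2}$, clipped to $[1/8, 8]$ — so an up-regulated
reaction is cheap to use under treatment and expensive under control.

Solving the LP once per condition gives the raw score

$$X_{raw} = \frac{X_{control} - X_{treatment}}{X_{control} + X_{treatment}}
\in [-1, 1],$$

positive when production became cheaper under treatment. Raw scores are
z-transformed across all scored metabolites
($X_s = (X_{raw} - \mu)/\sigma$) and classified: $X_s > 0.1$ predicted
increase, $X_s < -0.1$ predicted decrease, otherwise unchanged.

Physiology constrains the flux space before scoring: measured fasting
uptake rates fix both bounds of their exchange reactions, secretion rates
set lower bounds only, and metabolic-flux-analysis (MFA) measurements pin
mapped reactions to mean ± SD intervals. Predictions are evaluated by
*concordance*: the fraction of measured-significant metabolites
(FDR < 0.10, Welch's t-test on log abundances with minimum-value
imputation, Benjamini–Hochberg correction) whose predicted direction
matches the sign of the measured log2 fold change.

## Worked example

```python
from metresponse import SyntheticScenario, run_scenario

scenario = SyntheticScenario(seed=7, noise_sd_expr=0.0, noise_sd_abund=0.0)
result = run_scenario(scenario, time="10h")
print(result.scores.data[["metabolite_id", "X_raw", "X_s", "call"]])
print(result.fraction_correct)
```

prints

```
  metabolite_id     X_raw       X_s       call
0     prod_P1_e  0.236127  1.118814  increased
1     prod_P2_e  0.235618  1.116404  increased
2     prod_P3_e -0.236124 -1.116939  decreased
3     prod_P4_e -0.236765 -1.119975  decreased
4     prod_P5_e -0.000017  0.000848  unchanged
5     prod_P6_e -0.000017  0.000848  unchanged
1.0
```

The scenario plants +2 log2 units of expression on pathways P1/P2 and −2
on P3/P4 of a six-pathway liver-like toy network, with matching plasma
shifts. The scores recover every planted direction (the four significantly
altered products are all called correctly: concordance 1.0), while the
untouched pathways' products stay inside the ±0.1 "unchanged" band. The
`examples/` directory has one short script per capability — the
hand-checkable chain LP, the end-to-end synthetic study, the
random-expression baseline, constraint handling, the metabolomics
statistics and fixture-bundle export.

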