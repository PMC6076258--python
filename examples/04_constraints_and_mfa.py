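"""Boundary conditions, measured-flux bounds and the SSR acceptance region.

Fasting-state rules: uptake rates are enforced at both bounds of the
exchange reaction, secretion rates only as lower bounds, everything else
is closed to uptake.  Measured fluxes (mean +/- SD) narrow intracellular
reactions; a chi-square interval says which fitted SSR values are
acceptable; short-fast (5 h) fluxes are extrapolated from literature
fractions at 20% above the measured 10-h glucose output.
"""

from metresponse import (
    BoundaryConditions,
    MFAFluxSet,
    SyntheticScenario,
    apply_boundary_conditions,
    apply_mfa_constraints,
    chi2_ssr_acceptance,
    derive_5h_fluxes,
    generate_toy_network,
)

model = generate_toy_network(SyntheticScenario(seed=7))
bc = BoundaryConditions(uptake={"sub_e": 10.0}, units="mmol/h")
constrained = apply_boundary_conditions(model, bc)
ex = constrained.reaction("EX_sub_e")
print(f"substrate exchange bounds after constraining: [{ex.lb}, {ex.ub}]")
# Both bounds at -10: uptake is fixed exactly (negative flux = uptake).

mfa = MFAFluxSet(fluxes={"substrate_transport": (10.0, 1.0)}, units="absolute")
narrowed = apply_mfa_constraints(constrained, mfa, {"substrate_transport": "T_sub"})
t = narrowed.reaction("T_sub")
print(f"transport bounds after MFA constraint (10 +/- 1): [{t.lb}, {t.ub}]")

lower, upper = chi2_ssr_acceptance(dof=22, level=0.99)
print(f"99% SSR acceptance region, 22 dof: [{lower:.1f}, {upper:.1f}]")
# A goodness-of-fit SSR inside [8.6, 42.8] is consistent with the error model.

fluxes_5h = derive_5h_fluxes(
    {"glycogenolysis": 0.55, "gluconeogenesis": 0.45}, glucose_output_10h=100.0
)
for name, (mean, sd) in fluxes_5h.fluxes.items():
    print(f"5-h {name}: {mean:.1f} +/- {sd:.1f}")
# Glucose output at 5 h = 1.2 x the 10-h value, split by literature fractions.
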