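"""Production costs and directional scores on a hand-checkable chain.

A four-metabolite linear chain (uptake -> transport -> conversion ->
transport -> secretion) makes the weighted flux-minimization LP solvable
by hand: sustaining a demand of 9 forces |v| = 9 on all five reactions.
"""

import numpy as np

from metresponse import classify, production_cost, raw_score
from metresponse.model import MetabolicModel, Metabolite, Reaction
from metresponse.gpr import parse_gpr

chain = MetabolicModel(
    metabolites=[
        Metabolite("A_e", compartment="e"),
        Metabolite("A_c"),
        Metabolite("B_c"),
        Metabolite("B_e", compartment="e"),
    ],
    reactions=[
        Reaction("EX_A", {"A_e": -1.0}, lb=-10, ub=0, is_exchange=True),
        Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, lb=0, ub=1000),
        Reaction("R1", {"A_c": -1.0, "B_c": 1.0}, lb=0, ub=1000, gpr=parse_gpr("g1")),
        Reaction("T_B", {"B_c": -1.0, "B_e": 1.0}, lb=0, ub=1000),
        Reaction("EX_B", {"B_e": -1.0}, lb=0, ub=1000, is_exchange=True),
    ],
    genes=["g1"],
)

uniform = np.ones(5)
print("uniform-weight cost, demand 9:", production_cost(chain, uniform, "B_e", 9.0))
# 45.0 = 9 flux units on each of 5 unit-weight reactions.

# gene g1 up two-fold (r = 2): conversion costs 2 under control, 0.5 under
# treatment -- production becomes cheaper after treatment.
control, treatment = uniform.copy(), uniform.copy()
control[2], treatment[2] = 2.0, 0.5
x_c = production_cost(chain, control, "B_e", 9.0)
x_t = production_cost(chain, treatment, "B_e", 9.0)
print("control cost:", x_c, "| treatment cost:", x_t)  # 54.0 and 40.5
x_raw = raw_score(x_c, x_t)
print("raw score:", x_raw)  # 13.5/94.5 = 1/7: positive = predicted increase
print("call at threshold 0.1:", classify(x_raw, 0.1))
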