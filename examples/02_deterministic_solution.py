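"""Solve the deterministic (mean-geometry) muscle-force problem.

Builds the mid-support single-hand suspension state for both species and
resolves the ten element forces by stress-based optimization under moment
equilibrium, force bounds and the eight-direction glenoid stability
constraint. Forces print as a percentage of each element's maximum
(PCSA x specific tension).
"""

import cuffmc

for species_id in ("human", "chimpanzee"):
    sp = cuffmc.load_default(species_id)
    model = cuffmc.GlenohumeralModel(sp, "mid_support")
    sol = model.solve()
    print(f"\n{species_id} mid-support (full body weight on one hand)")
    print(f"  feasible: {sol.feasible}")
    print(f"  equilibrium residual: {sol.equilibrium_residual:.2e} N.m")
    print(f"  worst stability margin: {sol.stability_margins.min():.2e} N")
    for name, pct in sol.normalized_by_name().items():
        bar = "#" * int(pct / 2)
        print(f"  {name:22s} {pct:6.1f}% {bar}")
print(
    "\nA 0% element is predicted silent; a high percentage means the element"
    "\noperates near its maximum force capacity in this posture."
)
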