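"""One probabilistic analysis: perturb all 14 inputs, build the force CDF.

Runs a 300-iteration Monte Carlo of the human mid-support model (attachment
sites, glenoid inclination and stability ratios drawn from their Gaussian
distributions simultaneously) and prints the cumulative distribution of the
lower-infraspinatus force at the 11 study probability levels.
"""

import cuffmc

human = cuffmc.load_default("human")
model = cuffmc.GlenohumeralModel(human, "mid_support")
results, outputs, draws = cuffmc.run_monte_carlo(model, n=300, seed=42)

r = next(x for x in results if x.output_name == "infraspinatus_lower")
print("human mid-support, lower infraspinatus (% of maximum force)")
print(f"  iterations: {len(r.samples)} feasible, {r.n_infeasible} infeasible\n")
print("  level   force%")
for level, value in zip(r.cdf.levels, r.cdf.values):
    print(f"  {level:5.2f}   {value:6.2f}")
print("\n  percentile summary (1/25/50/75/99):")
print("  " + "  ".join(f"{p}%={v:.2f}" for p, v in r.cdf.percentiles.items()))
print(
    "\nThe spread shows how much anatomically plausible variation in the"
    "\nperturbed features moves this muscle's predicted effort."
)
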