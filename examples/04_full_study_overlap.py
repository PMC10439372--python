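"""The complete between-species study at a reduced iteration count.

Executes all 42 Monte Carlo analyses (7 cuff outputs x 3 support instances
x 2 species) at 150 iterations, assesses distribution overlap between the
species for every output, and writes figure/CSV reports. The full published
design uses 2500 iterations per analysis (see scripts/acceptance.py).
"""

from cuffmc import monte_carlo as mc
import cuffmc

cfg = mc.StudyConfig(n_iterations=150, seed=7)
suite = mc.run_analysis_suite(cfg)
print(f"{len(suite.results)} Monte Carlo analyses complete")

assessments = cuffmc.assess_suite(suite)
table = cuffmc.overlap_table(assessments)
cols = ["output", "instance", "human_p50", "chimp_p50", "functional_overlap"]
print(table[cols].round(2).to_string(index=False))
n = int(table.functional_overlap.sum())
print(
    f"\nfunctional overlap (human inner-50% band meets the chimpanzee range"
    f"\nand the human median is not above it) in {n} of {len(table)} pairs"
)

written = cuffmc.render_reports(suite, assessments, "scratch/example_study")
print("\nreports written:")
for name, path in written.items():
    print(f"  {path}")
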