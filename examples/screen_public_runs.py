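"""Screen a table of sequencing runs for viruses by reads-per-million.

Simulates 300 runs (50 projects x 3 samples x 2 runs) with infections
planted at 10% per (run, virus), converts counts to rpm, calls presence at
the 100 rpm detection limit, and summarises positivity at run, sample and
project level plus the threshold dependence.
"""

from flyvirome.screen import (
    positive_fraction,
    presence,
    rpm_matrix,
    threshold_curve,
    virus_dataset_counts,
)
from flyvirome.simulate import RunTableSpec, gen_run_table

spec = RunTableSpec(n_projects=50, samples_per_project=3, runs_per_sample=2,
                    infection_rate=0.1, seed=8)
table, truth = gen_run_table(spec)
rpm = rpm_matrix(table)
pres = presence(rpm, threshold=100.0)

print(f"{len(table)} runs screened against {len(rpm.columns)} viruses; "
      f"{len(truth['infected'])} (run, virus) infections planted")
for level in ("run", "sample", "project"):
    frac = positive_fraction(pres, table, level)
    print(f"  {level:>7}-level positivity at >=100 rpm: {frac:.1%}")
print("(positivity rises with grouping level: a project is positive "
      "if any member run is)")

counts = virus_dataset_counts(pres)
print("\npositive runs per virus:")
for virus, count in counts.items():
    print(f"  {virus:<14} {count}")

curve = threshold_curve(rpm, [10, 100, 1000])
print("\nrun positivity by detection threshold (monotone non-increasing):")
for threshold, frac in curve.items():
    print(f"  >={threshold:>5} rpm: {frac:.1%}")
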