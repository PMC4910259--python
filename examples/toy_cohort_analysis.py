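"""Full pipeline on a synthetic tumor cohort with one injected driver.

Builds a 2-Mb toy genome with 200 elements, injects a driver CDS in which
10 samples carry mostly hotspot (top-scoring) mutations, and runs the
FM-bias test.  The driver should rank first with a tiny q-value while the
neutral elements populate the rest of the table with uniform p-values.
"""

import numpy as np

import fmlbias as F

spec = F.SyntheticSpec(seed=7, driver_elements=("SYNG0005:cds",))
genome = F.generate_genome(spec)
catalog = F.build_toy_catalog(spec, genome)
store, hotspots = F.generate_scores(spec, genome, catalog)
cohort = F.generate_cohort(spec, genome, catalog, store, hotspots)
print(f"catalog: {len(catalog)} elements; cohort: {len(cohort)} SNVs "
      f"across {len(cohort.samples)} samples")

signature = F.compute_signature(cohort, genome, mode="cohort")
results = F.run_fml(
    catalog, cohort, store, signature,
    F.TestConfig(n_iterations=10_000, seed=7),
    genome=genome,
)

print(f"\ntested {len(results)} mutated elements; top 5 by p-value:")
print(f"{'element':<18}{'type':<10}{'k':>4}{'samples':>9}{'mean':>8}"
      f"{'p':>12}{'q':>12}")
for r in results[:5]:
    q = f"{r.q_value:.3g}" if r.q_value is not None else "-"
    print(f"{r.element_id:<18}{r.element_type:<10}{r.n_mutations:>4}"
          f"{r.n_samples:>9}{r.observed_mean:>8.2f}{r.p_value:>12.3g}{q:>12}")

n_hits = sum(1 for r in results if r.q_value is not None and r.q_value < 0.1)
print(f"\nelements at q < 0.1: {n_hits}")
print("The injected driver should appear at rank 1: its observed mean "
      "impact score sits far above the signature-weighted background of "
      "its own substitution space, so the empirical p-value escalates to "
      "the resolution ceiling.")
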