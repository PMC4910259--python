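"""Signature-preserving randomization as a false-positive control.

Repositions every mutation of a cohort within its 50-kb window onto a
position with the same (strand-collapsed) trinucleotide context, keeping
per-sample counts and the 96-channel spectrum exactly.  Re-running the test
on the randomized data estimates the method's false-positive behavior.
"""

import numpy as np

import fmlbias as F
from fmlbias.signature import count_channels

spec = F.SyntheticSpec(seed=3)
genome = F.generate_genome(spec)
catalog = F.build_toy_catalog(spec, genome)
store, hotspots = F.generate_scores(spec, genome, catalog)
cohort = F.generate_cohort(spec, genome, catalog, store, hotspots)

randomized, report = F.randomize_dataset(cohort, genome, window=50_000,
                                         rng=np.random.default_rng(3))
c0, _ = count_channels(cohort, genome)
c1, _ = count_channels(randomized, genome)

print(f"repositioned {report.n_repositioned}/{report.n_mutations} mutations "
      f"(kept {report.n_kept_original} without context match)")
print(f"max channel-count difference original vs randomized: "
      f"{int(abs(c0 - c1).max())}  (0 = spectrum conserved exactly)")

in_elements = sum(1 for m in randomized if catalog.lookup(m.chrom, m.pos))
print(f"randomized mutations still inside tested elements: "
      f"{in_elements}/{len(randomized)}")

signature = F.compute_signature(randomized, genome, mode="cohort")
results = F.run_fml(catalog, randomized, store, signature,
                    F.TestConfig(n_iterations=10_000, seed=3), genome=genome)
n_hits = sum(1 for r in results if r.q_value is not None and r.q_value < 0.1)
print(f"elements at q < 0.1 on randomized data: {n_hits}")
print("\nScattering mutations to context-matched positions destroys any "
      "enrichment at high-impact sites, so (almost) no element should stay "
      "significant; recurrent hits here would indicate a biased background.")
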