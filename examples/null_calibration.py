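"""Null calibration: p-values on a driver-free cohort should be uniform.

Draws every mutation of a synthetic cohort from the same signature-weighted
substitution space the test itself samples, so the resulting p-values must
be uniform on (0, 1] — the analog of the diagonal gray dots in a QQ plot of
a well-calibrated driver-detection method.
"""

from scipy import stats

import fmlbias as F

spec = F.SyntheticSpec(seed=1)  # no driver elements
genome = F.generate_genome(spec)
catalog = F.build_toy_catalog(spec, genome)
store, hotspots = F.generate_scores(spec, genome, catalog)
cohort = F.generate_cohort(spec, genome, catalog, store, hotspots)

signature = F.compute_signature(cohort, genome, mode="cohort")
results = F.run_fml(catalog, cohort, store, signature,
                    F.TestConfig(n_iterations=10_000, seed=1), genome=genome)

p_values = [r.p_value for r in results]
ks = stats.kstest(p_values, "uniform")
qq = F.qq_data(p_values)

print(f"tested {len(results)} elements on a null cohort of {len(cohort)} SNVs")
print(f"KS test vs U(0,1): statistic {ks.statistic:.4f}, p {ks.pvalue:.3f}")
print(f"elements at q < 0.1: "
      f"{sum(1 for r in results if r.q_value is not None and r.q_value < 0.1)}")
print("\nQQ data (head): expected vs observed -log10 p")
print(qq.tail(5).to_string(index=False))
print("\nA KS p-value well above 0.01 and QQ points hugging the diagonal "
      "mean the local background model is calibrated: no inflation from "
      "regional mutation-rate variation, no deflation from over-masking.")
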