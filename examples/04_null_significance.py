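"""Derive the enrichment a docking model must beat to be significant.

Testing hundreds of models means some will look enriched by chance.  The
empirical null distribution of normalized LogAUC under random ranking —
conditioned on the number of positives — combined with a Bonferroni
correction for the number of models tested gives the significance bar.
"""

from screenopt import SignificanceConfig, bonferroni, significance_threshold, simulate_null

n_pos, ratio = 20, 50.0
n_models_tested = 600
p_value = 0.01

corrected = bonferroni(p_value, n_models_tested)
null = simulate_null(n_pos=n_pos, ratio=ratio, reps=100_000, seed=0)
threshold = significance_threshold(
    null, SignificanceConfig(p_value=p_value, n_tests=n_models_tested)
)

print(f"null mean (should be ~0): {null.samples.mean():+.4f}")
print(f"corrected p: {p_value} / {n_models_tested} = {corrected:.2e}")
print(f"significance threshold: {threshold:.3f} normalized LogAUC")
print(f"null 99th percentile (single test): {null.samples[int(0.99 * len(null.samples))]:.3f}")
# A single model exceeding the threshold rejects the hypothesis that all
# observed enrichments came from a random classifier.  Fewer positives or
# more tested models push the bar higher.
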