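"""Calibration check: recovering the planted conditional log-OR.

Fixes one ~50,000-pair design, redraws the per-pair observation
Bernoullis 200 times, and reports bias, RMSE and 95%-CI coverage of the
Fisher log odds ratio against the planted log 2.
"""

import math

from sefx import GeneratorConfig, generate, recovery_report, replicate_enrichment

ds = generate(GeneratorConfig(seed=5, n_drugs=175))
print(f"design: {ds.truth['n_pairs']} pairs, "
      f"evidence prevalence {100 * ds.truth['evidence_prevalence']:.1f}%")

results = replicate_enrichment(ds, 200, seed=6)
rep = recovery_report(results, math.log(2.0))
print(f"replicates: {rep['n_replicates']}")
print(f"log-OR bias: {rep['bias']:+.4f}  (|bias| < 0.1 expected)")
print(f"log-OR RMSE: {rep['rmse']:.4f}")
print(f"95%-CI coverage: {100 * rep['coverage']:.1f}%  (nominal 95%)")
print(
    "\nthe Fisher conditional-MLE odds ratio is an essentially unbiased,"
    "\nwell-calibrated estimate of the planted conditional effect once the"
    "\nconfounded (indication-similar) pairs are filtered out."
)
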