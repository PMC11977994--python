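"""Threshold sensitivity sweeps and binned predictive values.

Shows how the odds ratio responds to the SE-trait similarity threshold
(the effect is planted at similarity >= 0.9 only) and how enrichment
varies by drug specificity and severity of the side effect.
"""

from sefx import (
    GeneratorConfig,
    generate,
    severity_bins,
    specificity_bins,
    sweep_assoc_threshold,
)
from sefx.filters import apply_filters, flag_evidence
from sefx.tables import build_universe

ds = generate(GeneratorConfig(seed=3))
uni = build_universe(ds.drugs, ds.se_records, ds.sim, ds.assocs)
flag_evidence(uni)

print("OR vs SE-trait similarity threshold (indication filter fixed at 0.9):")
sweep = sweep_assoc_threshold(uni, [0.3, 0.5, 0.75, 0.9, 0.95])
for row in sweep.itertuples(index=False):
    print(
        f"  theta >= {row.theta:.2f}: {row.n_evidence_pairs:>6} evidence pairs, "
        f"OR = {row.or_estimate:.2f}"
    )
print("the OR rises sharply near 0.9, where the effect is planted.\n")

retained, _ = apply_filters(uni)
print("enrichment by drug specificity (drugs reporting the SE):")
for b in specificity_bins(retained):
    orr = f"{b.enrichment.or_estimate:.2f}" if b.enrichment else "n/a"
    print(
        f"  {b.bin_label:>6}: base rate {100 * b.base_rate:5.1f}%, "
        f"PPV {100 * (b.ppv or 0):5.1f}%, OR {orr}"
    )

print("\nenrichment by severity quartile (Q4 most severe):")
for b in severity_bins(retained):
    print(
        f"  {b.bin_label:>10}: {b.n_pairs:>6} pairs, "
        f"base rate {100 * b.base_rate:5.1f}%"
    )
print(
    "\nseverity is planted to anti-correlate with specificity, so the most"
    "\nsevere quartile has the lowest base rate, as in labeled-SE data."
)
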