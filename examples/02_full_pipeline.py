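"""The full enrichment analysis on one synthetic study.

Generates the default-scale dataset (150 drugs, 300 ontology terms,
5.4% target base rate, planted conditional OR of 2), applies the
genetic-insight and similar-indication filters, and prints the primary
Fisher enrichment with predictive values.
"""

from sefx import (
    GeneratorConfig,
    generate,
    overall_base_rate,
    primary_enrichment,
)
from sefx.simulate import build_pipeline_universe, truth_eval

ds = generate(GeneratorConfig(seed=3))
print(
    f"universe: {len(ds.drugs)} drugs x {len(ds.se_vocab)} SE terms = "
    f"{ds.truth['n_pairs']} pairs, {ds.truth['n_observed']} observed"
)

retained, report = build_pipeline_universe(ds)
print(
    f"filters: {report.n_removed_insight} pairs lack genetic insight, "
    f"{report.n_removed_similar_indication} are similar to an indication "
    f"({report.n_retained} retained)"
)
print(f"base rate among retained pairs: {100 * overall_base_rate(retained):.1f}%")

r = primary_enrichment(retained)
print(
    f"\nprimary enrichment: OR = {r.or_estimate:.2f} "
    f"(95% CI {r.ci_low:.2f}-{r.ci_high:.2f}, P = {r.p:.2g}); "
    f"assoc/obs = {r.n_assoc_obs}/{r.n_assoc}"
)
print(f"PPV = {100 * r.ppv:.1f}%  (planted OR is 2: one observation draw)")

confusion = truth_eval(ds, retained)
print(
    f"evidence flags vs latent truth: {confusion['fp']} false positives, "
    f"{confusion['fn']} false negatives — the pipeline reconstructs the "
    "generator's evidence definition exactly."
)
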