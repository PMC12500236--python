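"""Matrisome composition of eluates (newsECM) vs inputs (bulk ECM).

Each protein carries a matrisome division/category annotation; the summary
reports per-category identified-protein counts and intensity proportions,
and the eluate/input proportion ratio that shows which ECM classes the
chemoselective enrichment favours.
"""

from newsecm import category_summary, decm_tumor_preset, generate_proteome_dataset

table, _ = generate_proteome_dataset(decm_tumor_preset(seed=1))
labeled = table.select_samples(model="decm_tumor", treatment="labeled")
summary = category_summary(labeled, treatment="labeled")

print("identified protein counts per category:")
print(summary.counts)
print("\nintensity proportions (share of all identified proteins):")
print(summary.proportions.round(4))
print("\neluate/input proportion ratios:")
print(summary.proportion_ratio.round(2))
print("\nRatios below 1 (collagens) mean the enrichment avoids the high-")
print("abundance structural background; ratios well above 1 (regulators,")
print("proteoglycans, secreted factors) mean better sensitivity for the")
print("low-abundance species that drive ECM remodeling.")
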