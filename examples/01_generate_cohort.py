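"""Generate a synthetic diagnostic-item cohort and inspect its structure.

The generator draws a latent severity per subject and item (standard normal,
shifted by delta for ASD subjects on informative items), discretizes it into
ordinal codes 0-3, then injects special codes 7/8 and missing entries.
"""

from itemreduce import generate_cohort, module_preset

spec = module_preset("children_m3_ados", n_subjects=500, seed=42)
table, truth = generate_cohort(spec)

print(f"cohort: {table.n_subjects} subjects x {table.n_items} ADOS items")
print(f"ASD prevalence: {table.labels.mean():.3f} (target {spec.prevalence})")
print(f"planted informative items (strongest first): {truth.informative_items}")
for item in truth.informative_items[:3]:
    print(f"  {item}: latent shift delta={truth.deltas[item]:.1f} "
          f"-> theoretical latent AUC {truth.latent_auc[item]:.3f}")

counts = table.codes["QSOV"].value_counts(dropna=False).sort_index()
print("\nobserved code distribution for QSOV (0-3 severity, 7/8 special, NA):")
print(counts.to_string())
# The latent AUC is the ceiling any classifier can reach on that item alone;
# discretization, special codes and missingness push observed AUC below it.
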