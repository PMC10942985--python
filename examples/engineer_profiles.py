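"""Build binary biomarker profiles from omics and clinical tables.

Shows the acquisition rules: SNV positivity (>= 1 variant in a driver gene,
wild-type otherwise), z-score binarization at {-2, 2}, clinical outcome
mappings, and the inclusion filters (min 10 positives; 20 for proteins;
10% ratio for transcriptomes).
"""

from histomark.profiles import (
    PROTEOME_THRESHOLDS,
    TRANSCRIPTOME_THRESHOLDS,
    apply_filter,
    clinical_outcome_profiles,
    expression_profiles,
    snv_profile,
)
from histomark.synthetic import (
    generate_clinical_table,
    generate_mutation_table,
    generate_zscore_table,
)

samples = [f"S{i:04d}" for i in range(120)]
muts = generate_mutation_table(120, {"TP53": 0.4, "KRAS": 0.15, "RB1": 0.05},
                               seed=1)
zs = generate_zscore_table(120, ["ESR1", "MYC"], {"ESR1": -1.0}, seed=2)
labels = {s: int(i % 3 == 0) for i, s in enumerate(samples)}
clin = generate_clinical_table(labels, ["residual_tumor", "msi_status"], seed=3)

profiles = (
    snv_profile(muts, ["TP53", "KRAS", "RB1"], samples)
    + expression_profiles(zs, TRANSCRIPTOME_THRESHOLDS, ["ESR1", "MYC"])
    + clinical_outcome_profiles(clin)
)

print(f"{'biomarker':28s} {'omic':22s} {'pos':>4s}/{'n':>4s}  decision")
for prof in profiles:
    keep, reason = apply_filter(prof)
    verdict = "keep" if keep else f"drop ({reason.split(': ')[1]})"
    print(f"{prof.biomarker_id:28s} {prof.omic_type.value:22s} "
          f"{prof.n_positive:4d}/{prof.n_total:4d}  {verdict}")
# Profiles failing their inclusion rule would be excluded from training;
# each kept profile is one classification target for the image model.
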