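"""Generate a synthetic cohort and write it to disk.

Builds a 20-patient cohort with a planted morphology effect, writes tiles,
manifest and the omics/clinical/purity tables, and prints what was made.
"""

from pathlib import Path

from histomark.synthetic import SyntheticCohortConfig, generate_cohort, write_cohort

cfg = SyntheticCohortConfig(
    n_patients=20, tiles_per_slide=8, tile_size=64,
    prevalence=0.4, effect_size=1.5, stain_jitter=0.5, seed=7,
)
cohort = generate_cohort(cfg)
out = write_cohort(cohort, Path("scratch/example_cohort"))

n_pos = sum(cohort.labels.values())
print(f"cohort: {cfg.n_patients} patients, {n_pos} biomarker-positive "
      f"(prevalence target {cfg.prevalence})")
print(f"slides: {len(cohort.slides)}, tiles/slide {cfg.tiles_per_slide}, "
      f"tile size {cfg.tile_size}px")
print(f"mutation records: {len(cohort.mutation_table)}")
print(f"written to {out}/ (manifest.tsv, tiles/, *.tsv, zscores.csv)")
# The positive class has nucleus density and hematoxylin intensity shifted by
# effect_size; at effect_size 0 the two classes are indistinguishable.
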