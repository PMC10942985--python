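"""Cross-validated training of the tile classifier on a planted signal.

A reduced-size run (24 patients, 3 epochs) of the full pipeline: Macenko
normalization, patient-stratified 3-fold cross-validation of the
autoencoder-classifier, tile -> slide -> patient aggregation, AUC summary,
significance, and a tile-score heatmap for one validation slide.
Takes a minute or two on one CPU.
"""

import numpy as np

from histomark.evaluation import biomarker_significance, render_heatmap
from histomark.model import ModelConfig, predict_tile_scores
from histomark.pipeline import run_cohort_pipeline
from histomark.synthetic import SyntheticCohortConfig, generate_cohort

cohort = generate_cohort(
    SyntheticCohortConfig(n_patients=24, tiles_per_slide=20, prevalence=0.4,
                          effect_size=1.5, stain_jitter=0.5, seed=2)
)
result, folds, trained = run_cohort_pipeline(
    cohort,
    ModelConfig(epochs=3, tiles_per_slide=50, seed=0),
    biomarker_id="planted_biomarker",
    seed=0,
)
(result,) = biomarker_significance([result], fdr=0.05)

print(f"fold AUCs: {[f'{a:.3f}' for a in result.fold_aucs]}")
print(f"mean AUC {result.mean_auc:.3f} +/- {result.std_auc:.3f} "
      f"(patient level, 3-fold)")
print(f"pooled-score t-test p={result.p_value:.2e}, q={result.q_value:.2e}, "
      f"significant={result.significant}")
for tm in trained:
    print(f"  fold {tm.fold}: best epoch {tm.selected_epoch}, "
          f"val AUC {tm.validation_auc:.3f}")

# Tile-score heatmap for one slide scored by the fold-0 model
slide = cohort.slides[0]
scores = predict_tile_scores(trained[0].model, slide.tiles)
grid = {(i // 5, i % 5): float(s) for i, s in enumerate(scores)}
heatmap, top = render_heatmap(grid, top_k=3)
print(f"heatmap over a 4x5 tile grid; top tiles by score: "
      f"{[(r, c, round(v, 2)) for r, c, v in top]}")
# Fold AUCs near 1 mean the planted morphology difference was recovered from
# tiles alone (at effect_size 0 they sit near 0.5).  With this demo's short
# 3-epoch budget the softmax scores stay compressed near 0.5, so the pooled
# cross-fold t-test can remain non-significant even at AUC 1.0; the full
# 10-epoch run (scripts/acceptance.py) separates the pooled scores and is
# significant after BH.
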