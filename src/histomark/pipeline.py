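"""End-to-end orchestration: cohort -> normalized tiles -> cross-validated AUC.

Mirrors the preprocessing-and-training protocol: one Macenko normalizer is
fitted on a designated cohort-level reference image, applied to every tile,
and the normalized slides enter patient-level stratified 3-fold
cross-validation of the autoencoder-classifier.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .model import LabeledSlide, ModelConfig
from .synthetic import SyntheticCohort
from .tiling import StainNormalizer, fit_normalizer, normalize_tile
from .evaluation import EvaluationResult, FoldAssignment, cross_validate_biomarker

__all__ = ["fit_cohort_normalizer", "prepare_slides", "run_cohort_pipeline"]


def fit_cohort_normalizer(
    cohort: SyntheticCohort, n_reference_tiles: int = 12
) -> StainNormalizer:
    """Fit one normalizer for the whole cohort on a fixed reference image.

    The reference is the first ``n_reference_tiles`` tiles of the cohort's
    first slide stacked into one image — a deterministic choice, equivalent
    to designating a reference slide in a config file.
    """
    first = cohort.slides[0]
    n = min(n_reference_tiles, len(first.tiles))
    reference = np.concatenate([first.tiles[i] for i in range(n)], axis=0)
    return fit_normalizer(reference)


def prepare_slides(
    cohort: SyntheticCohort, normalizer: StainNormalizer | None = None
) -> list[LabeledSlide]:
    """Stain-normalize every tile and attach the slide-level labels."""
    out = []
    for s in cohort.slides:
        if normalizer is not None:
            tiles = np.stack(
                [normalize_tile(t, normalizer)[0] for t in s.tiles]
            )
        else:
            tiles = s.tiles
        out.append(
            LabeledSlide(s.slide_id, s.patient_id, tiles,
                         cohort.labels[s.patient_id])
        )
    return out


def run_cohort_pipeline(
    cohort: SyntheticCohort,
    model_config: ModelConfig | None = None,
    biomarker_id: str = "biomarker",
    seed: int = 0,
    normalize: bool = True,
) -> tuple[EvaluationResult, FoldAssignment | None, list]:
    """Full pipeline on an in-memory cohort; see cross_validate_biomarker."""
    normalizer = fit_cohort_normalizer(cohort) if normalize else None
    slides = prepare_slides(cohort, normalizer)
    return cross_validate_biomarker(
        slides, cohort.labels, biomarker_id, model_config, seed=seed
    )
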