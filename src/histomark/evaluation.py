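"""Patient-level cross-validation, AUC statistics and significance testing.

The evaluation protocol: patients with a valid biomarker status are split
into three stratified folds at the patient level (all slides of a patient
share a fold; per-fold positive counts differ by at most one from exact
stratification).  Each fold's held-out predictions are aggregated
hierarchically — tile scores average to a slide score, slide scores average
to a patient score — and performance is the AUC over held-out patients,
reported as mean +/- sample standard deviation across the three folds.

Two significance procedures are provided.  At the group level, a collection
of AUCs is compared against a same-size normal sample with mean 0.5 and the
group's standard deviation (two-sided t-test).  At the biomarker level, the
pooled held-out patient scores of the positive and negative classes are
compared with a two-sided t-test, and p-values are corrected across the
batch with Benjamini–Hochberg at FDR 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FoldAssignment",
    "PredictionSet",
    "EvaluationResult",
    "make_folds",
    "aggregate",
    "compute_auc",
    "summarize",
    "group_significance",
    "biomarker_significance",
    "correlate",
    "render_heatmap",
    "cross_validate_biomarker",
]

MIN_POSITIVE_PATIENTS = 10


@dataclass
class FoldAssignment:
    """Patient -> fold partition for one biomarker."""

    biomarker_id: str
    fold_of: dict[str, int]
    k: int = 3

    def patients_in(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.fold_of.items() if f == fold)

    def assignment_hash(self) -> int:
        """Order-independent hash for fold-identity checks across experiments."""
        return hash(tuple(sorted(self.fold_of.items())))


@dataclass
class PredictionSet:
    """Held-out predictions of one fold at tile, slide and patient level."""

    tile_scores: dict[tuple[str, int], float]
    slide_scores: dict[str, float]
    patient_scores: dict[str, float]
    fold: int = 0


@dataclass
class EvaluationResult:
    """Cross-validated performance and significance of one biomarker."""

    biomarker_id: str
    fold_aucs: list[float]
    mean_auc: float
    std_auc: float
    pooled_scores: dict[str, tuple[float, int]]  # patient -> (score, label)
    p_value: float = float("nan")
    q_value: float = float("nan")
    significant: bool = False
    skipped: bool = False
    skip_reason: str = ""


def make_folds(
    labels: Mapping[str, int], k: int = 3, seed: int = 0,
    biomarker_id: str = "biomarker",
) -> FoldAssignment | None:
    """Stratified patient-level partition into k folds.

    Positives and negatives are shuffled separately and dealt round-robin, so
    per-fold class counts are within one patient of exact stratification.
    Returns None (a discard signal, not an error) when fewer than ten
    positive patients exist.
    """
    n_pos = sum(labels.values())
    if n_pos < MIN_POSITIVE_PATIENTS:
        return None
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF01D)))
    fold_of: dict[str, int] = {}
    for cls in (1, 0):
        members = sorted(p for p, v in labels.items() if v == cls)
        rng.shuffle(members)
        for i, p in enumerate(members):
            fold_of[p] = i % k
    return FoldAssignment(biomarker_id, fold_of, k)


def aggregate(
    tile_scores: Mapping[tuple[str, int], float],
    slide_to_patient: Mapping[str, str],
    fold: int = 0,
) -> PredictionSet:
    """Hierarchical means: tiles -> slide, slides -> patient."""
    by_slide: dict[str, list[float]] = {}
    for (slide, _), v in tile_scores.items():
        by_slide.setdefault(slide, []).append(v)
    for slide in slide_to_patient:
        if slide not in by_slide:
            raise ValueError(f"slide {slide} has no scored tiles")
    slide_scores = {s: float(np.mean(v)) for s, v in by_slide.items()}
    by_patient: dict[str, list[float]] = {}
    for s, v in slide_scores.items():
        by_patient.setdefault(slide_to_patient[s], []).append(v)
    patient_scores = {p: float(np.mean(v)) for p, v in by_patient.items()}
    return PredictionSet(dict(tile_scores), slide_scores, patient_scores, fold)


def compute_auc(scores: Mapping[str, float], labels: Mapping[str, int]) -> float:
    """ROC AUC via the rank (Mann–Whitney) statistic; ties credited 0.5."""
    keys = sorted(scores)
    if set(keys) != set(labels):
        keys = sorted(set(scores) & set(labels))
    y = np.array([labels[k] for k in keys])
    s = np.array([scores[k] for k in keys], dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def summarize(
    biomarker_id: str,
    fold_predictions: Sequence[PredictionSet],
    labels: Mapping[str, int],
) -> EvaluationResult:
    """Per-fold patient-level AUCs, their mean and sample std, pooled scores."""
    fold_aucs = []
    pooled: dict[str, tuple[float, int]] = {}
    for ps in fold_predictions:
        fold_labels = {p: labels[p] for p in ps.patient_scores}
        fold_aucs.append(compute_auc(ps.patient_scores, fold_labels))
        for p, sc in ps.patient_scores.items():
            pooled[p] = (sc, labels[p])
    arr = np.array(fold_aucs)
    return EvaluationResult(
        biomarker_id=biomarker_id,
        fold_aucs=[float(a) for a in fold_aucs],
        mean_auc=float(arr.mean()),
        std_auc=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        pooled_scores=pooled,
    )


def group_significance(group_aucs: Sequence[float], seed: int = 0) -> float:
    """Two-sided t-test of a group of AUCs against simulated random models.

    The null sample has the same size as the group, mean 0.5 and the group's
    standard deviation.  Degenerate (zero-spread) groups return p = 1.
    """
    aucs = np.asarray(group_aucs, dtype=float)
    if len(aucs) < 2:
        raise ValueError("need at least 2 AUC values")
    sd = aucs.std(ddof=1)
    if sd <= 0:
        warnings.warn("degenerate AUC group (zero std); p set to 1")
        return 1.0
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x6A0B)))
    null = rng.normal(0.5, sd, size=len(aucs))
    return float(stats.ttest_ind(aucs, null).pvalue)


def biomarker_significance(
    results: Sequence[EvaluationResult], fdr: float = 0.05
) -> list[EvaluationResult]:
    """Per-biomarker t-test on pooled scores plus BH correction across the batch.

    For each biomarker the pooled held-out patient scores of positives and
    negatives are compared with a two-sided t-test; biomarkers whose pooled
    set is single-class are excluded from the BH family with a warning.
    Significance means adjusted p < 0.05.
    """
    testable: list[EvaluationResult] = []
    for r in results:
        if r.skipped:
            continue
        scores = np.array([s for s, _ in r.pooled_scores.values()])
        labs = np.array([l for _, l in r.pooled_scores.values()])
        if len(np.unique(labs)) < 2:
            warnings.warn(
                f"{r.biomarker_id}: pooled scores single-class; excluded from BH"
            )
            r.p_value = float("nan")
            continue
        r.p_value = float(
            stats.ttest_ind(scores[labs == 1], scores[labs == 0]).pvalue
        )
        testable.append(r)
    if testable:
        pvals = np.array([r.p_value for r in testable])
        reject, qvals, *_ = multipletests(pvals, alpha=fdr, method="fdr_bh")
        for r, q, rej in zip(testable, qvals, reject):
            r.q_value = float(q)
            r.significant = bool(rej) and r.q_value < 0.05
    return list(results)


def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation coefficient with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def render_heatmap(
    tile_scores: Mapping[tuple[int, int], float],
    top_k: int = 5,
    cmap: str = "inferno",
) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """Spatial score heatmap at tile resolution plus the top-k tile list.

    ``tile_scores`` maps (row, col) grid coordinates to scores in [0, 1].
    Returns an RGB uint8 heatmap (positions without a scored tile are white)
    and the top-k tiles sorted by descending score, ties broken by (row, col).
    """
    if not tile_scores:
        raise ValueError("empty tile score set")
    import matplotlib

    rows = [r for r, _ in tile_scores]
    cols = [c for _, c in tile_scores]
    h, w = max(rows) + 1, max(cols) + 1
    img = np.full((h, w, 3), 255, dtype=np.uint8)
    mapper = matplotlib.colormaps[cmap]
    for (r, c), v in tile_scores.items():
        rgba = mapper(float(np.clip(v, 0, 1)))
        img[r, c] = np.rint(np.array(rgba[:3]) * 255)
    ranked = sorted(tile_scores.items(), key=lambda kv: (-kv[1], kv[0]))
    top = [(r, c, float(v)) for (r, c), v in ranked[:top_k]]
    return img, top


# --------------------------------------------------------------------------
# End-to-end orchestration
# --------------------------------------------------------------------------

def cross_validate_biomarker(
    slides: Sequence,
    labels: Mapping[str, int],
    biomarker_id: str = "biomarker",
    model_config=None,
    k: int = 3,
    seed: int = 0,
) -> tuple[EvaluationResult, FoldAssignment | None, list]:
    """Full pipeline for one biomarker: folds, per-fold training, aggregation.

    ``slides`` are :class:`histomark.model.LabeledSlide` objects (or anything
    with slide_id/patient_id/tiles/label).  Returns the evaluation result
    (without BH correction — apply :func:`biomarker_significance` across the
    batch), the fold assignment, and the trained fold models.
    """
    from .model import AutoencoderClassifier, LabeledSlide, ModelConfig, \
        predict_tile_scores, train_fold

    model_config = model_config or ModelConfig(seed=seed)
    folds = make_folds(labels, k=k, seed=seed, biomarker_id=biomarker_id)
    if folds is None:
        res = EvaluationResult(
            biomarker_id, [], float("nan"), float("nan"), {},
            skipped=True,
            skip_reason="fewer than ten positive patients",
        )
        return res, None, []

    by_patient: dict[str, list] = {}
    for s in slides:
        by_patient.setdefault(s.patient_id, []).append(s)
    missing = set(by_patient) - set(labels)
    if missing:
        raise ValueError(f"slides for unlabeled patients: {sorted(missing)}")

    predictions: list[PredictionSet] = []
    trained = []
    for fold in range(k):
        val_p = set(folds.patients_in(fold))
        train_slides = [
            LabeledSlide(s.slide_id, s.patient_id, s.tiles, labels[s.patient_id])
            for p, ss in by_patient.items() if p not in val_p for s in ss
        ]
        val_slides = [
            LabeledSlide(s.slide_id, s.patient_id, s.tiles, labels[s.patient_id])
            for p, ss in by_patient.items() if p in val_p for s in ss
        ]
        cfg = ModelConfig(**{
            **{f: getattr(model_config, f)
               for f in model_config.__dataclass_fields__},
            "seed": int(np.random.SeedSequence((seed, fold)).generate_state(1)[0]
                        % (2**31)),
        })
        net = AutoencoderClassifier(cfg)
        tm = train_fold(net, train_slides, val_slides, cfg, fold=fold)
        trained.append(tm)

        tile_scores: dict[tuple[str, int], float] = {}
        slide_to_patient = {}
        for s in val_slides:
            scores = predict_tile_scores(tm.model, s.tiles)
            for i, sc in enumerate(scores):
                tile_scores[(s.slide_id, i)] = float(sc)
            slide_to_patient[s.slide_id] = s.patient_id
        predictions.append(aggregate(tile_scores, slide_to_patient, fold))

    result = summarize(biomarker_id, predictions, labels)
    return result, folds, trained


def results_table(results: Sequence[EvaluationResult]) -> pd.DataFrame:
    """Summary CSV-ready table across biomarkers."""
    rows = []
    for r in results:
        rows.append(
            dict(
                biomarker_id=r.biomarker_id,
                mean_auc=r.mean_auc,
                std_auc=r.std_auc,
                p_value=r.p_value,
                q_value=r.q_value,
                significant=r.significant,
                skipped=r.skipped,
            )
        )
    return pd.DataFrame(rows)
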