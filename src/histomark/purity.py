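"""Tumor-purity baseline: can percent-tumor-cells alone predict the biomarker?

For every biomarker a one-to-one control experiment is run: the same fold
assignment used by the image model trains three single-feature random-forest
classifiers on per-case tumor purity (the mean of the biospecimen table's
``percent_tumor_cells`` over a patient's slides).  The image-model and
purity-model AUC collections are compared per omic subgroup with a two-sided
t-test, and mean per-biomarker purity is correlated with image-model AUC
(Pearson) per subgroup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .evaluation import FoldAssignment, compute_auc, correlate
from .profiles import BiomarkerProfile

__all__ = [
    "PurityRecord",
    "PurityComparison",
    "purity_from_biospecimen",
    "train_purity_classifier",
    "compare_dl_vs_purity",
    "purity_auc_correlation",
]


@dataclass(frozen=True)
class PurityRecord:
    """Per-patient tumor purity in percent (mean over available slides)."""

    patient_id: str
    purity: float


def purity_from_biospecimen(records: pd.DataFrame) -> list[PurityRecord]:
    """Average percent_tumor_cells per patient; patients lacking it are dropped.

    ``records`` needs patient_id, slide_id and percent_tumor_cells columns.
    Values outside [0, 100] are an input error.
    """
    required = {"patient_id", "slide_id", "percent_tumor_cells"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"biospecimen table missing columns: {sorted(missing)}")
    valid = records.dropna(subset=["percent_tumor_cells"])
    vals = valid["percent_tumor_cells"].astype(float)
    if ((vals < 0) | (vals > 100)).any():
        raise ValueError("percent_tumor_cells outside [0, 100]")
    means = valid.groupby("patient_id")["percent_tumor_cells"].mean()
    return [PurityRecord(p, float(v)) for p, v in means.items()]


def train_purity_classifier(
    purity: Sequence[PurityRecord],
    profile: BiomarkerProfile,
    folds: FoldAssignment,
    seed: int = 0,
    n_estimators: int = 100,
) -> list[float]:
    """Per-fold held-out AUCs of single-feature random forests on purity.

    The fold assignment must be the one used by the image model for the same
    biomarker (checked only for coverage here; identity is the caller's
    invariant, verifiable via ``folds.assignment_hash()``).  Folds whose
    held-out patients are single-class are skipped with a warning.
    """
    purity_of = {r.patient_id: r.purity for r in purity}
    usable = [p for p in folds.fold_of if p in purity_of and p in profile.labels]
    aucs: list[float] = []
    for fold in range(folds.k):
        test_p = [p for p in usable if folds.fold_of[p] == fold]
        train_p = [p for p in usable if folds.fold_of[p] != fold]
        y_test = [profile.labels[p] for p in test_p]
        y_train = [profile.labels[p] for p in train_p]
        if len(set(y_test)) < 2 or len(set(y_train)) < 2:
            warnings.warn(f"fold {fold}: single-class; skipped")
            continue
        rf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed
        )
        rf.fit(np.array([[purity_of[p]] for p in train_p]), y_train)
        prob = rf.predict_proba(np.array([[purity_of[p]] for p in test_p]))[:, 1]
        scores = dict(zip(test_p, prob.astype(float)))
        labels = dict(zip(test_p, y_test))
        aucs.append(compute_auc(scores, labels))
    return aucs


def compare_dl_vs_purity(
    dl_aucs: Mapping[str, Sequence[float]],
    rf_aucs: Mapping[str, Sequence[float]],
    subgroups: Mapping[str, str],
) -> dict[str, float]:
    """Two-sided t-test of image-model vs purity-model AUCs per omic subgroup.

    ``dl_aucs`` and ``rf_aucs`` map biomarker_id to its per-fold AUCs; the
    biomarker sets must match.  Subgroups with fewer than two biomarkers are
    skipped.
    """
    if set(dl_aucs) != set(rf_aucs):
        raise ValueError("DL and RF biomarker sets differ")
    out: dict[str, float] = {}
    for sub in sorted(set(subgroups.values())):
        ids = [b for b in dl_aucs if subgroups.get(b) == sub]
        if len(ids) < 2:
            warnings.warn(f"subgroup {sub!r} has <2 biomarkers; skipped")
            continue
        a = np.concatenate([np.asarray(dl_aucs[b], dtype=float) for b in ids])
        b = np.concatenate([np.asarray(rf_aucs[i], dtype=float) for i in ids])
        out[sub] = float(stats.ttest_ind(a, b).pvalue)
    return out


def purity_auc_correlation(
    mean_purity: Mapping[str, float],
    dl_auc: Mapping[str, float],
    subgroups: Mapping[str, str],
) -> dict[str, tuple[float, float]]:
    """Pearson correlation of mean per-biomarker purity with image-model AUC,
    one (r, p) pair per omic subgroup with at least 3 biomarkers."""
    out: dict[str, tuple[float, float]] = {}
    for sub in sorted(set(subgroups.values())):
        ids = [b for b in mean_purity
               if subgroups.get(b) == sub and b in dl_auc]
        if len(ids) < 3:
            warnings.warn(f"subgroup {sub!r} has <3 biomarkers; skipped")
            continue
        out[sub] = correlate([mean_purity[b] for b in ids],
                             [dl_auc[b] for b in ids])
    return out
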