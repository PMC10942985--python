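"""Binary biomarker profile construction from omics and clinical tables.

A *profile* is a per-patient binary label vector for one biomarker.  The rules
implemented here are the standard acquisition conventions for TCGA/CPTAC-style
inputs:

* SNV profiles: a sequenced sample is positive for a driver gene if it carries
  at least one single-nucleotide variant in that gene; sequenced samples with
  no record are wild-type (negative).
* Expression profiles: z-scores binarized at symmetric thresholds — under if
  z <= t_under, over if z >= t_over (boundaries inclusive); one under- and one
  over-expression profile per gene.  Transcriptomic thresholds are {-2, 2},
  proteomic {-1.5, 1.5}.
* Clinical outcome mappings: residual tumor R1/R2 positive vs R0 negative
  (margin_status as fallback), complete remission/response positive vs stable
  disease / partial response / progressive disease negative, MSI-H positive vs
  MSS/MSI-L negative.
* Categorical features are one-hot encoded into one profile per category;
  continuous features are binarized at the mean of non-missing values.

Patients with missing source values are excluded from the affected profile,
never imputed.  Inclusion filters discard sparse profiles: minimum ten
positive patients in general, twenty for proteomic profiles, and for
transcriptomic profiles additionally a positive ratio of at least 10%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OmicType",
    "ZScoreThresholds",
    "TRANSCRIPTOME_THRESHOLDS",
    "PROTEOME_THRESHOLDS",
    "BiomarkerProfile",
    "FilterRule",
    "DEFAULT_FILTER_RULES",
    "snv_profile",
    "expression_profiles",
    "apply_filter",
    "one_hot_profiles",
    "mean_binarize",
    "clinical_outcome_profiles",
    "msi_profile",
    "read_driver_genes",
    "write_profile_tables",
]


class OmicType(str, Enum):
    SNV = "snv"
    TRANSCRIPTOME_UNDER = "transcriptome_under"
    TRANSCRIPTOME_OVER = "transcriptome_over"
    PROTEIN_UNDER = "protein_under"
    PROTEIN_OVER = "protein_over"
    STANDARD_CLINICAL = "standard_clinical"
    SUBTYPE_SIGNATURE = "subtype_signature"
    OUTCOME_RESPONSE = "outcome_response"


@dataclass(frozen=True)
class ZScoreThresholds:
    """Symmetric under/over expression cutoffs in z-score units."""

    t_under: float
    t_over: float

    def __post_init__(self) -> None:
        if not self.t_under < self.t_over:
            raise ValueError("t_under must be < t_over")


TRANSCRIPTOME_THRESHOLDS = ZScoreThresholds(-2.0, 2.0)
PROTEOME_THRESHOLDS = ZScoreThresholds(-1.5, 1.5)


@dataclass
class BiomarkerProfile:
    """Per-patient binary labels for one biomarker."""

    biomarker_id: str
    omic_type: OmicType
    labels: dict[str, int]

    @property
    def n_total(self) -> int:
        return len(self.labels)

    @property
    def n_positive(self) -> int:
        return sum(self.labels.values())

    @property
    def positive_ratio(self) -> float:
        return self.n_positive / self.n_total if self.n_total else 0.0


@dataclass(frozen=True)
class FilterRule:
    """Minimum positive count (and optional positive-ratio) for inclusion."""

    min_positive: int = 10
    min_positive_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.min_positive < 0:
            raise ValueError("min_positive must be >= 0")
        if self.min_positive_ratio is not None and not (
            0.0 <= self.min_positive_ratio <= 1.0
        ):
            raise ValueError("min_positive_ratio must be in [0, 1]")


#: Default inclusion rules keyed by omic type.  Proteomic profiles need 20
#: positives; transcriptomic ones need 10 positives and a 10% positive ratio;
#: everything else needs 10 positives.
DEFAULT_FILTER_RULES: dict[OmicType, FilterRule] = {
    OmicType.SNV: FilterRule(10),
    OmicType.TRANSCRIPTOME_UNDER: FilterRule(10, 0.10),
    OmicType.TRANSCRIPTOME_OVER: FilterRule(10, 0.10),
    OmicType.PROTEIN_UNDER: FilterRule(20),
    OmicType.PROTEIN_OVER: FilterRule(20),
    OmicType.STANDARD_CLINICAL: FilterRule(10),
    OmicType.SUBTYPE_SIGNATURE: FilterRule(10),
    OmicType.OUTCOME_RESPONSE: FilterRule(10),
}


def snv_profile(
    mutations: pd.DataFrame,
    driver_genes: Sequence[str],
    sequenced_samples: Sequence[str],
) -> list[BiomarkerProfile]:
    """One SNV profile per driver gene over the sequenced-sample universe.

    ``sequenced_samples`` defines which samples may be assumed wild-type when
    unlisted; callers must pre-exclude samples without WGS/WXS data.
    """
    if len(driver_genes) == 0:
        raise ValueError("driver gene list is empty")
    universe = list(dict.fromkeys(sequenced_samples))
    uni_set = set(universe)
    mut = mutations[mutations["Tumor_Sample_Barcode"].isin(uni_set)]
    profiles = []
    for gene in driver_genes:
        hit = set(mut.loc[mut["Hugo_Symbol"] == gene, "Tumor_Sample_Barcode"])
        labels = {s: int(s in hit) for s in universe}
        profiles.append(BiomarkerProfile(f"{gene}_snv", OmicType.SNV, labels))
    return profiles


def expression_profiles(
    zscores: pd.DataFrame,
    thresholds: ZScoreThresholds,
    driver_genes: Sequence[str],
    omic: str = "transcriptome",
) -> list[BiomarkerProfile]:
    """Under- and over-expression profiles per driver gene (boundary inclusive).

    ``zscores`` is genes x samples.  Genes absent from the matrix are skipped
    with a warning; samples with a missing z-score are excluded from that
    gene's profiles.
    """
    if omic not in ("transcriptome", "protein"):
        raise ValueError("omic must be 'transcriptome' or 'protein'")
    under_t = OmicType[f"{omic.upper()}_UNDER"]
    over_t = OmicType[f"{omic.upper()}_OVER"]
    profiles = []
    for gene in driver_genes:
        if gene not in zscores.index:
            warnings.warn(f"gene {gene!r} absent from z-score matrix; skipped")
            continue
        row = zscores.loc[gene]
        valid = row[row.notna()]
        under = {s: int(v <= thresholds.t_under) for s, v in valid.items()}
        over = {s: int(v >= thresholds.t_over) for s, v in valid.items()}
        profiles.append(BiomarkerProfile(f"{gene}_under", under_t, under))
        profiles.append(BiomarkerProfile(f"{gene}_over", over_t, over))
    return profiles


def apply_filter(
    profile: BiomarkerProfile, rule: FilterRule | None = None
) -> tuple[bool, str]:
    """Keep/drop decision for a profile; returns (keep, reason)."""
    if rule is None:
        rule = DEFAULT_FILTER_RULES[profile.omic_type]
    if profile.n_positive < rule.min_positive:
        return False, (
            f"{profile.biomarker_id}: {profile.n_positive} positives "
            f"< minimum {rule.min_positive}"
        )
    if (
        rule.min_positive_ratio is not None
        and profile.positive_ratio < rule.min_positive_ratio
    ):
        return False, (
            f"{profile.biomarker_id}: positive ratio "
            f"{profile.positive_ratio:.3f} < {rule.min_positive_ratio:.2f}"
        )
    return True, "kept"


def one_hot_profiles(
    categorical: Mapping[str, str],
    biomarker_prefix: str = "category",
    omic_type: OmicType = OmicType.SUBTYPE_SIGNATURE,
) -> list[BiomarkerProfile]:
    """One profile per category; each patient positive in exactly one."""
    values = {p: v for p, v in categorical.items() if not _is_missing(v)}
    cats = sorted(set(values.values()))
    if len(cats) < 2:
        raise ValueError("one-hot encoding needs at least 2 categories")
    return [
        BiomarkerProfile(
            f"{biomarker_prefix}_{c}",
            omic_type,
            {p: int(v == c) for p, v in values.items()},
        )
        for c in cats
    ]


def mean_binarize(
    values: Mapping[str, float],
    biomarker_id: str = "continuous",
    omic_type: OmicType = OmicType.SUBTYPE_SIGNATURE,
) -> BiomarkerProfile:
    """Binarize a continuous feature at the mean of its non-missing values.

    A value exactly at the mean is negative (strict >).
    """
    valid = {p: float(v) for p, v in values.items() if not _is_missing(v)}
    if len(valid) < 2:
        raise ValueError("need at least 2 non-missing values")
    mu = float(np.mean(list(valid.values())))
    return BiomarkerProfile(
        biomarker_id, omic_type, {p: int(v > mu) for p, v in valid.items()}
    )


def _is_missing(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and np.isnan(v):
        return True
    return False


# Clinical category -> label mappings (inverse of the synthetic generator's).
_CLINICAL_MAPS: dict[str, dict[str, int]] = {
    "residual_tumor": {"R0": 0, "R1": 1, "R2": 1},
    "margin_status": {"Negative": 0, "Positive": 1},
    "treatment_outcome_first_course": {
        "Complete Remission/Response": 1,
        "Stable Disease": 0,
        "Partial Response": 0,
        "Progressive Disease": 0,
    },
    "treatment_best_response": {
        "Complete Response": 1,
        "Stable Disease": 0,
        "Partial Response": 0,
        "Progressive Disease": 0,
    },
}


def clinical_outcome_profiles(clinical: pd.DataFrame) -> list[BiomarkerProfile]:
    """Profiles from clinical outcome and treatment-response columns.

    Recognized columns: residual_tumor (margin_status as fallback when absent),
    treatment_outcome_first_course, treatment_best_response, and any of
    os/dss/dfi/pfi supplied as already-binary 0/1 columns.  Unknown category
    strings are excluded with a warning; missing values are excluded silently.
    """
    if "patient_id" not in clinical.columns:
        raise ValueError("clinical table needs a patient_id column")
    cols = [c for c in clinical.columns if c != "patient_id"]
    profiles: list[BiomarkerProfile] = []
    recognized = False

    mapped_cols = [c for c in cols if c in _CLINICAL_MAPS]
    if "residual_tumor" in mapped_cols and "margin_status" in mapped_cols:
        mapped_cols.remove("margin_status")  # fallback only
    for col in mapped_cols:
        recognized = True
        mapping = _CLINICAL_MAPS[col]
        labels: dict[str, int] = {}
        for p, v in zip(clinical["patient_id"], clinical[col]):
            if _is_missing(v):
                continue
            if v not in mapping:
                warnings.warn(f"unrecognized {col} value {v!r}; patient excluded")
                continue
            labels[p] = mapping[v]
        profiles.append(
            BiomarkerProfile(col, OmicType.OUTCOME_RESPONSE, labels)
        )

    for col in cols:
        if col.lower() in ("os", "dss", "dfi", "pfi"):
            recognized = True
            labels = {
                p: int(v)
                for p, v in zip(clinical["patient_id"], clinical[col])
                if not _is_missing(v)
            }
            if any(v not in (0, 1) for v in labels.values()):
                raise ValueError(f"survival endpoint {col} must be binary 0/1")
            profiles.append(
                BiomarkerProfile(col.upper(), OmicType.OUTCOME_RESPONSE, labels)
            )

    if "msi_status" in cols:
        recognized = True
        profiles.append(
            msi_profile(dict(zip(clinical["patient_id"], clinical["msi_status"])))
        )

    if not recognized:
        raise ValueError("no recognized clinical outcome columns")
    return profiles


def msi_profile(status: Mapping[str, str]) -> BiomarkerProfile:
    """MSI-H positive; MSS and MSI-L negative; unknown levels excluded."""
    labels: dict[str, int] = {}
    for p, v in status.items():
        if _is_missing(v):
            continue
        if v == "MSI-H":
            labels[p] = 1
        elif v in ("MSS", "MSI-L"):
            labels[p] = 0
        else:
            warnings.warn(f"unknown MSI level {v!r}; patient excluded")
    return BiomarkerProfile("msi_status", OmicType.STANDARD_CLINICAL, labels)


def read_driver_genes(path: str | Path) -> list[str]:
    """Driver-gene list, one symbol per line, '#' comments allowed."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_profile_tables(
    profiles: Sequence[BiomarkerProfile],
    out_dir: str | Path,
    rules: Mapping[OmicType, FilterRule] | None = None,
) -> tuple[Path, Path]:
    """Write the patient x biomarker label table and profile metadata TSVs.

    Patients absent from a profile get NA.  Metadata records the omic type,
    counts and the filter decision for every profile (kept or not).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rules = dict(rules or DEFAULT_FILTER_RULES)
    patients = sorted({p for pr in profiles for p in pr.labels})
    table = pd.DataFrame(index=patients)
    meta = []
    for pr in profiles:
        keep, reason = apply_filter(pr, rules.get(pr.omic_type))
        meta.append(
            (pr.biomarker_id, pr.omic_type.value, pr.n_positive, pr.n_total,
             keep, reason)
        )
        table[pr.biomarker_id] = pd.Series(pr.labels).reindex(patients)
    labels_path = out / "profile_labels.tsv"
    meta_path = out / "profile_metadata.tsv"
    table.to_csv(labels_path, sep="\t", index_label="patient_id", na_rep="NA")
    pd.DataFrame(
        meta,
        columns=["biomarker_id", "omic_type", "n_positive", "n_total", "kept",
                 "reason"],
    ).to_csv(meta_path, sep="\t", index=False)
    return labels_path, meta_path
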