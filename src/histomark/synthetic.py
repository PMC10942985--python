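"""Desk-scale synthetic cohorts: H&E-like tiles plus omics/clinical/purity tables.

The generator produces everything the downstream stages consume — tile images
with a planted, tunable morphology difference between label classes, a MAF-like
mutation table, a gene x sample z-score matrix, a TCGA-style clinical table and
a biospecimen purity table — all with known ground truth and full determinism
under a seed.

The image model is deliberately simple but optically honest: tiles are rendered
in optical-density (OD) space by Beer–Lambert mixing of the two reference stain
vectors (hematoxylin and eosin), so stain estimation downstream can be checked
against known ground truth.  Positive-class slides have their nucleus density
and hematoxylin OD amplitude shifted by ``effect_size``; ``effect_size = 0``
makes the two classes pixel-for-pixel exchangeable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "HEMATOXYLIN_OD",
    "EOSIN_OD",
    "WHITE_LEVEL",
    "SyntheticCohortConfig",
    "SlideImages",
    "SyntheticCohort",
    "generate_cohort",
    "generate_zscore_table",
    "generate_mutation_table",
    "generate_clinical_table",
    "render_slide_image",
    "write_cohort",
]

#: Reference H&E stain vectors in optical-density space (unit norm).
HEMATOXYLIN_OD = np.array([0.65, 0.70, 0.29])
HEMATOXYLIN_OD = HEMATOXYLIN_OD / np.linalg.norm(HEMATOXYLIN_OD)
EOSIN_OD = np.array([0.07, 0.99, 0.11])
EOSIN_OD = EOSIN_OD / np.linalg.norm(EOSIN_OD)

#: Flat-field white level of the simulated scanner.
WHITE_LEVEL = 242.0

# Morphology constants (per 64x64 tile; scaled by tile area).
_NUCLEI_PER_64_TILE = 8.0
_H_AMPLITUDE = 0.85
_E_AMPLITUDE = 0.30
# Relative effect of `effect_size` on density vs. hematoxylin amplitude.
_DENSITY_GAIN = 1.0
_AMPLITUDE_GAIN = 0.5


class ConfigurationError(ValueError):
    """Raised for invalid cohort configurations."""


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Stated world for one synthetic cohort.

    Parameters
    ----------
    n_patients : int
        Cohort size.
    tiles_per_slide : int
        Tissue tiles rendered for each slide.
    prevalence : float
        Probability that a patient is biomarker-positive, in (0, 1).
    effect_size : float
        Morphology shift of the positive class; 0 is an exact null.
    purity_label_corr : float
        Target point-biserial correlation between percent tumor cells and the
        label, in [-1, 1].
    stain_jitter : float
        Scale of per-slide stain-vector and brightness perturbation.
    """

    n_patients: int
    tiles_per_slide: int = 40
    slides_per_patient: int = 1
    tile_size: int = 64
    prevalence: float = 0.5
    effect_size: float = 0.0
    purity_label_corr: float = 0.0
    stain_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigurationError(
                f"prevalence must be in (0, 1), got {self.prevalence}"
            )
        if self.tile_size < 32:
            raise ConfigurationError("tile_size must be >= 32")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if not (-1.0 <= self.purity_label_corr <= 1.0):
            raise ConfigurationError("purity_label_corr must be in [-1, 1]")
        if self.stain_jitter < 0:
            raise ConfigurationError("stain_jitter must be non-negative")
        if self.n_patients < 2:
            raise ConfigurationError("need at least 2 patients")


@dataclass
class SlideImages:
    """Tiles of one slide, pre-extracted, with the per-slide render settings."""

    patient_id: str
    slide_id: str
    tiles: np.ndarray  # (n_tiles, ts, ts, 3) uint8
    stain_vectors: np.ndarray  # (3, 2) columns = (hematoxylin, eosin) used
    white_level: float


@dataclass
class SyntheticCohort:
    config: SyntheticCohortConfig
    slides: list[SlideImages]
    labels: dict[str, int]
    purity_table: pd.DataFrame  # biospecimen-style, one row per slide
    mutation_table: pd.DataFrame
    zscore_table: pd.DataFrame  # genes x samples
    clinical_table: pd.DataFrame

    @property
    def patients(self) -> list[str]:
        return sorted(self.labels)

    def tilesets_by_patient(self) -> dict[str, list[SlideImages]]:
        out: dict[str, list[SlideImages]] = {p: [] for p in self.labels}
        for s in self.slides:
            out[s.patient_id].append(s)
        return out


def _jittered_stains(rng: np.random.Generator, jitter: float) -> tuple[np.ndarray, float]:
    h = HEMATOXYLIN_OD + jitter * rng.normal(0.0, 0.05, 3)
    e = EOSIN_OD + jitter * rng.normal(0.0, 0.05, 3)
    h = np.abs(h) / np.linalg.norm(h)
    e = np.abs(e) / np.linalg.norm(e)
    white = WHITE_LEVEL * (1.0 + jitter * rng.uniform(-0.08, 0.08))
    return np.column_stack([h, e]), float(white)


def _render_tile(
    rng: np.random.Generator,
    tile_size: int,
    label: int,
    effect_size: float,
    stain_matrix: np.ndarray,
    white_level: float,
) -> np.ndarray:
    """Render one tissue tile in OD space and develop it to RGB uint8."""
    ts = tile_size
    bump = effect_size * label
    lam = _NUCLEI_PER_64_TILE * (ts / 64.0) ** 2 * (1.0 + _DENSITY_GAIN * bump)
    amp = _H_AMPLITUDE * (1.0 + _AMPLITUDE_GAIN * bump)

    yy, xx = np.mgrid[0:ts, 0:ts].astype(np.float64)
    od_h = np.zeros((ts, ts))
    n_nuclei = rng.poisson(lam)
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(0, ts, 2)
        a = rng.uniform(2.5, 5.0)
        b = rng.uniform(2.0, 4.0)
        theta = rng.uniform(0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        xr = (xx - cx) * ct + (yy - cy) * st
        yr = -(xx - cx) * st + (yy - cy) * ct
        q = (xr / a) ** 2 + (yr / b) ** 2
        od_h += amp * rng.uniform(0.8, 1.2) * np.exp(-(q ** 1.5))

    # Low-frequency eosin (cytoplasm) field, identical law for both classes;
    # attenuated where nuclei are dense (nuclei displace cytoplasm), which
    # also gives the OD cloud near-pure hematoxylin pixels.
    noise = gaussian_filter(rng.normal(0.0, 1.0, (ts, ts)), sigma=6.0)
    noise /= max(noise.std(), 1e-9)
    od_e = _E_AMPLITUDE * (1.0 + 0.5 * np.tanh(1.5 * noise))
    od_e = od_e * np.exp(-2.0 * od_h)

    # White lumens/gaps (glands, fat, tears): both stains attenuated.  They
    # keep a fraction of near-white pixels in every tile, as in real tissue,
    # which is what makes tile-level white-point estimation well posed.
    clear = np.ones((ts, ts))
    for _ in range(rng.poisson(1.5) + 1):
        cy, cx = rng.uniform(0, ts, 2)
        a = rng.uniform(5.0, 12.0)
        b = rng.uniform(4.0, 10.0)
        q = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
        clear *= 1.0 - 0.98 * np.exp(-(q ** 2))
    od_h = od_h * clear
    od_e = od_e * clear

    od = od_h[..., None] * stain_matrix[:, 0] + od_e[..., None] * stain_matrix[:, 1]
    rgb = white_level * np.exp(-od)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def render_slide_image(
    seed: int,
    height: int = 1024,
    width: int = 1024,
    n_tissue_blobs: int = 3,
    tile_size: int = 64,
    effect_size: float = 0.0,
    label: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a monolithic slide image: white background with tissue regions.

    Returns the RGB uint8 image and a boolean tissue mask of the same height
    and width.  Exercises the tiler's background rejection: tiles fully outside
    the mask are blank white (zero variance).
    """
    rng = np.random.default_rng(seed)
    mask = np.zeros((height, width), dtype=bool)
    yy, xx = np.mgrid[0:height, 0:width]
    for _ in range(n_tissue_blobs):
        cy = rng.uniform(0.2 * height, 0.8 * height)
        cx = rng.uniform(0.2 * width, 0.8 * width)
        a = rng.uniform(0.12, 0.25) * width
        b = rng.uniform(0.12, 0.25) * height
        mask |= ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 < 1.0

    image = np.full((height, width, 3), int(round(WHITE_LEVEL)), dtype=np.uint8)
    stains = np.column_stack([HEMATOXYLIN_OD, EOSIN_OD])
    for r0 in range(0, height - tile_size + 1, tile_size):
        for c0 in range(0, width - tile_size + 1, tile_size):
            block = mask[r0 : r0 + tile_size, c0 : c0 + tile_size]
            if not block.any():
                continue
            tile = _render_tile(rng, tile_size, label, effect_size, stains, WHITE_LEVEL)
            region = image[r0 : r0 + tile_size, c0 : c0 + tile_size]
            region[block] = tile[block]
    return image, mask


def generate_zscore_table(
    n_samples: int,
    genes: Sequence[str],
    shifted_genes: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene x sample z-score matrix: standard normal with per-gene mean shifts."""
    if len(genes) == 0:
        raise ValueError("genes must be non-empty")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene names")
    shifted_genes = dict(shifted_genes or {})
    unknown = set(shifted_genes) - set(genes)
    if unknown:
        raise ValueError(f"shifted genes not in gene list: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, 1.0, (len(genes), n_samples))
    for g, shift in shifted_genes.items():
        z[list(genes).index(g)] += shift
    samples = [f"S{i:04d}" for i in range(n_samples)]
    return pd.DataFrame(z, index=list(genes), columns=samples)


def generate_mutation_table(
    n_samples: int,
    gene_rates: Mapping[str, float],
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """MAF-like records: each sample x gene mutated independently at its rate."""
    for g, r in gene_rates.items():
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"mutation rate for {g} outside [0, 1]: {r}")
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    elif len(sample_ids) != n_samples:
        raise ValueError("sample_ids length must equal n_samples")
    records = []
    for gene, rate in gene_rates.items():
        hits = rng.random(n_samples) < rate
        for sid in np.asarray(sample_ids)[hits]:
            records.append((sid, gene, "SNP"))
    return pd.DataFrame(
        records, columns=["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Type"]
    )


# Clinical column vocabulary and the label -> category mappings used both by
# the generator (forward) and by the profiles module (inverse).
CLINICAL_POSITIVE = {
    "residual_tumor": ("R1", "R2"),
    "margin_status": ("Positive",),
    "treatment_outcome_first_course": ("Complete Remission/Response",),
    "treatment_best_response": ("Complete Response",),
    "msi_status": ("MSI-H",),
}
CLINICAL_NEGATIVE = {
    "residual_tumor": ("R0",),
    "margin_status": ("Negative",),
    "treatment_outcome_first_course": (
        "Stable Disease",
        "Partial Response",
        "Progressive Disease",
    ),
    "treatment_best_response": (
        "Stable Disease",
        "Partial Response",
        "Progressive Disease",
    ),
    "msi_status": ("MSS", "MSI-L"),
}
SUPPORTED_CLINICAL_FIELDS = tuple(CLINICAL_POSITIVE)


def generate_clinical_table(
    labels: Mapping[str, int],
    fields: Sequence[str],
    seed: int = 0,
    missing_rate: float = 0.0,
) -> pd.DataFrame:
    """Clinical table whose categories encode the given binary labels."""
    for f in fields:
        if f not in SUPPORTED_CLINICAL_FIELDS:
            raise ValueError(f"unknown clinical field: {f!r}")
    if not (0.0 <= missing_rate <= 1.0):
        raise ValueError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    patients = list(labels)
    data: dict[str, list] = {"patient_id": patients}
    for f in fields:
        col = []
        for p in patients:
            pool = CLINICAL_POSITIVE[f] if labels[p] == 1 else CLINICAL_NEGATIVE[f]
            col.append(pool[rng.integers(len(pool))])
        data[f] = col
    table = pd.DataFrame(data)
    if missing_rate > 0:
        for f in fields:
            drop = rng.random(len(patients)) < missing_rate
            table.loc[drop, f] = np.nan
    return table


def _purity_values(
    rng: np.random.Generator, labels: np.ndarray, prevalence: float, corr: float
) -> np.ndarray:
    """Percent tumor cells with a calibrated point-biserial label correlation.

    purity = base + delta * (label - p) + N(0, sigma); delta solves
    corr = delta * sqrt(p(1-p)) / sqrt(delta^2 p(1-p) + sigma^2).
    """
    sigma, base = 10.0, 55.0
    c = float(np.clip(corr, -0.999, 0.999))
    p = prevalence
    delta = sigma * c / np.sqrt(p * (1 - p) * (1 - c * c))
    vals = base + delta * (labels - p) + rng.normal(0.0, sigma, labels.shape)
    return np.clip(vals, 0.0, 100.0)


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort from its configuration.

    The seed is split hierarchically (`numpy.random.SeedSequence`) so every
    component stream is independent and the whole cohort is bit-reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    s_labels, s_images, s_purity, s_mut, s_z, s_clin = ss.spawn(6)

    rng = np.random.default_rng(s_labels)
    patients = [f"P{i:04d}" for i in range(config.n_patients)]
    label_arr = (rng.random(config.n_patients) < config.prevalence).astype(int)
    labels = dict(zip(patients, (int(v) for v in label_arr)))

    # --- images -----------------------------------------------------------
    slides: list[SlideImages] = []
    img_rng = np.random.default_rng(s_images)
    for pi, p in enumerate(patients):
        for si in range(config.slides_per_patient):
            stains, white = _jittered_stains(img_rng, config.stain_jitter)
            tiles = np.stack(
                [
                    _render_tile(
                        img_rng,
                        config.tile_size,
                        labels[p],
                        config.effect_size,
                        stains,
                        white,
                    )
                    for _ in range(config.tiles_per_slide)
                ]
            )
            slides.append(
                SlideImages(
                    patient_id=p,
                    slide_id=f"{p}-SL{si:02d}",
                    tiles=tiles,
                    stain_vectors=stains,
                    white_level=white,
                )
            )

    # --- purity (biospecimen-style, one row per slide) --------------------
    pur_rng = np.random.default_rng(s_purity)
    patient_purity = _purity_values(
        pur_rng, label_arr.astype(float), config.prevalence, config.purity_label_corr
    )
    rows = []
    for s in slides:
        pi = patients.index(s.patient_id)
        v = np.clip(patient_purity[pi] + pur_rng.normal(0.0, 2.0), 0.0, 100.0)
        rows.append((s.patient_id, s.slide_id, round(float(v), 1)))
    purity_table = pd.DataFrame(
        rows, columns=["patient_id", "slide_id", "percent_tumor_cells"]
    )

    # --- omics tables tied to the ground-truth label ----------------------
    # TP53 mutation status mirrors the image label exactly; other driver genes
    # carry independent background mutation rates.
    mut_rng_seed = int(np.random.default_rng(s_mut).integers(2**31))
    background = {"PIK3CA": 0.25, "KRAS": 0.2, "EGFR": 0.15, "BRAF": 0.1}
    mutation_table = generate_mutation_table(
        config.n_patients, background, seed=mut_rng_seed, sample_ids=patients
    )
    tp53 = pd.DataFrame(
        [(p, "TP53", "SNP") for p in patients if labels[p] == 1],
        columns=mutation_table.columns,
    )
    mutation_table = pd.concat([tp53, mutation_table], ignore_index=True)

    z_seed = int(np.random.default_rng(s_z).integers(2**31))
    zscore_table = generate_zscore_table(
        config.n_patients,
        ["MKI67", "ESR1", "ERBB2", "MYC"],
        shifted_genes={"MKI67": 1.0},
        seed=z_seed,
    )
    zscore_table.columns = patients

    clin_seed = int(np.random.default_rng(s_clin).integers(2**31))
    clinical_table = generate_clinical_table(
        labels,
        ["residual_tumor", "treatment_best_response", "msi_status"],
        seed=clin_seed,
    )

    return SyntheticCohort(
        config=config,
        slides=slides,
        labels=labels,
        purity_table=purity_table,
        mutation_table=mutation_table,
        zscore_table=zscore_table,
        clinical_table=clinical_table,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write tiles as PNGs plus manifest and tables as TSV/CSV under out_dir."""
    out = Path(out_dir)
    tile_dir = out / "tiles"
    tile_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for s in cohort.slides:
        for ti, tile in enumerate(s.tiles):
            path = tile_dir / f"{s.slide_id}_{ti:04d}.png"
            Image.fromarray(tile).save(path)
            manifest.append(
                (s.patient_id, s.slide_id, str(path.relative_to(out)),
                 cohort.labels[s.patient_id])
            )
    pd.DataFrame(
        manifest, columns=["patient_id", "slide_id", "path", "label"]
    ).to_csv(out / "manifest.tsv", sep="\t", index=False)
    cohort.purity_table.to_csv(out / "biospecimen.tsv", sep="\t", index=False)
    cohort.mutation_table.to_csv(out / "mutations.maf.tsv", sep="\t", index=False)
    cohort.zscore_table.to_csv(out / "zscores.csv")
    cohort.clinical_table.to_csv(out / "clinical.tsv", sep="\t", index=False)
    return out
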