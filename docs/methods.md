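# Methods

`histomark` implements, at desk scale, the weakly-supervised pipeline used to
assess whether molecular biomarker status can be predicted from H&E histology
tiles: label engineering from omics and clinical tables, tile preprocessing
with Macenko stain normalization, an autoencoder-with-classifier tile
network, patient-level cross-validated AUC evaluation with two significance
procedures, and a tumor-purity control. This note records the model, its
assumptions, the parameters that matter, and the numerical and design
choices made where the protocol left them open.

## Biomarker label engineering

A biomarker profile is a per-patient binary vector. The construction rules:

* **SNV profiles.** A sequenced sample is positive for a driver gene if it
  carries at least one single-nucleotide variant in that gene. Samples
  without WGS/WXS data must be excluded by the caller *before* profile
  construction; the remaining unlisted samples are assumed wild-type
  (negative). This asymmetry is the reason `snv_profile` takes an explicit
  `sequenced_samples` universe.
* **Expression profiles.** z-scores are binarized at symmetric thresholds,
  boundaries inclusive: under-expressed iff z ≤ t_under, over-expressed iff
  z ≥ t_over, with {−2, 2} for transcriptomics and {−1.5, 1.5} for
  proteomics. Each gene yields one under- and one over-expression profile.
* **Clinical mappings.** Residual tumor R1/R2 → positive, R0 → negative
  (`margin_status` Positive/Negative as fallback when residual tumor is
  absent); treatment outcome/best response: complete remission/response →
  positive, stable disease / partial response / progressive disease →
  negative; MSI-H → positive, MSS and MSI-L → negative. Survival endpoints
  (OS/DSS/DFI/PFI) are consumed as already-binary labels; deriving them from
  raw clinical fields is out of scope.
* **Categorical features** are one-hot encoded (one profile per category);
  **continuous features** are binarized at the mean of non-missing values.
  A value exactly at the mean is negative — the rule is a strict `>`, a
  choice this package declares and tests.
* Missing source values exclude a patient from the affected profile; nothing
  is imputed.

Inclusion filters: minimum 10 positive patients in general, 20 for
proteomic profiles, and for transcriptomic profiles additionally a positive
ratio of at least 10%. The filter registry is keyed by omic type and can be
overridden. Patients whose samples disagree on a label are an error, not a
merge: reconciliation policy is the caller's.

## Tiling and stain normalization

Slides are parcellated into a non-overlapping grid of square tiles (256 px
in the reference protocol; 64 px at desk scale); partial edge tiles are
dropped. A tile is kept iff its grayscale standard deviation exceeds a
threshold (default 5.0 on 8-bit gray; the protocol names the filter but not
the value, so it is exposed in config, and whether the filter is grayscale
or per-channel was also unstated — grayscale chosen). A slide with fewer
than 10 surviving tiles is discarded, as is a slide without
microns-per-pixel metadata.

Macenko normalization: pixels are mapped to optical density
OD = −log(I / I₀); pixels with all OD components below the floor β = 0.15
are background; the stain plane is the span of the top-2 right singular
vectors of the (uncentered) foreground OD matrix; the two stain vectors are
the angular extremes of the projected cloud at percentile α = 1%; the
concentration scale is the 99th percentile of per-stain concentrations.
These are the standard reference-implementation defaults. The hematoxylin
column is the extreme with the larger red OD component. Normalizing a tile
solves non-negative concentrations against the fitted matrix, rescales them
to the reference's concentration maxima, and redevelops with the reference
stain matrix and white level.

**White point.** I₀ is estimated as the 99th-percentile luminance of the
image. An earlier draft used the 90th percentile; that estimator is biased
dark on tiles that are mostly tissue (the 90th percentile then falls inside
stained tissue), which tilts every OD vector by a constant multiple of
(1,1,1) and systematically rotates the recovered eosin direction by ~25°.
The 99th percentile lands on lumens/gaps, which real tissue tiles — and the
generator's — contain. "Brightness normalization" means each tile's own
white point is mapped to the reference's before OD conversion.

One normalizer is fitted per cohort on a designated reference image (the
protocol is silent; cohort-level is chosen for determinism), and a
degenerate tile (no stained pixels) is returned unchanged with a warning
flag rather than failing the slide.

## Network and training

The network is an autoencoder with an auxiliary softmax head. The encoder
maps a tile to a d-dimensional embedding; the decoder reconstructs the tile
from the embedding; a single dense layer classifies the embedding into two
classes. The total loss is CE + w·MSE with w = 1 (the protocol says the
losses are "added"; pixels are scaled to [0,1] so the two terms are
comparable; w is exposed in config). Probabilities are clamped at 1e−12 in
the CE term.

Two encoder architectures exist. `small_cnn` (the desk-scale default,
d = 64): three stride-2 3×3 conv blocks (8/16/32 channels) → global average
pool → dense; the decoder mirrors it with three 2×2 stride-2 transposed
convolutions and a sigmoid output. `resnet34` (d = 512): a
resnet34-style encoder — 7×7 stride-2 stem, 2×2 max pool, basic residual
blocks in stages of (3,4,6,3) — without batch normalization (a desk-scale
simplification; the reference names only the architecture family). It is
constructible and trainable but not exercised by the acceptance runs, which
the reference protocol's GPU-scale configuration does not require.

Because no GPU framework is available in the target environment, the layers
are implemented directly in numpy with manual gradients; convolutions are
im2col matrix products, so the heavy work is BLAS. Gradients are verified
against central finite differences in the test suite.

Weak supervision and training protocol: every tile inherits its slide's
label; 200 tiles are sampled per training slide each epoch (without
replacement when the slide has enough tiles, with replacement otherwise;
whether the reference redraws per epoch is unstated — redrawn per epoch
chosen, exposed in config); minority-class tiles are oversampled with
replacement to an exact 50–50 epoch composition; optimization is Adam at
learning rate 1e−4 for 10 epochs. The minibatch size defaults to 16: per
epoch it costs the same wall time as larger batches here (the per-tile conv
cost is flat), and because Adam's per-parameter step is bounded by the
learning rate, the number of steps — not the data volume — bounds how far
weights can move at desk scale. Large batches leave the softmax scores
compressed around 0.5, which in turn lets per-fold calibration offsets
dominate pooled cross-fold score comparisons. After each epoch, slide-level AUC on the
held-out fold is logged (slide score = mean tile probability), and the
epoch with the highest validation AUC supplies the final weights (earliest
epoch wins ties; a single-class validation fold falls back to the last
epoch with a warning). Note the protocol's "validation" fold doubles as the
reported test fold — a selection leak it inherits and this package
reproduces as described rather than silently fixing.

Training is bit-reproducible under a fixed seed (numpy `SeedSequence`
spawning per component; single-threaded BLAS may be required for exact
cross-machine reproducibility of float32 reductions).

## Evaluation and statistics

Patients with a valid label are split into k = 3 folds, stratified by
shuffling positives and negatives separately and dealing round-robin, which
guarantees per-fold positive counts within one of exact stratification. All
slides of a patient share a fold. A biomarker with fewer than 10 positive
patients is skipped (a signal, not an exception). Held-out scores aggregate
hierarchically: slide score = mean of tile scores, patient score = mean of
slide scores. AUC is the rank (Mann–Whitney) statistic with ties credited
0.5; the per-biomarker summary is the mean and sample (n−1) standard
deviation over the three fold AUCs.

Group-level significance: a group of AUCs is compared by two-sided t-test
(`scipy.stats.ttest_ind`) against a same-size normal sample with mean 0.5
and the group's standard deviation (the reference states the mean and
standard deviation of the null sample but not its size; same-size chosen).
Biomarker-level significance: pooled held-out *patient* scores (the
reference does not fully specify slide vs patient level; patient chosen)
from all three folds, positives vs negatives, two-sided t-test — note this
pooling compares raw scores produced by three independently trained models,
so per-fold calibration offsets add variance the within-fold AUCs do not
see; the
resulting p-values are corrected with Benjamini–Hochberg at FDR 0.05 across
all biomarkers evaluated in one run (the family scope is likewise
unstated). Significant means adjusted p < 0.05. BH is delegated to
`statsmodels.multipletests(method="fdr_bh")` and cross-checked in the tests
against a literal step-up implementation; AUC is similarly cross-checked
against brute-force pair counting.

Heatmaps color-map tile scores onto the slide grid; top-k tiles are sorted
by score with ties broken by (row, col).

## Tumor-purity baseline

Per-case purity is the mean of `percent_tumor_cells` over a patient's
biospecimen slide rows; cases lacking the field are excluded. For each
biomarker, three random-forest classifiers (scikit-learn, 100 trees,
default depth, fixed seed — hyperparameters unstated in the reference) are
trained on purity alone using *the same fold assignment* as the image
model, giving a one-to-one f_image vs f_purity correspondence. A
single-feature random forest is nearly a learned thresholding; that is the
point — it measures how much of the image model's performance purity alone
explains. Image-vs-purity AUC collections are compared per omic subgroup
with a two-sided t-test, and mean per-biomarker purity is correlated with
image-model AUC (Pearson) per subgroup.

## Synthetic cohorts: what they emulate, and what a green test means

The generator produces tiles in OD space by Beer–Lambert mixing of the two
reference stain vectors (hematoxylin ≈ (0.65, 0.70, 0.29), eosin ≈
(0.07, 0.99, 0.11), unit-normalized) over a flat white of 242: elliptical
"nuclei" carry hematoxylin, a low-frequency smooth field carries eosin
(attenuated where nuclei are dense — nuclei displace cytoplasm, which also
gives the OD cloud near-pure hematoxylin pixels), and elliptical white
lumens/gaps keep a fraction of near-white pixels in every tile so white-point
estimation is well posed. Positive-class slides have nucleus density scaled
by (1 + effect_size) and hematoxylin amplitude by (1 + effect_size/2);
effect_size 0 makes the classes exactly exchangeable. Per-slide stain
jitter perturbs the stain vectors (σ = 0.05·jitter per component) and the
white level (±8%·jitter). Defaults: 40 tiles/slide, 64 px tiles,
one slide per patient.

Purity values are base 55%, σ = 10, with a label-conditional shift Δ
calibrated analytically so the point-biserial correlation with the label
equals `purity_label_corr`:
Δ = σ·c / √(p(1−p)(1−c²)). A Gaussian-copula construction was considered
and rejected: with a binary label at prevalence 0.4 its point-biserial
correlation is capped near 0.79, so strong-correlation regimes (0.9) would
be unreachable.

Mutation tables are independent per-gene Bernoulli draws in a minimal MAF
dialect; z-score tables are standard normal with per-gene mean shifts;
clinical tables are the exact inverse images of the profile mappings with
configurable missingness — so generator → profiles round-trips recover
ground truth exactly at missing rate 0.

What a green test does *not* establish: the image model is not
photo-realistic — no nuclear chromatin texture, no pen/blur/fold artifacts,
no site-specific fingerprints, no relationship between real H&E morphology
and real biomarkers. The planted effect sizes are stand-ins; nothing here
claims real slides carry signal of any particular magnitude. Green means
the *machinery* — label rules, stain math, training loop, aggregation,
statistics — does what it says on inputs with known truth.

## Degenerate inputs and tie-breaks (summary)

* AUC with one class present: error. Tied scores: 0.5 credit.
* Validation fold single-class: AUC undefined → last epoch, warning.
* Zero-spread AUC group in the group t-test: p = 1, warning.
* Single-class pooled scores: excluded from the BH family, warning.
* Mean-binarization tie at the mean: negative.
* Top-k tile ties: (row, col) lexicographic.
* All-white tile in normalization: returned unchanged, flagged.
* Epoch-selection tie on validation AUC: earliest epoch.

## Known limitations

* Desk-scale only: the reference's 12,093-model TCGA-scale experiment and
  its headline AUC distribution are not reproducible here and are not
  attempted; acceptance runs use a 60-patient synthetic cohort.
* The numpy network trains at useful speed only for small tiles and
  channel counts; `resnet34` at 256 px is supported in construction
  but impractical to train on one CPU.
* Pyramidal WSI formats are out of scope; inputs are PNG/TIFF images or
  pre-extracted tiles with caller-supplied MPP.
* The validation-as-test selection leak of the reference protocol is
  reproduced, not repaired.
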