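"""Encoder–decoder–classifier tile network and its training loop.

The network is an autoencoder with an auxiliary classification head: an
encoder maps a tile to a d-dimensional embedding, a decoder reconstructs the
tile from the embedding (mean-squared-error loss), and a single dense softmax
layer classifies the embedding (cross-entropy loss).  The two losses are
added; training the reconstruction path regularizes the embedding toward
noise-free representations.

Training follows the weakly-supervised tile paradigm: every tile inherits its
slide's binary label, a fixed number of tiles is sampled per training slide
each epoch, minority-class tiles are oversampled to a 50–50 epoch composition,
optimization is Adam at learning rate 1e-4 for 10 epochs, and the epoch with
the best slide-level validation AUC provides the final weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nnet

__all__ = [
    "ModelConfig",
    "LabeledSlide",
    "AutoencoderClassifier",
    "TrainedFoldModel",
    "build_model",
    "combined_loss",
    "sample_training_tiles",
    "train_fold",
    "predict_tile_scores",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one biomarker/fold model.

    ``d`` is the embedding dimension (64 for the desk-scale encoder, 512 for
    the full-scale resnet one); training defaults mirror the reference protocol:
    Adam at 1e-4, 10 epochs, 200 tiles sampled per training slide (redrawn
    every epoch), 1:1 loss weighting on pixel scale [0, 1].
    """

    d: int = 64
    encoder_arch: str = "small_cnn"  # or "resnet34"
    tile_size: int = 64
    learning_rate: float = 1e-4
    epochs: int = 10
    tiles_per_slide: int = 200
    # small batches cost the same wall time per epoch as large ones here but
    # give Adam an order of magnitude more steps, which the scores' dynamic
    # range depends on at desk scale
    batch_size: int = 16
    loss_weight_mse: float = 1.0
    resample_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("d must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.encoder_arch not in ("small_cnn", "resnet34"):
            raise ValueError(f"unknown encoder_arch {self.encoder_arch!r}")
        down = 8 if self.encoder_arch == "small_cnn" else 32
        if self.tile_size % down != 0:
            raise ValueError(
                f"tile_size {self.tile_size} incompatible with "
                f"{self.encoder_arch} downsampling factor {down}"
            )


@dataclass
class LabeledSlide:
    """All filtered tiles of one slide with its weak (slide-level) label."""

    slide_id: str
    patient_id: str
    tiles: np.ndarray  # (n, ts, ts, 3) uint8
    label: int


class AutoencoderClassifier:
    """Encoder + decoder + softmax classifier over tile embeddings."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        ts, d = config.tile_size, config.d
        if config.encoder_arch == "small_cnn":
            chans = (8, 16, 32)
            self.encoder = nnet.Sequential(
                nnet.Conv2d(3, chans[0], 3, 2, 1, rng), nnet.ReLU(),
                nnet.Conv2d(chans[0], chans[1], 3, 2, 1, rng), nnet.ReLU(),
                nnet.Conv2d(chans[1], chans[2], 3, 2, 1, rng), nnet.ReLU(),
                nnet.GlobalAvgPool(),
                nnet.Dense(chans[2], d, rng),
            )
            bottom, factor = chans[2], 8
            dec_chans = (32, 16, 8)
        else:
            self.encoder = _resnet34_encoder(d, rng)
            bottom, factor = 512, 32
            dec_chans = (512, 256, 128, 64, 32)
        hb = ts // factor
        dec: list[nnet.Layer] = [
            nnet.Dense(d, bottom * hb * hb, rng), nnet.ReLU(),
            nnet.Reshape((bottom, hb, hb)),
        ]
        prev = bottom
        for c in dec_chans[1:]:
            dec += [nnet.ConvTranspose2d(prev, c, 2, 2, rng), nnet.ReLU()]
            prev = c
        dec += [nnet.ConvTranspose2d(prev, 3, 2, 2, rng), nnet.Sigmoid()]
        self.decoder = nnet.Sequential(*dec)
        self.classifier = nnet.Sequential(nnet.Dense(d, 2, rng))

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """x: (B, 3, ts, ts) float32 in [0,1] -> (embedding, logits, recon)."""
        emb = self.encoder.forward(x)
        logits = self.classifier.forward(emb)
        recon = self.decoder.forward(emb)
        return emb, logits, recon

    def backward(self, dlogits: np.ndarray, drecon: np.ndarray) -> None:
        demb = self.classifier.backward(dlogits) + self.decoder.backward(drecon)
        self.encoder.backward(demb)

    def parameters(self) -> list[np.ndarray]:
        return (self.encoder.parameters() + self.classifier.parameters()
                + self.decoder.parameters())

    def gradients(self) -> list[np.ndarray]:
        return (self.encoder.gradients() + self.classifier.gradients()
                + self.decoder.gradients())

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights, strict=True):
            p[...] = w


def _resnet34_encoder(d: int, rng: np.random.Generator) -> nnet.Sequential:
    """Resnet34-style encoder: 7x7 stem + (3,4,6,3) basic blocks, no batch norm."""
    def block(c_in, c_out, stride):
        body = nnet.Sequential(
            nnet.Conv2d(c_in, c_out, 3, stride, 1, rng), nnet.ReLU(),
            nnet.Conv2d(c_out, c_out, 3, 1, 1, rng),
        )
        proj = (nnet.Conv2d(c_in, c_out, 1, stride, 0, rng)
                if (stride != 1 or c_in != c_out) else None)
        return nnet.ResidualBlock(body, proj)

    layers: list[nnet.Layer] = [
        nnet.Conv2d(3, 64, 7, 2, 3, rng), nnet.ReLU(), nnet.MaxPool2x2(),
    ]
    spec = [(64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)]
    c_in = 64
    for c_out, n_blocks, first_stride in spec:
        for i in range(n_blocks):
            layers.append(block(c_in, c_out, first_stride if i == 0 else 1))
            c_in = c_out
    layers += [nnet.GlobalAvgPool(), nnet.Dense(512, d, rng)]
    return nnet.Sequential(*layers)


def build_model(config: ModelConfig) -> AutoencoderClassifier:
    """Construct an untrained network from its configuration."""
    return AutoencoderClassifier(config)


_EPS = 1e-12


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def combined_loss(
    tile: np.ndarray,
    reconstruction: np.ndarray,
    class_probabilities: np.ndarray,
    label: np.ndarray | int,
    mse_weight: float = 1.0,
) -> float:
    """Total loss = cross-entropy(label, probs) + w * MSE(tile, reconstruction).

    Tiles and reconstructions are on pixel scale [0, 1] so the two terms have
    comparable magnitude.  Probabilities are clamped at 1e-12, never infinite.
    """
    tile = np.asarray(tile, dtype=np.float64)
    recon = np.asarray(reconstruction, dtype=np.float64)
    probs = np.atleast_2d(np.asarray(class_probabilities, dtype=np.float64))
    labels = np.atleast_1d(np.asarray(label, dtype=int))
    mse = float(np.mean((tile - recon) ** 2))
    p_true = np.clip(probs[np.arange(len(labels)), labels], _EPS, 1.0)
    ce = float(-np.mean(np.log(p_true)))
    return ce + mse_weight * mse


def _loss_and_grads(
    x: np.ndarray, logits: np.ndarray, recon: np.ndarray, labels: np.ndarray,
    mse_weight: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Batch loss and gradients w.r.t. logits and reconstruction."""
    B = x.shape[0]
    probs = softmax(logits)
    loss = combined_loss(x, recon, probs, labels, mse_weight)
    onehot = np.zeros_like(probs)
    onehot[np.arange(B), labels] = 1.0
    dlogits = ((probs - onehot) / B).astype(np.float32)
    drecon = (mse_weight * 2.0 * (recon - x) / x.size).astype(np.float32)
    return loss, dlogits, drecon


def sample_training_tiles(
    tiles: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample n tile indices; without replacement when enough tiles exist."""
    m = len(tiles)
    if m == 0:
        raise ValueError("empty tile set")
    idx = rng.choice(m, size=n, replace=m < n)
    return tiles[idx]


def _oversample_balance(
    x: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Resample minority-class tiles with replacement to an exact 50-50 mix."""
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0 or n_pos == n_neg:
        return x, y
    minority = 1 if n_pos < n_neg else 0
    need = abs(n_neg - n_pos)
    pool = np.where(y == minority)[0]
    extra = rng.choice(pool, size=need, replace=True)
    return np.concatenate([x, x[extra]]), np.concatenate([y, y[extra]])


def _as_batch(tiles: np.ndarray) -> np.ndarray:
    """uint8 NHWC -> float32 NCHW in [0, 1]."""
    return (tiles.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)


def predict_tile_scores(
    model: AutoencoderClassifier, tiles: np.ndarray, batch_size: int = 256
) -> np.ndarray:
    """Positive-class probability per tile (forward pass only)."""
    out = []
    for i in range(0, len(tiles), batch_size):
        x = _as_batch(tiles[i : i + batch_size])
        emb = model.encoder.forward(x)
        logits = model.classifier.forward(emb)
        out.append(softmax(logits)[:, 1])
    return np.concatenate(out)


@dataclass
class TrainedFoldModel:
    """Weights selected by validation AUC, plus the full training log."""

    model: AutoencoderClassifier
    selected_epoch: int  # 1-based
    training_log: list[dict]
    fold: int = 0

    @property
    def validation_auc(self) -> float:
        return self.training_log[self.selected_epoch - 1]["val_auc"]


def train_fold(
    model: AutoencoderClassifier,
    train_slides: Sequence[LabeledSlide],
    val_slides: Sequence[LabeledSlide],
    config: ModelConfig | None = None,
    fold: int = 0,
) -> TrainedFoldModel:
    """Train one cross-validation fold and return the best-epoch weights.

    Train and validation patient sets must be disjoint.  Each epoch: redraw
    ``tiles_per_slide`` tiles per training slide, oversample the minority
    class to 50-50, run Adam over shuffled minibatches, then log slide-level
    validation AUC.  The returned weights are from the epoch with the highest
    validation AUC (earliest wins ties); if validation AUC is undefined
    (single-class fold) the last epoch is used with a warning.
    """
    from .evaluation import compute_auc  # local import to avoid a cycle

    config = config or model.config
    train_pat = {s.patient_id for s in train_slides}
    val_pat = {s.patient_id for s in val_slides}
    if train_pat & val_pat:
        raise ValueError(f"patients in both train and val: {train_pat & val_pat}")

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1, fold)))
    opt = nnet.Adam(model.parameters(), model.gradients(), lr=config.learning_rate)
    log: list[dict] = []
    snapshots: list[list[np.ndarray]] = []

    fixed_draw: tuple[np.ndarray, np.ndarray] | None = None
    for epoch in range(1, config.epochs + 1):
        if config.resample_each_epoch or fixed_draw is None:
            xs, ys = [], []
            for s in train_slides:
                xs.append(sample_training_tiles(s.tiles, config.tiles_per_slide, rng))
                ys.append(np.full(config.tiles_per_slide, s.label, dtype=int))
            draw = (np.concatenate(xs), np.concatenate(ys))
            if not config.resample_each_epoch:
                fixed_draw = draw
        else:
            draw = fixed_draw
        x_all, y_all = _oversample_balance(draw[0], draw[1], rng)
        order = rng.permutation(len(x_all))
        x_all, y_all = x_all[order], y_all[order]

        losses = []
        for i in range(0, len(x_all), config.batch_size):
            x = _as_batch(x_all[i : i + config.batch_size])
            y = y_all[i : i + config.batch_size]
            _, logits, recon = model.forward(x)
            loss, dlogits, drecon = _loss_and_grads(
                x, logits, recon, y, config.loss_weight_mse
            )
            model.backward(dlogits, drecon)
            opt.step()
            losses.append(loss)

        slide_scores = {
            s.slide_id: float(predict_tile_scores(model, s.tiles).mean())
            for s in val_slides
        }
        val_labels = {s.slide_id: s.label for s in val_slides}
        if len(set(val_labels.values())) < 2:
            val_auc = float("nan")
        else:
            val_auc = compute_auc(slide_scores, val_labels)
        log.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_auc": val_auc}
        )
        snapshots.append(model.get_weights())

    aucs = np.array([e["val_auc"] for e in log])
    if np.isnan(aucs).all():
        warnings.warn("validation fold is single-class; using last epoch")
        best = len(log)
    else:
        best = int(np.nanargmax(aucs)) + 1
    model.set_weights(snapshots[best - 1])
    return TrainedFoldModel(model, best, log, fold)


def save_checkpoint(trained: TrainedFoldModel, path: str | Path) -> None:
    """Write weights (.npz) plus config/log JSON next to it."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"),
             *[p for p in trained.model.parameters()])
    meta = {
        "config": {k: getattr(trained.model.config, k)
                   for k in trained.model.config.__dataclass_fields__},
        "selected_epoch": trained.selected_epoch,
        "fold": trained.fold,
        "training_log": trained.training_log,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> TrainedFoldModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig(**meta["config"])
    model = AutoencoderClassifier(config)
    with np.load(path.with_suffix(".npz")) as data:
        weights = [data[k] for k in data.files]
    model.set_weights(weights)
    return TrainedFoldModel(
        model, meta["selected_epoch"], meta["training_log"], meta["fold"]
    )
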