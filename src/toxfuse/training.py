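"""Two-phase optimization under a masked multi-task objective.

Phase 1 trains each modality encoder individually (jointly with a 12-task
linear probe head) so it can later serve as a fixed feature extractor; the
spectrum encoder trains only on the spectrum-available subset.  Phase 2
freezes all encoders and trains the fusion network plus the learnable
missing-spectrum token on the full dataset.  Both phases use Adam, early
stopping on validation macro ROC-AUC, and restore the best-epoch weights.

Defaults follow the protocol: encoder phase max 50 epochs / patience 10,
fusion phase max 30 epochs / patience 5, batch size 32.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from . import nn
from .chem_io import (MISSING, N_TASKS, MoleculeRecord, SpectrumBinning,
                      bin_spectrum, featurize_graph, normalize_image,
                      render_image, tokenize_smiles)
from .encoders import (GraphEncoder, GraphEncoderConfig, ImageEncoder,
                       ImageEncoderConfig, SmilesEncoder, SmilesEncoderConfig,
                       SpectrumEncoder, SpectrumEncoderConfig, MODALITIES)
from .fusion import FusionConfig, FusionModel, ModalityBundle
from .splits_eval import macro_roc_auc

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    phase: str = "encoder"  # {"encoder", "fusion"}
    max_epochs: int = 50
    batch_size: int = 32
    patience: int = 10
    lr: float = 1e-3
    weight_decay: float = 0.0
    seed: int = 0
    augment_images: bool = True
    per_task_mean: bool = False  # mean-of-task-means loss variant

    def __post_init__(self):
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def fusion_train_config(**kw) -> TrainConfig:
    defaults = dict(phase="fusion", max_epochs=30, patience=5)
    defaults.update(kw)
    return TrainConfig(**defaults)


@dataclass
class LabelMask:
    """Binary targets with an observed-entry mask; MISSING slots carry an
    arbitrary stored value and must never influence loss or gradients."""

    targets: np.ndarray  # (B, 12) in {0, 1} (arbitrary where unobserved)
    observed: np.ndarray  # (B, 12) bool

    @classmethod
    def from_labels(cls, labels: np.ndarray) -> "LabelMask":
        labels = np.asarray(labels, dtype=np.float32)
        observed = labels != MISSING
        targets = np.where(observed, labels, 0.0).astype(np.float32)
        return cls(targets, observed)


def masked_multitask_loss(logits: nn.Tensor, lm: LabelMask,
                          per_task_mean: bool = False) -> nn.Tensor:
    """Binary cross-entropy with logits, averaged over observed entries only.

    Entries whose label is missing contribute neither loss nor gradient; a
    batch with no observed entry has loss exactly 0.  ``per_task_mean``
    switches to the mean-of-per-task-means variant.
    """
    obs = lm.observed.astype(nn.DTYPE)
    n_obs = float(obs.sum())
    if n_obs == 0:
        return nn._wrap(np.asarray(0.0, dtype=nn.DTYPE))
    y = nn._wrap((lm.targets * lm.observed).astype(nn.DTYPE))
    # stable BCE-with-logits: max(z,0) − z·y + log(1 + exp(−|z|))
    elem = nn.add(nn.add(nn.relu(logits), -nn.mul(logits, y)),
                  nn.softplus(-nn.add(nn.relu(logits), nn.relu(-logits))))
    elem = nn.mul(elem, nn._wrap(obs))
    if per_task_mean:
        per_task_n = np.maximum(obs.sum(axis=0), 1.0)
        task_means = nn.mul(nn.tsum(elem, axis=0),
                            nn._wrap((1.0 / per_task_n).astype(nn.DTYPE)))
        n_tasks_obs = float((obs.sum(axis=0) > 0).sum())
        return nn.mul(nn.tsum(task_means),
                      nn._wrap(np.asarray(1.0 / n_tasks_obs, dtype=nn.DTYPE)))
    return nn.mul(nn.tsum(elem), nn._wrap(np.asarray(1.0 / n_obs, dtype=nn.DTYPE)))


# ---------------------------------------------------------------------------
# Featurization caches
# ---------------------------------------------------------------------------


class FeaturizedDataset:
    """Per-record deterministic features computed once and reused each epoch.

    Images are cached as raw uint8 rasters; augmentation + normalization is
    applied per epoch at batch-assembly time.
    """

    def __init__(self, records: list[MoleculeRecord], vocab: dict[str, int],
                 grid: SpectrumBinning | None = None,
                 need: tuple[str, ...] = MODALITIES):
        self.records = records
        self.vocab = vocab
        self.grid = grid or SpectrumBinning()
        self.need = need
        self.graphs = [featurize_graph(r.mol) for r in records] if "graph" in need else None
        self.tokens = [tokenize_smiles(r.smiles, vocab) for r in records] if "smiles" in need else None
        self.rasters = None
        if "image" in need:
            self.rasters = []
            for r in records:
                if r.image_path is not None:
                    from PIL import Image
                    self.rasters.append(
                        np.asarray(Image.open(r.image_path).convert("RGB"), dtype=np.uint8))
                else:
                    self.rasters.append(render_image(r.mol))
        self.spectra = None
        if "spectrum" in need:
            self.spectra = [
                bin_spectrum(r.peaks, self.grid) if r.has_spectrum else None
                for r in records
            ]
        self.labels = np.stack([r.labels for r in records])
        self.spectrum_present = np.array([r.has_spectrum for r in records])

    def __len__(self):
        return len(self.records)

    def image_batch(self, idx, augment: bool, rng) -> np.ndarray:
        return np.stack([
            normalize_image(self.rasters[i], augment=augment, rng=rng) for i in idx
        ])

    def spectrum_batch(self, idx) -> np.ndarray:
        rows = [self.spectra[i] for i in idx]
        if any(r is None for r in rows):
            raise ValueError("spectrum batch contains spectrum-absent records")
        return np.stack(rows)


def encoder_forward(encoder, modality: str, ds: FeaturizedDataset, idx,
                    rng=None, augment: bool = False) -> nn.Tensor:
    if modality == "graph":
        return encoder.encode([ds.graphs[i] for i in idx], rng)
    if modality == "smiles":
        return encoder.encode([ds.tokens[i] for i in idx], rng)
    if modality == "image":
        return encoder.encode(ds.image_batch(idx, augment, rng), rng)
    if modality == "spectrum":
        return encoder.encode(ds.spectrum_batch(idx), rng)
    raise ValueError(f"unknown modality {modality!r}")


def build_encoder(modality: str, cfg=None, seed: int = 0, vocab_size: int | None = None):
    if modality == "graph":
        return GraphEncoder(cfg or GraphEncoderConfig(), seed)
    if modality == "smiles":
        cfg = cfg or SmilesEncoderConfig()
        if vocab_size is not None:
            cfg = replace(cfg, vocab_size=vocab_size)
        return SmilesEncoder(cfg, seed)
    if modality == "image":
        return ImageEncoder(cfg or ImageEncoderConfig(), seed)
    if modality == "spectrum":
        return SpectrumEncoder(cfg or SpectrumEncoderConfig(), seed)
    raise ValueError(f"unknown modality {modality!r}")


# ---------------------------------------------------------------------------
# Phase 1: encoder training (with a linear probe head)
# ---------------------------------------------------------------------------


class ProbedEncoder(nn.Module):
    """Encoder + 12-task linear probe, optimized jointly; the probe also
    serves as the single-modality baseline predictor."""

    def __init__(self, encoder, modality: str, seed: int = 0):
        super().__init__()
        rng = np.random.Generator(np.random.PCG64(seed + 101))
        self.encoder = encoder
        self.modality = modality
        self.probe = nn.Linear(encoder.output_dim, N_TASKS, rng)

    def logits(self, ds: FeaturizedDataset, idx, rng=None, augment=False) -> nn.Tensor:
        emb = encoder_forward(self.encoder, self.modality, ds, idx, rng, augment)
        return self.probe(emb)


def _epoch_batches(n: int, batch_size: int, rng) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


def _eval_scores(model: ProbedEncoder, ds: FeaturizedDataset, idx,
                 batch_size: int = 128) -> np.ndarray:
    model.eval()
    outs = []
    with nn.no_grad():
        for i in range(0, len(idx), batch_size):
            logits = model.logits(ds, idx[i:i + batch_size])
            outs.append(expit(logits.data.astype(np.float64)))
    model.train()
    return np.concatenate(outs, axis=0)


def train_encoder(modality: str, ds: FeaturizedDataset,
                  train_idx: np.ndarray, valid_idx: np.ndarray,
                  enc_cfg=None, cfg: TrainConfig | None = None) -> tuple:
    """Train one modality encoder with a joint linear probe.

    For the spectrum modality the index sets are automatically restricted to
    spectrum-present records.  Early stopping monitors validation macro
    ROC-AUC over endpoints with both classes present (single-class endpoints
    are skipped and logged); the best epoch's weights are restored.

    Returns ``(probed_encoder, log)`` where ``log`` is a per-epoch DataFrame
    with columns epoch/train_loss/valid_auc/best_auc.
    """
    cfg = cfg or TrainConfig()
    if modality == "spectrum":
        train_idx = np.asarray([i for i in train_idx if ds.spectrum_present[i]])
        valid_idx = np.asarray([i for i in valid_idx if ds.spectrum_present[i]])
        if len(train_idx) == 0:
            raise ValueError("no spectrum-present records in the training split")
    train_idx = np.asarray(train_idx)
    valid_idx = np.asarray(valid_idx)

    encoder = build_encoder(modality, enc_cfg, cfg.seed,
                            vocab_size=len(ds.vocab))
    model = ProbedEncoder(encoder, modality, cfg.seed)
    opt = nn.Adam(model.trainable_parameters(), lr=cfg.lr,
                  weight_decay=cfg.weight_decay)
    rng = np.random.Generator(np.random.PCG64(cfg.seed))

    best_auc, best_state, best_epoch, log = -np.inf, None, -1, []
    since_best = 0
    for epoch in range(cfg.max_epochs):
        model.train()
        losses = []
        for idx in _epoch_batches(len(train_idx), cfg.batch_size, rng):
            batch = train_idx[idx]
            augment = cfg.augment_images and modality == "image"
            logits = model.logits(ds, batch, rng, augment=augment)
            loss = masked_multitask_loss(
                logits, LabelMask.from_labels(ds.labels[batch]), cfg.per_task_mean)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        scores = _eval_scores(model, ds, valid_idx)
        vauc = macro_roc_auc(scores, ds.labels[valid_idx])
        if vauc is not None and vauc > best_auc:
            best_auc, best_epoch, since_best = vauc, epoch, 0
            best_state = model.state_dict()
        else:
            since_best += 1
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                    "valid_auc": np.nan if vauc is None else vauc,
                    "best_auc": best_auc if np.isfinite(best_auc) else np.nan})
        if since_best > cfg.patience:
            logger.info("%s encoder: early stop at epoch %d (best %d)",
                        modality, epoch, best_epoch)
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, pd.DataFrame(log)


# ---------------------------------------------------------------------------
# Phase 2: fusion training with frozen encoders
# ---------------------------------------------------------------------------


def precompute_embeddings(encoders: dict[str, ProbedEncoder],
                          ds: FeaturizedDataset, idx: np.ndarray,
                          batch_size: int = 128) -> dict[str, np.ndarray]:
    """Eval-mode embeddings from frozen encoders, computed once.

    Spectrum embeddings are computed only for spectrum-present rows; absent
    rows carry zeros (never consumed — the fusion missing token replaces
    them)."""
    idx = np.asarray(idx)
    out: dict[str, np.ndarray] = {}
    for m, probed in encoders.items():
        enc = probed.encoder
        enc.eval()
        rows = np.zeros((len(idx), enc.output_dim), dtype=nn.DTYPE)
        if m == "spectrum":
            sub = np.where(ds.spectrum_present[idx])[0]
            src_idx = idx[sub]
        else:
            sub = np.arange(len(idx))
            src_idx = idx
        with nn.no_grad():
            for i in range(0, len(src_idx), batch_size):
                emb = encoder_forward(enc, m, ds, src_idx[i:i + batch_size])
                rows[sub[i:i + batch_size]] = emb.data
        out[m] = rows
    return out


def train_fusion(encoders: dict[str, ProbedEncoder], ds: FeaturizedDataset,
                 train_idx: np.ndarray, valid_idx: np.ndarray,
                 fusion_cfg: FusionConfig | None = None,
                 cfg: TrainConfig | None = None) -> tuple:
    """Train the fusion network (and missing token) on frozen encoders.

    Encoders are frozen for the whole phase; only fusion parameters receive
    gradient.  Supports any non-empty modality subset via
    ``fusion_cfg.active_modalities`` (the ablation harness).  Returns
    ``(fusion_model, log)``.
    """
    cfg = cfg or fusion_train_config()
    fusion_cfg = fusion_cfg or FusionConfig(
        active_modalities=tuple(encoders.keys()))
    active = fusion_cfg.active_modalities
    missing = set(active) - set(encoders)
    if missing:
        raise ValueError(f"no trained encoder for: {sorted(missing)}")
    for m in active:
        encoders[m].encoder.freeze()
        encoders[m].encoder.eval()

    train_idx, valid_idx = np.asarray(train_idx), np.asarray(valid_idx)
    subset = {m: encoders[m] for m in active}
    emb_train = precompute_embeddings(subset, ds, train_idx)
    emb_valid = precompute_embeddings(subset, ds, valid_idx)
    input_dims = {m: subset[m].encoder.output_dim for m in active}

    model = FusionModel(input_dims, fusion_cfg, cfg.seed)
    opt = nn.Adam(model.trainable_parameters(), lr=cfg.lr,
                  weight_decay=cfg.weight_decay)
    rng = np.random.Generator(np.random.PCG64(cfg.seed + 7))

    def forward(embs, present, rows, rng=None):
        bundle = ModalityBundle(
            {m: embs[m][rows] for m in active},
            spectrum_present=present[rows] if "spectrum" in active else None,
        )
        return model(bundle, rng)

    present_train = ds.spectrum_present[train_idx]
    present_valid = ds.spectrum_present[valid_idx]
    best_auc, best_state, best_epoch, log = -np.inf, None, -1, []
    since_best = 0
    for epoch in range(cfg.max_epochs):
        model.train()
        losses = []
        for rows in _epoch_batches(len(train_idx), cfg.batch_size, rng):
            out = forward(emb_train, present_train, rows, rng)
            loss = masked_multitask_loss(
                out.logits, LabelMask.from_labels(ds.labels[train_idx[rows]]),
                cfg.per_task_mean)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        model.eval()
        with nn.no_grad():
            out = forward(emb_valid, present_valid, np.arange(len(valid_idx)))
            scores = expit(out.logits.data.astype(np.float64))
        vauc = macro_roc_auc(scores, ds.labels[valid_idx])
        if vauc is not None and vauc > best_auc:
            best_auc, best_epoch, since_best = vauc, epoch, 0
            best_state = model.state_dict()
        else:
            since_best += 1
        log.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                    "valid_auc": np.nan if vauc is None else vauc,
                    "best_auc": best_auc if np.isfinite(best_auc) else np.nan})
        if since_best > cfg.patience:
            logger.info("fusion: early stop at epoch %d (best %d)", epoch, best_epoch)
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, pd.DataFrame(log)


def fusion_scores(model: FusionModel, encoders: dict[str, ProbedEncoder],
                  ds: FeaturizedDataset, idx: np.ndarray):
    """Sigmoid endpoint scores and attention maps for a held-out index set."""
    idx = np.asarray(idx)
    active = model.cfg.active_modalities
    embs = precompute_embeddings({m: encoders[m] for m in active}, ds, idx)
    model.eval()
    with nn.no_grad():
        bundle = ModalityBundle(
            {m: embs[m] for m in active},
            spectrum_present=ds.spectrum_present[idx] if "spectrum" in active else None,
        )
        out = model(bundle)
    scores = expit(out.logits.data.astype(np.float64))
    return scores, out.attention


# ---------------------------------------------------------------------------
# Hyperparameter search (seeded random search)
# ---------------------------------------------------------------------------


def hyperparameter_search(space: dict, budget: int, seed: int,
                          eval_fn) -> tuple[dict, pd.DataFrame]:
    """Seeded random search over a finite space description.

    ``space`` maps parameter name → list of candidate values; ``eval_fn``
    maps a sampled config dict → validation macro AUC.  Returns the best
    config and a record of all trials.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    trials = []
    best_cfg, best_score = None, -np.inf
    for t in range(budget):
        cand = {k: v[rng.integers(len(v))] for k, v in space.items()}
        score = eval_fn(cand)
        trials.append({**cand, "trial": t, "score": score})
        if score > best_score:
            best_cfg, best_score = cand, score
    return best_cfg, pd.DataFrame(trials)
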