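"""Attention-based fusion of modality embeddings with a learnable
missing-spectrum token, ending in a 12-endpoint multi-task head.

Each active modality embedding is mapped by its own linear layer + ReLU into a
common dimension ``d_e``; the resulting M tokens (fixed order: graph, smiles,
image, spectrum) pass through one shared multi-head self-attention layer,

    Z = MultiHead(X, X, X),      fused = (1/M) Σ_m Z_m,

and the mean-pooled fused vector feeds a Linear→ReLU→Dropout block followed by
an MLP head producing one logit per endpoint.  Compounds without a spectrum
substitute a trainable token — initialized to zeros, with the dimension of the
spectrum embedding — *before* the shared spectrum projection, so the
projection weights are shared between the real and missing paths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .encoders import MODALITIES

logger = logging.getLogger(__name__)


@dataclass
class FusionConfig:
    common_dim: int = 256
    n_heads: int = 4
    dropout: float = 0.1
    n_tasks: int = 12
    active_modalities: tuple[str, ...] = MODALITIES
    #: residual + pre-norm around the attention layer (off: plain MultiHead)
    residual_attention: bool = False

    def __post_init__(self):
        if self.common_dim % self.n_heads:
            raise ValueError("common_dim must be divisible by n_heads")
        if not self.active_modalities:
            raise ValueError("active_modalities must be non-empty")
        bad = set(self.active_modalities) - set(MODALITIES)
        if bad:
            raise ValueError(f"unknown modalities: {sorted(bad)}")
        # keep canonical token order regardless of input order
        self.active_modalities = tuple(
            m for m in MODALITIES if m in self.active_modalities
        )


@dataclass
class ModalityBundle:
    """Per-batch encoded inputs: modality → (B, d_m) arrays or Tensors, plus a
    per-sample spectrum-presence flag.  Graph/SMILES/image are always present
    in the default benchmark; absent modality slots are simply unused."""

    embeddings: dict
    spectrum_present: np.ndarray | None = None  # (B,) bool; None = all present


@dataclass
class FusionOutput:
    logits: nn.Tensor  # (B, n_tasks)
    attention: np.ndarray  # (B, heads, M, M) row-stochastic
    fused: nn.Tensor  # (B, d_e)


class FusionModel(nn.Module):
    def __init__(self, input_dims: dict[str, int], cfg: FusionConfig, seed: int = 0):
        super().__init__()
        rng = np.random.Generator(np.random.PCG64(seed))
        self.cfg = cfg
        self.proj = {}
        for m in cfg.active_modalities:
            self.proj[m] = nn.Linear(input_dims[m], cfg.common_dim, rng)
        # registered as attributes so parameter traversal sees them
        for m, lin in self.proj.items():
            setattr(self, f"proj_{m}", lin)
        if "spectrum" in cfg.active_modalities:
            self.missing_token = nn.Parameter(np.zeros(input_dims["spectrum"]))
        d = cfg.common_dim
        self.attn = nn.MultiHeadSelfAttention(d, cfg.n_heads, rng)
        self.ln = nn.LayerNorm(d) if cfg.residual_attention else None
        self.fc1 = nn.Linear(d, d, rng)
        self.drop = nn.Dropout(cfg.dropout)
        self.fc2 = nn.Linear(d, d // 2, rng)
        self.out = nn.Linear(d // 2, cfg.n_tasks, rng)

    # -- stages -------------------------------------------------------------
    def project_modalities(self, bundle: ModalityBundle) -> nn.Tensor:
        """Stack per-modality projected tokens into a (B, M, d_e) tensor.

        For spectrum-absent samples the learnable missing token replaces the
        (ignored) spectrum embedding before the shared projection."""
        active = self.cfg.active_modalities
        extra = set(bundle.embeddings) - set(active)
        if extra:
            logger.debug("ignoring inactive modalities supplied: %s", sorted(extra))
        some = next(iter(bundle.embeddings.values()))
        batch = some.shape[0]
        rows = []
        for m in active:
            if m == "spectrum":
                rows.append(self._spectrum_tokens(bundle, batch))
                continue
            emb = bundle.embeddings[m]
            emb = emb if isinstance(emb, nn.Tensor) else nn._wrap(np.asarray(emb, dtype=nn.DTYPE))
            rows.append(nn.relu(self.proj[m](emb)))
        return nn.stack(rows, axis=1)  # (B, M, d_e)

    def _spectrum_tokens(self, bundle: ModalityBundle, batch: int) -> nn.Tensor:
        present = bundle.spectrum_present
        if present is None:
            present = np.ones(batch, dtype=bool)
        present = np.asarray(present, dtype=bool)
        if present.all():
            emb = bundle.embeddings["spectrum"]
            emb = emb if isinstance(emb, nn.Tensor) else nn._wrap(np.asarray(emb, dtype=nn.DTYPE))
            return nn.relu(self.proj["spectrum"](emb))
        token = nn.reshape(self.missing_token, (1, -1))
        if not present.any():
            tiled = nn.mul(token, nn._wrap(np.ones((batch, 1), dtype=nn.DTYPE)))
            return nn.relu(self.proj["spectrum"](tiled))
        # mixed batch: scatter real embeddings and the missing token by mask.
        emb = bundle.embeddings["spectrum"]
        emb = emb if isinstance(emb, nn.Tensor) else nn._wrap(np.asarray(emb, dtype=nn.DTYPE))
        if emb.shape[0] == batch:
            real = emb
        else:  # compact storage: one row per spectrum-present sample
            expand = np.zeros((batch, emb.shape[0]), dtype=nn.DTYPE)
            expand[np.where(present)[0], np.arange(emb.shape[0])] = 1.0
            real = nn.matmul(nn._wrap(expand), emb)
        pmask = nn._wrap(present[:, None].astype(nn.DTYPE))
        amask = nn._wrap((~present)[:, None].astype(nn.DTYPE))
        mixed = nn.add(nn.mul(real, pmask),
                       nn.mul(nn.mul(token, nn._wrap(np.ones((batch, 1), dtype=nn.DTYPE))), amask))
        return nn.relu(self.proj["spectrum"](mixed))

    def attention_fuse(self, tokens: nn.Tensor):
        """Shared multi-head self-attention over the M modality tokens, then
        mean pooling: fused = mean over tokens of the attended rows."""
        x = self.ln(tokens) if self.ln is not None else tokens
        z, attn = self.attn(x)
        if self.cfg.residual_attention:
            z = nn.add(tokens, z)
        fused = nn.tmean(z, axis=1)
        return fused, attn

    def predict(self, fused: nn.Tensor, rng=None) -> nn.Tensor:
        """Linear → ReLU → Dropout, then the final MLP head → 12 logits
        (sigmoid is applied only at metric time)."""
        h = self.drop(nn.relu(self.fc1(fused)), rng)
        h = nn.relu(self.fc2(h))
        return self.out(h)

    def __call__(self, bundle: ModalityBundle, rng=None) -> FusionOutput:
        tokens = self.project_modalities(bundle)
        fused, attn = self.attention_fuse(tokens)
        return FusionOutput(self.predict(fused, rng), attn, fused)


# ---------------------------------------------------------------------------
# Attention reporting
# ---------------------------------------------------------------------------


def extract_attention_summary(attention_batches, active_modalities,
                              split_seed=None) -> pd.DataFrame:
    """Average attention maps over samples and heads.

    ``attention_batches``: iterable of (B, heads, M, M) arrays from evaluated
    batches.  Returns a long-format frame (query_modality, key_modality,
    mean_weight[, split_seed]); rows are query modalities, columns keys."""
    maps = [np.asarray(a, dtype=np.float64) for a in attention_batches]
    if not maps or sum(a.shape[0] for a in maps) == 0:
        raise ValueError("no evaluated batches")
    total = sum(a.sum(axis=(0, 1)) for a in maps)
    count = sum(a.shape[0] * a.shape[1] for a in maps)
    mean_map = total / count  # (M, M)
    rows = []
    for qi, qm in enumerate(active_modalities):
        for ki, km in enumerate(active_modalities):
            row = {"query_modality": qm, "key_modality": km,
                   "mean_weight": mean_map[qi, ki]}
            if split_seed is not None:
                row["split_seed"] = split_seed
            rows.append(row)
    return pd.DataFrame(rows)


def mean_received_attention(summary: pd.DataFrame) -> pd.Series:
    """Per-modality mean attention received (average over query rows)."""
    return summary.groupby("key_modality", sort=False)["mean_weight"].mean()
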