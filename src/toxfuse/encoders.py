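"""Trainable modality encoders: graph GINE stack, SMILES transformer,
2-D image CNN, and 1-D spectrum CNN, each ending in a projection head.

All four are trained from scratch at small scale; ``load_backbone_weights``
accepts externally produced checkpoints (npz of the backbone state dict) but
that hook is outside the tested surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .chem_io import NODE_DIM, GraphFeatures, TokenSequence

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


@dataclass
class EncoderConfig:
    hidden_dim: int = 128
    n_layers: int = 5
    output_dim: int = 128
    dropout: float = 0.1
    backbone_frozen: bool = False


@dataclass
class GraphEncoderConfig(EncoderConfig):
    pass


@dataclass
class SmilesEncoderConfig(EncoderConfig):
    n_layers: int = 4
    n_heads: int = 4
    ffn_dim: int | None = None  # default 2×hidden
    vocab_size: int = 64
    max_len: int = 202


@dataclass
class ImageEncoderConfig(EncoderConfig):
    widths: tuple[int, ...] = (32, 64, 128)
    backbone_dim: int = 512  # feature size after global average pooling
    stem_pool: int = 4


@dataclass
class SpectrumEncoderConfig(EncoderConfig):
    conv_widths: tuple[int, ...] = (32, 64, 128)
    kernel: int = 5
    backbone_dim: int = 768
    n_bins: int = 260


# ---------------------------------------------------------------------------
# Shared pieces
# ---------------------------------------------------------------------------


class TwoLayerMLP(nn.Module):
    def __init__(self, in_dim: int, hidden: int, out_dim: int, rng):
        super().__init__()
        self.fc1 = nn.Linear(in_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, out_dim, rng)

    def __call__(self, x):
        return self.fc2(nn.relu(self.fc1(x)))


class ProjectionHead(nn.Module):
    """Two-stage projection: Linear → (activation/dropout) → Linear.

    ``gelu_after_dropout=True`` gives the dropout-then-GELU ordering used by
    the SMILES branch; the default is ReLU-then-dropout.
    """

    def __init__(self, in_dim: int, hidden: int, out_dim: int, dropout: float,
                 rng, gelu_after_dropout: bool = False):
        super().__init__()
        self.fc1 = nn.Linear(in_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, out_dim, rng)
        self.drop = nn.Dropout(dropout)
        self.gelu_after_dropout = gelu_after_dropout

    def __call__(self, x, rng=None):
        h = self.fc1(x)
        if self.gelu_after_dropout:
            h = nn.gelu(self.drop(h, rng))
        else:
            h = self.drop(nn.relu(h), rng)
        return self.fc2(h)


def _np_rng(seed: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed))


# ---------------------------------------------------------------------------
# Graph branch (edge-aware GIN)
# ---------------------------------------------------------------------------


def gine_layer(x: nn.Tensor, edge_index: np.ndarray, edge_attr: nn.Tensor,
               eps, mlp) -> nn.Tensor:
    """One round of edge-aware GIN message passing.

    For every node v:  ``out_v = MLP((1 + ε)·x_v + Σ_{u∈N(v)} ReLU(x_u + e_uv))``
    where the sum runs over incoming directed edges.  ``edge_attr`` must
    already live in the node feature dimension.  Isolated nodes receive an
    empty (zero) neighbour sum.
    """
    n = x.shape[0]
    if edge_attr.shape[0] != edge_index.shape[1]:
        raise ValueError("edge_attr rows must match number of directed edges")
    if edge_index.shape[1] > 0:
        src = edge_index[0].astype(np.int64)
        dst = edge_index[1].astype(np.int64)
        msg = nn.relu(nn.add(x[src], edge_attr))
        agg = nn.segment_sum(msg, dst, n)
    else:
        agg = nn._wrap(np.zeros_like(x.data))
    one_plus_eps = nn.add(nn._wrap(np.asarray(1.0, dtype=nn.DTYPE)), eps) \
        if isinstance(eps, nn.Tensor) else nn._wrap(np.asarray(1.0 + eps, dtype=nn.DTYPE))
    return mlp(nn.add(nn.mul(x, one_plus_eps), agg))


def batch_graphs(graphs: list[GraphFeatures]):
    """Concatenate graphs block-diagonally: node matrix, offset edge index,
    edge attributes, and a per-node graph-id vector."""
    xs, eis, eas, batch = [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        n = g.node_features.shape[0]
        xs.append(g.node_features)
        eis.append(g.edge_index + offset)
        eas.append(g.edge_attr)
        batch.append(np.full(n, gi, dtype=np.int64))
        offset += n
    x = np.concatenate(xs, axis=0).astype(nn.DTYPE)
    ei = np.concatenate(eis, axis=1) if eis else np.zeros((2, 0), np.int64)
    ea = np.concatenate(eas, axis=0).astype(nn.DTYPE)
    return x, ei, ea, np.concatenate(batch)


class GraphEncoder(nn.Module):
    """L stacked GINE layers (each: message passing → 2-layer MLP → batchnorm
    → ReLU → dropout), global sum pooling, then a projection head."""

    def __init__(self, cfg: GraphEncoderConfig, seed: int = 0):
        super().__init__()
        rng = _np_rng(seed)
        h = cfg.hidden_dim
        self.cfg = cfg
        self.edge_lins, self.mlps, self.bns, self.drops, self.eps = [], [], [], [], []
        in_dim = NODE_DIM
        for _ in range(cfg.n_layers):
            self.edge_lins.append(nn.Linear(4, in_dim, rng))
            self.mlps.append(TwoLayerMLP(in_dim, h, h, rng))
            self.bns.append(nn.BatchNorm(h, axes=(0,)))
            self.drops.append(nn.Dropout(cfg.dropout))
            self.eps.append(nn.Parameter(np.zeros(())))  # ε learnable, init 0
            in_dim = h
        self.head = ProjectionHead(h, h, cfg.output_dim, cfg.dropout, rng)

    @property
    def output_dim(self) -> int:
        return self.cfg.output_dim

    def node_states(self, x_np, edge_index, edge_attr_np, rng=None) -> nn.Tensor:
        x = nn._wrap(x_np)
        ea = nn._wrap(edge_attr_np)
        for lin_e, mlp, bn, drop, eps in zip(
            self.edge_lins, self.mlps, self.bns, self.drops, self.eps
        ):
            e = lin_e(ea)
            x = gine_layer(x, edge_index, e, eps, mlp)
            x = drop(nn.relu(bn(x)), rng)
        return x

    def pooled(self, graphs: list[GraphFeatures], rng=None) -> nn.Tensor:
        x_np, ei, ea, batch = batch_graphs(graphs)
        states = self.node_states(x_np, ei, ea, rng)
        return nn.segment_sum(states, batch, len(graphs))

    def encode(self, graphs: list[GraphFeatures], rng=None) -> nn.Tensor:
        return self.head(self.pooled(graphs, rng), rng)

    def load_backbone_weights(self, path) -> None:  # untested external hook
        _load_partial(self, path)


# ---------------------------------------------------------------------------
# SMILES branch (small transformer)
# ---------------------------------------------------------------------------


class TransformerBlock(nn.Module):
    def __init__(self, dim: int, n_heads: int, ffn_dim: int, dropout: float, rng):
        super().__init__()
        self.ln1 = nn.LayerNorm(dim)
        self.attn = nn.MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln2 = nn.LayerNorm(dim)
        self.ffn1 = nn.Linear(dim, ffn_dim, rng)
        self.ffn2 = nn.Linear(ffn_dim, dim, rng)
        self.drop = nn.Dropout(dropout)

    def __call__(self, x, key_mask, rng=None):
        a, _ = self.attn(self.ln1(x), key_mask)
        x = nn.add(x, self.drop(a, rng))
        f = self.ffn2(nn.gelu(self.ffn1(self.ln2(x))))
        return nn.add(x, self.drop(f, rng))


class SmilesEncoder(nn.Module):
    """Token embedding + sinusoidal positions → pre-norm transformer blocks
    with attention restricted to real tokens → masked mean pooling → two-stage
    projection head (linear, dropout, GELU, linear)."""

    def __init__(self, cfg: SmilesEncoderConfig, seed: int = 0):
        super().__init__()
        rng = _np_rng(seed)
        h = cfg.hidden_dim
        self.cfg = cfg
        self.embed = nn.Embedding(cfg.vocab_size, h, rng)
        self.pe = nn.sinusoidal_position_encoding(cfg.max_len, h)
        ffn = cfg.ffn_dim or 2 * h
        self.blocks = [
            TransformerBlock(h, cfg.n_heads, ffn, cfg.dropout, rng)
            for _ in range(cfg.n_layers)
        ]
        self.head = ProjectionHead(h, h, cfg.output_dim, cfg.dropout, rng,
                                   gelu_after_dropout=True)

    @property
    def output_dim(self) -> int:
        return self.cfg.output_dim

    def encode(self, seqs: list[TokenSequence], rng=None) -> nn.Tensor:
        ids = np.stack([s.ids for s in seqs])
        mask = np.stack([s.mask for s in seqs])
        counts = mask.sum(axis=1)
        if np.any(counts == 0):
            raise ValueError("all-pad token sequence")
        tmax = int(counts.max())  # pads beyond the longest real prefix are inert
        ids, mask = ids[:, :tmax], mask[:, :tmax]
        x = nn.add(self.embed(ids), nn._wrap(self.pe[:tmax][None, :, :]))
        for blk in self.blocks:
            x = blk(x, mask, rng)
        m = mask[:, :, None].astype(nn.DTYPE)
        summed = nn.tsum(nn.mul(x, nn._wrap(m)), axis=1)
        pooled = nn.mul(summed, nn._wrap((1.0 / counts)[:, None].astype(nn.DTYPE)))
        return self.head(pooled, rng)

    def load_backbone_weights(self, path) -> None:  # untested external hook
        _load_partial(self, path)


# ---------------------------------------------------------------------------
# Image branch (small residual CNN)
# ---------------------------------------------------------------------------


class ImageBackbone(nn.Module):
    def __init__(self, cfg: ImageEncoderConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.convs, self.bns = [], []
        cin = 3
        for w in cfg.widths:
            self.convs.append(nn.Conv2d(cin, w, 3, rng))
            self.bns.append(nn.BatchNorm(w, axes=(0, 2, 3)))
            cin = w
        # one residual 3×3 block at the last stage width
        self.res_conv = nn.Conv2d(cin, cin, 3, rng)
        self.res_bn = nn.BatchNorm(cin, axes=(0, 2, 3))
        self.out_conv = nn.Conv2d(cin, cfg.backbone_dim, 1, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        x = nn.avg_pool2d(x, self.cfg.stem_pool)
        for conv, bn in zip(self.convs, self.bns):
            x = nn.avg_pool2d(nn.relu(bn(conv(x))), 2)
        x = nn.relu(nn.add(x, self.res_bn(self.res_conv(x))))
        x = self.out_conv(x)
        return nn.tmean(x, axis=(2, 3))  # (B, backbone_dim)


class ImageEncoder(nn.Module):
    """Residual CNN backbone with global average pooling to a 512-dim feature
    vector, refined by a two-layer projection head."""

    def __init__(self, cfg: ImageEncoderConfig, seed: int = 0):
        super().__init__()
        rng = _np_rng(seed)
        self.cfg = cfg
        self.backbone = ImageBackbone(cfg, rng)
        self.head = ProjectionHead(cfg.backbone_dim, cfg.backbone_dim,
                                   cfg.output_dim, cfg.dropout, rng)
        if cfg.backbone_frozen:
            self.backbone.freeze()

    @property
    def output_dim(self) -> int:
        return self.cfg.output_dim

    def encode(self, images: np.ndarray, rng=None) -> nn.Tensor:
        """images: (B, 3, 224, 224) normalized tensors."""
        if images.ndim != 4 or images.shape[1] != 3:
            raise ValueError(f"expected (B,3,H,W) image batch, got {images.shape}")
        feats = self.backbone(nn._wrap(images.astype(nn.DTYPE)))
        return self.head(feats, rng)

    def load_backbone_weights(self, path) -> None:  # untested external hook
        _load_partial(self.backbone, path)


# ---------------------------------------------------------------------------
# Spectrum branch (1-D CNN over peak bits)
# ---------------------------------------------------------------------------


class SpectrumBackbone(nn.Module):
    """Conv blocks over the peak-bit vector with a position-aware input.

    Global average pooling makes a plain conv stack translation-invariant,
    which would erase the chemical-shift position of a peak — the very signal
    a binned spectrum carries.  The input therefore gets two channels: the
    raw bits and bits × normalized bin position, so pooled features can
    depend on where along the ppm axis peaks occur.
    """

    def __init__(self, cfg: SpectrumEncoderConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.ramp = (np.arange(cfg.n_bins, dtype=nn.DTYPE) / (cfg.n_bins - 1))
        self.convs, self.bns, self.pools = [], [], []
        cin, length = 2, cfg.n_bins
        for w in cfg.conv_widths:
            self.convs.append(nn.Conv1d(cin, w, cfg.kernel, rng))
            self.bns.append(nn.BatchNorm(w, axes=(0, 2)))
            self.pools.append(2 if length % 2 == 0 else 1)
            length //= self.pools[-1]
            cin = w
        self.out = nn.Linear(cin, cfg.backbone_dim, rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        for conv, bn, pool in zip(self.convs, self.bns, self.pools):
            x = nn.relu(bn(conv(x)))
            if pool > 1:
                x = nn.avg_pool1d(x, pool)
        pooled = nn.tmean(x, axis=2)  # (B, C)
        return self.out(pooled)  # (B, backbone_dim)


class SpectrumEncoder(nn.Module):
    """Stacked conv→ReLU→pool blocks over the binary peak vector, global
    pooling to a 768-dim backbone feature, then a projection head.  With a
    frozen backbone only the head receives gradient."""

    def __init__(self, cfg: SpectrumEncoderConfig, seed: int = 0):
        super().__init__()
        rng = _np_rng(seed)
        self.cfg = cfg
        self.backbone = SpectrumBackbone(cfg, rng)
        self.head = ProjectionHead(cfg.backbone_dim, cfg.backbone_dim,
                                   cfg.output_dim, cfg.dropout, rng)
        if cfg.backbone_frozen:
            self.backbone.freeze()

    @property
    def output_dim(self) -> int:
        return self.cfg.output_dim

    def encode(self, bits: np.ndarray, rng=None) -> nn.Tensor:
        """bits: (B, n_bins) binary spectrum vectors."""
        if bits.ndim != 2 or bits.shape[1] != self.cfg.n_bins:
            raise ValueError(
                f"expected (B,{self.cfg.n_bins}) spectrum batch, got {bits.shape}"
            )
        raw = bits.astype(nn.DTYPE)
        pos = raw * self.backbone.ramp[None, :].astype(raw.dtype)
        x = nn._wrap(np.stack([raw, pos], axis=1))
        feats = self.backbone(x)
        return self.head(feats, rng)

    def load_backbone_weights(self, path) -> None:  # untested external hook
        _load_partial(self.backbone, path)


# ---------------------------------------------------------------------------


def _load_partial(module: nn.Module, path) -> None:
    """Load whatever subset of a saved npz state dict matches this module."""
    data = np.load(path)
    state = {k: data[k] for k in data.files}
    own = dict(module.named_parameters())
    loaded = 0
    for k, v in state.items():
        if k in own and own[k].data.shape == v.shape:
            own[k].data = v.astype(own[k].data.dtype)
            loaded += 1
    logger.info("loaded %d/%d arrays from %s", loaded, len(state), path)


MODALITIES = ("graph", "smiles", "image", "spectrum")
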