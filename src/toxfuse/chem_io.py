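"""Compound I/O and deterministic per-modality featurization.

A compound enters the pipeline as a SMILES string plus a sparse 12-endpoint
label vector, optionally accompanied by a ¹³C NMR peak list (ppm) and/or a
pre-rendered 224×224 RGB depiction.  This module validates and canonicalizes
the chemistry and turns each record into the four fixed representations the
encoders consume:

* molecular graph  — 78-dim node features, directed edge list, bond one-hots;
* SMILES tokens    — regex tokenization, padded/truncated to 202 positions;
* 2-D image        — RDKit depiction, ImageNet-normalized channels-first tensor;
* spectrum vector  — binary peak-presence bits on a 1 ppm grid over [−20, 240).

All featurizers are deterministic; augmentation (image only) is driven by an
explicit RNG and reserved for training.
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from rdkit import Chem, RDLogger
from rdkit.Chem.Draw import rdMolDraw2D
from scipy import ndimage

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

MISSING = -1.0
N_TASKS = 12

#: default endpoint column order: 7 nuclear-receptor + 5 stress-response assays
ENDPOINTS = [
    "NR-AR", "NR-AR-LBD", "NR-AhR", "NR-Aromatase", "NR-ER", "NR-ER-LBD",
    "NR-PPAR-gamma", "SR-ARE", "SR-ATAD5", "SR-HSE", "SR-MMP", "SR-p53",
]

# 43-symbol atom vocabulary (DeepChem-style canonical list) + "other" slot.
ATOM_SYMBOLS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
]
HYBRIDIZATIONS = [
    Chem.HybridizationType.S,
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
    Chem.HybridizationType.UNSPECIFIED,
]
BOND_TYPES = [
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
]
NODE_DIM = len(ATOM_SYMBOLS) + 1 + 11 + 11 + len(HYBRIDIZATIONS) + 5  # = 78

MAX_TOKENS = 202
IMAGE_SIZE = 224
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float64)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float64)

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"

_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|se|@@|N|O|S|P|F|I|B|C|b|c|n|o|s|p"
    r"|\(|\)|\.|=|#|-|\+|\\|/|:|~|@|\?|>|\*|\$|%[0-9]{2}|[0-9])"
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GraphFeatures:
    """Molecular graph: node matrix (N×78), directed edges (2×2B), bond
    one-hots (2B×4).  Every undirected bond contributes the two directed
    edges adjacently in the edge list."""

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_attr: np.ndarray


@dataclass
class TokenSequence:
    """Padded/truncated SMILES token ids (202,) with a prefix-of-ones mask."""

    ids: np.ndarray
    mask: np.ndarray


@dataclass
class SpectrumBinning:
    """Uniform chemical-shift grid; default 1 ppm bins over [−20, 240)."""

    lo: float = -20.0
    hi: float = 240.0
    width: float = 1.0

    @property
    def n_bins(self) -> int:
        return int(round((self.hi - self.lo) / self.width))


@dataclass
class MoleculeRecord:
    """One compound with its labels and (optional) extra modalities."""

    id: str
    smiles: str
    labels: np.ndarray  # (12,) values in {0, 1, MISSING}
    peaks: list[float] | None = None
    image_path: Path | None = None
    mol: object = field(default=None, repr=False, compare=False)

    @property
    def has_spectrum(self) -> bool:
        return self.peaks is not None and len(self.peaks) > 0


@dataclass
class DatasetSummary:
    n_rows: int
    n_valid: int
    n_rejected: int
    n_with_spectrum: int

    @property
    def spectrum_fraction(self) -> float:
        return self.n_with_spectrum / max(self.n_valid, 1)


# ---------------------------------------------------------------------------
# Parsing and validation
# ---------------------------------------------------------------------------


def parse_and_validate(smiles: str):
    """Parse a SMILES string; return an RDKit molecule or ``None``.

    Invalid strings are rejected (returned as ``None``) rather than raising,
    so a corrupt row never aborts a batch; callers drop and log rejections.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumAtoms() == 0:
        return None
    return mol


# ---------------------------------------------------------------------------
# Graph featurization
# ---------------------------------------------------------------------------


def _one_hot(value, choices) -> list[float]:
    return [1.0 if value == c else 0.0 for c in choices]


def _atom_features(atom) -> list[float]:
    symbol = atom.GetSymbol()
    sym = _one_hot(symbol, ATOM_SYMBOLS)
    other = 0.0 if symbol in ATOM_SYMBOLS else 1.0
    if other:
        logger.debug("atom symbol %s outside vocabulary; using 'other' slot", symbol)
    degree = _one_hot(min(atom.GetDegree(), 10), list(range(11)))
    n_h = _one_hot(min(atom.GetTotalNumHs(), 10), list(range(11)))
    hyb = atom.GetHybridization()
    hyb_oh = _one_hot(hyb if hyb in HYBRIDIZATIONS else Chem.HybridizationType.UNSPECIFIED,
                      HYBRIDIZATIONS)
    chiral = 1.0 if atom.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED else 0.0
    return (
        sym + [other] + degree + n_h + hyb_oh
        + [float(atom.GetFormalCharge()), float(atom.GetNumRadicalElectrons()),
           float(atom.GetIsAromatic()), float(atom.IsInRing()), chiral]
    )


def featurize_graph(mol) -> GraphFeatures:
    """Build node/edge matrices for GINE message passing.

    Hydrogens stay implicit.  Each undirected bond becomes two directed edges
    (forward then backward, adjacent in the list) carrying the same bond-type
    one-hot over (single, double, triple, aromatic).  A bond outside that
    vocabulary signals corrupt input and raises.
    """
    n = mol.GetNumAtoms()
    x = np.array([_atom_features(a) for a in mol.GetAtoms()], dtype=np.float32)
    assert x.shape == (n, NODE_DIM)
    src, dst, attr = [], [], []
    for bond in mol.GetBonds():
        bt = bond.GetBondType()
        if bt not in BOND_TYPES:
            raise ValueError(f"unsupported bond type {bt} — corrupt input")
        oh = _one_hot(bt, BOND_TYPES)
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        src += [i, j]
        dst += [j, i]
        attr += [oh, oh]
    edge_index = np.array([src, dst], dtype=np.int64).reshape(2, -1)
    edge_attr = (np.array(attr, dtype=np.float32) if attr
                 else np.zeros((0, len(BOND_TYPES)), dtype=np.float32))
    return GraphFeatures(x, edge_index, edge_attr)


# ---------------------------------------------------------------------------
# SMILES tokenization
# ---------------------------------------------------------------------------


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into chemical tokens: bracket atoms and
    two-character elements (Cl, Br, Si, Se) stay single tokens."""
    return _SMILES_TOKEN_RE.findall(smiles)


def build_vocab(smiles_iter) -> dict[str, int]:
    """Token→id map from a corpus (training split); pad=0, unk=1."""
    vocab = {PAD_TOKEN: 0, UNK_TOKEN: 1}
    for smi in smiles_iter:
        for tok in tokenize(smi):
            if tok not in vocab:
                vocab[tok] = len(vocab)
    return vocab


def tokenize_smiles(smiles: str, vocab: dict[str, int],
                    max_len: int = MAX_TOKENS) -> TokenSequence:
    """Tokenize, map through the vocabulary, pad/truncate to ``max_len``."""
    toks = tokenize(smiles)[:max_len]
    unk = vocab[UNK_TOKEN]
    ids = np.full(max_len, vocab[PAD_TOKEN], dtype=np.int64)
    mask = np.zeros(max_len, dtype=np.int64)
    n_unk = 0
    for i, tok in enumerate(toks):
        tid = vocab.get(tok, unk)
        n_unk += tid == unk
        ids[i] = tid
        mask[i] = 1
    if n_unk:
        logger.debug("%d unknown tokens in %r", n_unk, smiles)
    return TokenSequence(ids, mask)


# ---------------------------------------------------------------------------
# Image rendering and normalization
# ---------------------------------------------------------------------------


def render_image(mol, cache_dir: Path | None = None,
                 record_id: str | None = None) -> np.ndarray:
    """Deterministic white-background 2-D depiction, (224, 224, 3) uint8.

    With a cache directory and record id, the PNG is written once and reused.
    """
    if cache_dir is not None and record_id is not None:
        path = Path(cache_dir) / f"{record_id}.png"
        if path.exists():
            return np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)
    drawer = rdMolDraw2D.MolDraw2DCairo(IMAGE_SIZE, IMAGE_SIZE)
    try:
        rdMolDraw2D.PrepareAndDrawMolecule(drawer, mol)
        drawer.FinishDrawing()
        png = drawer.GetDrawingText()
    except Exception as exc:  # depiction failure → caller rejects the record
        raise ValueError(f"depiction failed: {exc}") from exc
    img = Image.open(io.BytesIO(png)).convert("RGB")
    arr = np.asarray(img, dtype=np.uint8)
    if cache_dir is not None and record_id is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        (Path(cache_dir) / f"{record_id}.png").write_bytes(png)
    return arr


def normalize_image(raster: np.ndarray, augment: bool = False,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Scale to [0,1], optionally augment, then ImageNet-normalize.

    Augmentation (training only): horizontal flip p=0.5, rotation uniform in
    ±15° (bilinear, white fill), full grayscale p=0.2.  ``augment=False`` is
    the identity before normalization.  Output is channels-first float32
    (3, 224, 224): ``(pixel − mean_c) / std_c``.
    """
    x = np.asarray(raster, dtype=np.float64)
    if x.max() > 1.5:  # uint8 range
        x = x / 255.0
    if x.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
        raise ValueError(f"expected ({IMAGE_SIZE},{IMAGE_SIZE},3) raster, got {x.shape}")
    if augment:
        if rng is None:
            raise ValueError("augment=True requires an rng")
        if rng.random() < 0.5:
            x = x[:, ::-1, :]
        angle = rng.uniform(-15.0, 15.0)
        x = ndimage.rotate(x, angle, axes=(0, 1), reshape=False, order=1,
                           mode="constant", cval=1.0)
        x = np.clip(x, 0.0, 1.0)
        if rng.random() < 0.2:
            gray = x @ np.array([0.299, 0.587, 0.114])
            x = np.repeat(gray[:, :, None], 3, axis=2)
    x = (x - IMAGENET_MEAN) / IMAGENET_STD
    return np.ascontiguousarray(x.transpose(2, 0, 1).astype(np.float32))


def denormalize_image(tensor: np.ndarray) -> np.ndarray:
    """Inverse of the normalization (no augmentation): (3,H,W) → (H,W,3)."""
    x = np.asarray(tensor, dtype=np.float64).transpose(1, 2, 0)
    return x * IMAGENET_STD + IMAGENET_MEAN


# ---------------------------------------------------------------------------
# Spectrum binning
# ---------------------------------------------------------------------------


def bin_spectrum(peaks, grid: SpectrumBinning | None = None) -> np.ndarray:
    """Discretize a ¹³C peak list into a binary bit vector.

    Bit ``b`` is set iff some peak falls in ``[lo + b·w, lo + (b+1)·w)``;
    out-of-range peaks clamp to the boundary bin.  Idempotent in peak
    multiplicity.  An empty peak list is an error — absent spectra must go
    through the missing-modality path, not through a zero vector.
    """
    grid = grid or SpectrumBinning()
    peaks = np.asarray(list(peaks), dtype=np.float64)
    if peaks.size == 0:
        raise ValueError("empty peak list; use the missing-modality path")
    if not np.all(np.isfinite(peaks)):
        raise ValueError("non-finite chemical shift")
    idx = np.floor((peaks - grid.lo) / grid.width).astype(np.int64)
    n_clamped = int(np.sum((idx < 0) | (idx >= grid.n_bins)))
    if n_clamped:
        logger.debug("%d peaks outside [%g, %g) clamped", n_clamped, grid.lo, grid.hi)
    idx = np.clip(idx, 0, grid.n_bins - 1)
    bits = np.zeros(grid.n_bins, dtype=np.float32)
    bits[idx] = 1.0
    return bits


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def _read_peak_source(path: Path) -> dict[str, list[float]]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return {str(k): [float(p) for p in v] for k, v in data.items()}
    df = pd.read_csv(path, dtype={"id": str})
    if not {"id", "ppm"}.issubset(df.columns):
        raise ValueError(f"peak CSV {path} needs columns id,ppm")
    out: dict[str, list[float]] = {}
    for rid, sub in df.groupby("id", sort=False):
        out[str(rid)] = [float(p) for p in sub["ppm"]]
    return out


def _parse_label(cell) -> float:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return MISSING
    s = str(cell).strip()
    if s in ("", "-1", "-1.0"):
        return MISSING
    if s in ("0", "0.0"):
        return 0.0
    if s in ("1", "1.0"):
        return 1.0
    raise ValueError(f"label value {cell!r} outside {{0, 1, missing}}")


def load_dataset(compound_csv, peaks_files=(), image_dir=None,
                 endpoints: list[str] | None = None
                 ) -> tuple[list[MoleculeRecord], DatasetSummary]:
    """Read a compound table and join optional peak sources and images.

    ``peaks_files`` is an ordered sequence of CSV/JSON sources; the first
    source containing a compound id wins and later sources are not consulted
    for it.  Rows whose SMILES does not parse are dropped (logged), mirroring
    a valid-molecule filter; duplicate ids are an error.
    """
    endpoints = endpoints or ENDPOINTS
    df = pd.read_csv(compound_csv, dtype={"id": str})
    missing_cols = {"id", "smiles"} - set(df.columns)
    if missing_cols:
        raise ValueError(f"compound table lacks columns {sorted(missing_cols)}")
    label_cols = [c for c in endpoints if c in df.columns]
    if len(label_cols) != len(endpoints):
        raise ValueError(
            f"compound table has {len(label_cols)} of {len(endpoints)} endpoint columns"
        )
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate compound ids: {dups[:5]}")

    sources = [_read_peak_source(p) for p in peaks_files]
    image_dir = Path(image_dir) if image_dir is not None else None

    records: list[MoleculeRecord] = []
    n_rejected = n_spec = 0
    for row in df.to_dict(orient="records"):
        rid, smiles = str(row["id"]), row["smiles"]
        mol = parse_and_validate(smiles)
        if mol is None:
            logger.info("rejecting unparsable SMILES for id=%s: %r", rid, smiles)
            n_rejected += 1
            continue
        labels = np.array([_parse_label(row[c]) for c in endpoints], dtype=np.float32)
        peaks = None
        for src in sources:  # first-match-wins across ordered sources
            if rid in src:
                peaks = src[rid]
                break
        if peaks is not None and len(peaks) == 0:
            peaks = None
        n_spec += peaks is not None
        image_path = None
        if image_dir is not None:
            candidate = image_dir / f"{rid}.png"
            if candidate.exists():
                image_path = candidate
        records.append(MoleculeRecord(rid, smiles, labels, peaks, image_path, mol))
    summary = DatasetSummary(len(df), len(records), n_rejected, n_spec)
    logger.info("loaded %d/%d valid compounds (%d with spectra)",
                summary.n_valid, summary.n_rows, summary.n_with_spectrum)
    return records, summary
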