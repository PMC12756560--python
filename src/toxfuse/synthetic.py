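"""Synthetic multimodal benchmark with planted, modality-distributed signal.

The generator assembles valid small organic molecules from a fragment grammar
(benzene / pyridine / cyclohexane scaffolds and short chains, decorated with
halogens, hydroxyl, nitro, carbonyl and amine groups), simulates ¹³C spectra
from simple carbon-environment rules, and drives 12 sparse binary endpoints
from planted substructure "toxicophores" through a logistic model with
calibrated intercepts.  Spectra are available for only a configurable
fraction of compounds (default 0.36, matching the kind of partial spectral
coverage seen in public toxicity corpora), so the missing-modality machinery
is exercised end to end.

The default toxicophores — nitroaromatic, carbonyl, aromatic halide — were
chosen because each is visible to a different modality (planted signal can be
split between graph-visible ring halogenation and spectrum-visible carbonyl
presence via ``complementary=True``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import ENDPOINTS, MISSING, MoleculeRecord, parse_and_validate
from .splits_eval import bemis_murcko_scaffold

logger = logging.getLogger(__name__)

#: SMARTS patterns defining the planted toxicophores
TOXICOPHORES = {
    "nitroaromatic": "[c][N+](=O)[O-]",
    "carbonyl": "[CX3]=[OX1]",
    "aromatic_halide": "[c][F,Cl,Br,I]",
}


@dataclass
class SynthConfig:
    n_molecules: int = 600
    seed: int = 0
    toxicophores: dict = field(default_factory=lambda: dict(TOXICOPHORES))
    #: per-endpoint weights over toxicophores, shape (12, n_toxicophores);
    #: None → default complementary/mixed pattern (see endpoint_weights()).
    weights: np.ndarray | None = None
    label_noise: float = 0.05
    missing_rate: float = 0.15
    spectrum_availability: float = 0.36
    shift_noise_sd: float = 1.0
    #: split endpoint signal between a graph-visible toxicophore (aromatic
    #: halide) and a spectrum-visible one (carbonyl)
    complementary: bool = True
    signal_strength: float = 6.0
    target_positive_range: tuple[float, float] = (0.05, 0.40)
    #: fraction of purely acyclic (empty-scaffold) molecules
    acyclic_fraction: float = 0.1
    #: bypass intercept calibration with explicit per-endpoint intercepts
    #: (needed e.g. for the deterministic strong-signal limit, where a
    #: calibrated intercept would sit exactly on a toxicophore-group boundary)
    fixed_intercepts: tuple | None = None
    #: probability a molecule carries a second ring joined by a linker,
    #: multiplying scaffold diversity
    second_ring_prob: float = 0.8

    def __post_init__(self):
        for name, val in (("label_noise", self.label_noise),
                          ("missing_rate", self.missing_rate),
                          ("spectrum_availability", self.spectrum_availability)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.n_molecules < 20:
            raise ValueError("n_molecules must be >= 20")
        if len(self.toxicophores) < 2:
            raise ValueError("need >= 2 toxicophores")


def endpoint_weights(cfg: SynthConfig) -> np.ndarray:
    """Default (12 × K) signal weights.

    Complementary mode drives the first six endpoints by the aromatic-halide
    indicator and the last six by the carbonyl indicator, with a weak
    nitroaromatic contribution everywhere; otherwise all endpoints mix all
    toxicophores with varying sign-free magnitudes."""
    if cfg.weights is not None:
        w = np.asarray(cfg.weights, dtype=np.float64)
        if w.shape != (len(ENDPOINTS), len(cfg.toxicophores)):
            raise ValueError("weights must be (12, n_toxicophores)")
        return w
    keys = list(cfg.toxicophores)
    k = {name: i for i, name in enumerate(keys)}
    w = np.zeros((len(ENDPOINTS), len(keys)))
    s = cfg.signal_strength
    if cfg.complementary and {"carbonyl", "aromatic_halide"} <= set(k):
        w[:6, k["aromatic_halide"]] = s
        w[6:, k["carbonyl"]] = s
        if "nitroaromatic" in k:
            w[:, k["nitroaromatic"]] = 0.25 * s
    else:
        rng = np.random.Generator(np.random.PCG64(cfg.seed + 999))
        w = rng.uniform(0.3 * s, s, size=w.shape)
    return w


# ---------------------------------------------------------------------------
# Molecule generation (fragment grammar)
# ---------------------------------------------------------------------------

# Ring templates with two parenthesised splice slots {a}/{b} inside the ring
# and a raw tail slot {c} after ring closure.  Ring identity x linker x
# optional second ring multiplies into hundreds of distinct Bemis-Murcko
# scaffolds, so scaffold splits of synthetic sets have realistic geometry.
_AROMATIC_RINGS = {
    "benzene": "c1c{a}cc{b}cc1{c}",
    "pyridine": "n1c{a}cc{b}cc1{c}",
    "pyrimidine": "n1c{a}nc{b}cc1{c}",
    "furan": "o1c{a}cc{b}c1{c}",
    "thiophene": "s1c{a}cc{b}c1{c}",
}
_ALIPHATIC_RINGS = {
    "cyclohexane": "C1C{a}CC{b}CC1{c}",
    "cyclopentane": "C1C{a}CC{b}C1{c}",
    "piperidine": "N1C{a}CC{b}CC1{c}",
    "oxane": "O1C{a}CC{b}CC1{c}",
}
_BICYCLIC_RINGS = {
    "naphthalene": "c1c{a}cc2cc{b}ccc2c1{c}",
    "quinoline": "c1c{a}cc2ncc{b}cc2c1{c}",
    "indane": "C1C{a}Cc2cc{b}ccc21{c}",
    "decalin": "C1C{a}CC2CC{b}CCC2C1{c}",
}
_LINKERS = ["", "C", "CC", "CCC", "O", "OC", "N", "NC", "C(C)"]
_PLAIN_DECOR = ["C", "CC", "O", "N", "OC", "C(C)C", "CO", "CN"]
_HALOGENS = ["F", "Cl", "Br", "I"]
_CARBONYLS = ["C(C)=O", "C=O", "C(=O)OC", "C(=O)N"]


def _ring(template: str, a: str = "", b: str = "", c: str = "") -> str:
    return template.format(a=f"({a})" if a else "", b=f"({b})" if b else "", c=c)


def _second_ring(rng: np.random.Generator) -> str:
    templates = {**_AROMATIC_RINGS, **_ALIPHATIC_RINGS}
    name = str(rng.choice(list(templates)))
    ring2 = _ring(templates[name]).replace("1", "3")
    return str(rng.choice(_LINKERS)) + ring2


def _generate_one(rng: np.random.Generator, want_nitro: bool, want_carbonyl: bool,
                  want_halide: bool, acyclic: bool, second_ring_prob: float) -> str:
    """Assemble one SMILES realizing the requested toxicophore pattern."""
    if acyclic and not (want_nitro or want_halide):
        n = int(rng.integers(2, 7))
        smi = "C" * n
        if rng.random() < 0.4:
            smi += str(rng.choice(["O", "N", "CO"]))
        if want_carbonyl:
            smi = "CC(=O)" + smi
        return smi
    aromatic_needed = want_nitro or want_halide
    templates = {**_AROMATIC_RINGS, **_ALIPHATIC_RINGS, **_BICYCLIC_RINGS}
    pool = ({**_AROMATIC_RINGS, "naphthalene": None, "quinoline": None}
            if aromatic_needed else templates)
    ring1 = templates[str(rng.choice(list(pool)))]
    decs: list[str] = []
    if want_nitro:
        decs.append("[N+](=O)[O-]")
    if want_halide:
        decs.append(str(rng.choice(_HALOGENS)))
    if want_carbonyl:
        decs.append(str(rng.choice(_CARBONYLS)))
    if len(decs) < 3 and rng.random() < second_ring_prob:
        decs.append(_second_ring(rng))
    if len(decs) < 3 and rng.random() < 0.5:
        decs.append(str(rng.choice(_PLAIN_DECOR)))
    rng.shuffle(decs)
    decs = (decs + ["", "", ""])[:3]
    return _ring(ring1, a=decs[0], b=decs[1], c=decs[2])


def generate_molecules(cfg: SynthConfig) -> list[str]:
    """Deterministic list of valid SMILES with controlled toxicophore content.

    Guarantees ≥3 distinct Bemis-Murcko scaffold groups and, for every
    toxicophore, both present and absent molecules; raises if the retry
    budget cannot satisfy the constraints."""
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    patterns = {k: Chem.MolFromSmarts(s) for k, s in cfg.toxicophores.items()}
    out: list[str] = []
    budget = cfg.n_molecules * 30
    while len(out) < cfg.n_molecules and budget > 0:
        budget -= 1
        want = rng.random(3) < 0.35
        acyclic = rng.random() < cfg.acyclic_fraction
        smi = _generate_one(rng, *want, acyclic, cfg.second_ring_prob)
        mol = parse_and_validate(smi)
        if mol is None:
            continue
        out.append(Chem.MolToSmiles(mol))
    if len(out) < cfg.n_molecules:
        raise RuntimeError("retry budget exhausted while generating molecules")
    mols = [Chem.MolFromSmiles(s) for s in out]
    scaffolds = {bemis_murcko_scaffold(m) for m in mols}
    if len(scaffolds) < 3:
        raise RuntimeError("generator produced <3 distinct scaffolds")
    for name, patt in patterns.items():
        hits = sum(bool(m.HasSubstructMatch(patt)) for m in mols)
        if hits == 0 or hits == len(mols):
            raise RuntimeError(f"toxicophore {name} not both present and absent")
    return out


def toxicophore_matrix(mols, toxicophores=None) -> np.ndarray:
    """(n, K) binary indicators of planted substructure presence."""
    toxicophores = toxicophores or TOXICOPHORES
    patterns = {k: Chem.MolFromSmarts(s) for k, s in toxicophores.items()}
    out = np.zeros((len(mols), len(patterns)), dtype=np.float64)
    for i, m in enumerate(mols):
        for j, patt in enumerate(patterns.values()):
            out[i, j] = float(m.HasSubstructMatch(patt))
    return out


# ---------------------------------------------------------------------------
# Spectrum simulation
# ---------------------------------------------------------------------------

_CARBONYL_PATT = Chem.MolFromSmarts("[CX3]=[OX1]")


def _carbon_environment(atom, mol) -> float:
    """Base ¹³C shift by environment class: carbonyl 180, aromatic 128,
    sp³ C bound to a heteroatom 60, plain sp³ 25 ppm."""
    idx = atom.GetIdx()
    for match in mol.GetSubstructMatches(_CARBONYL_PATT):
        if idx == match[0]:
            return 180.0
    if atom.GetIsAromatic():
        return 128.0
    for nb in atom.GetNeighbors():
        if nb.GetSymbol() in ("N", "O", "F", "Cl", "Br", "I"):
            return 60.0
    return 25.0


def simulate_spectrum(mol, cfg: SynthConfig, rng: np.random.Generator) -> list[float]:
    """One peak per symmetry-equivalent carbon class, Gaussian jitter of
    ``shift_noise_sd`` ppm.  Molecules without carbon give an empty list
    (callers mark the spectrum absent)."""
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    classes: dict[int, float] = {}
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "C":
            continue
        key = ranks[atom.GetIdx()]
        if key not in classes:
            classes[key] = _carbon_environment(atom, mol)
    peaks = []
    for key in sorted(classes):
        base = classes[key]
        jitter = rng.normal(0.0, cfg.shift_noise_sd) if cfg.shift_noise_sd > 0 else 0.0
        peaks.append(float(base + jitter))
    return peaks


# ---------------------------------------------------------------------------
# Label simulation
# ---------------------------------------------------------------------------


def _calibrate_intercept(lin: np.ndarray, target: float) -> float:
    """Bisection on b so that mean(sigmoid(lin + b)) ≈ target."""
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        p = 1.0 / (1.0 + np.exp(-(lin + mid)))
        if p.mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_labels(mols, cfg: SynthConfig, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """12-endpoint sparse labels from the planted logistic model.

    activity_t = sigmoid(Σ_k w_tk · has_toxicophore_k + b_t) with b_t
    calibrated so each endpoint's expected positive rate lands inside
    ``target_positive_range``; labels are Bernoulli draws XOR label noise,
    then masked MISSING at the per-endpoint missing rate.  Returns
    ``(labels, activities)``."""
    x = toxicophore_matrix(mols, cfg.toxicophores)
    w = endpoint_weights(cfg)
    lo, hi = cfg.target_positive_range
    targets = rng.uniform(lo + 0.03, hi - 0.03, size=len(ENDPOINTS))
    labels = np.zeros((len(mols), len(ENDPOINTS)), dtype=np.float32)
    acts = np.zeros_like(labels, dtype=np.float64)
    for t in range(len(ENDPOINTS)):
        lin = x @ w[t]
        if cfg.fixed_intercepts is not None:
            b = float(np.broadcast_to(cfg.fixed_intercepts, (len(ENDPOINTS),))[t])
        else:
            b = _calibrate_intercept(lin, targets[t])
        p = 1.0 / (1.0 + np.exp(-(lin + b)))
        acts[:, t] = p
        y = (rng.random(len(mols)) < p).astype(np.float32)
        flip = rng.random(len(mols)) < cfg.label_noise
        y = np.where(flip, 1.0 - y, y)
        miss = rng.random(len(mols)) < cfg.missing_rate
        labels[:, t] = np.where(miss, MISSING, y)
    return labels, acts


# ---------------------------------------------------------------------------
# Benchmark assembly
# ---------------------------------------------------------------------------


def make_records(cfg: SynthConfig) -> list[MoleculeRecord]:
    """In-memory benchmark: molecules, labels, and partial spectra."""
    smiles = generate_molecules(cfg)
    mols = [Chem.MolFromSmiles(s) for s in smiles]
    rng = np.random.Generator(np.random.PCG64(cfg.seed + 1))
    labels, _ = simulate_labels(mols, cfg, rng)
    has_spec = rng.random(len(mols)) < cfg.spectrum_availability
    records = []
    for i, (smi, mol) in enumerate(zip(smiles, mols)):
        peaks = None
        if has_spec[i]:
            p = simulate_spectrum(mol, cfg, rng)
            peaks = p if p else None
        records.append(MoleculeRecord(f"SYN{i:05d}", smi, labels[i], peaks,
                                      None, mol))
    return records


def build_benchmark(cfg: SynthConfig, out_dir, write_images: bool = False) -> dict:
    """Write the benchmark in the standard interchange formats.

    Produces ``compounds.csv`` (id, smiles, 12 endpoint columns with -1 for
    missing), ``peaks.json`` (id → ppm list) and a ``manifest.json``
    recording the configuration and seed.  Images are rendered lazily by the
    loader by default; ``write_images=True`` additionally writes
    ``images/<id>.png``.  Byte-identical outputs for identical configs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = make_records(cfg)
    rows = []
    for r in records:
        row = {"id": r.id, "smiles": r.smiles}
        for t, ep in enumerate(ENDPOINTS):
            row[ep] = int(r.labels[t])
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "compounds.csv", index=False)
    peaks = {r.id: [round(p, 4) for p in r.peaks] for r in records if r.has_spectrum}
    (out_dir / "peaks.json").write_text(json.dumps(peaks, indent=0, sort_keys=True))
    if write_images:
        from .chem_io import render_image
        img_dir = out_dir / "images"
        for r in records:
            render_image(r.mol, cache_dir=img_dir, record_id=r.id)
    manifest = {
        "seed": cfg.seed,
        "n_molecules": cfg.n_molecules,
        "spectrum_availability": cfg.spectrum_availability,
        "label_noise": cfg.label_noise,
        "missing_rate": cfg.missing_rate,
        "toxicophores": cfg.toxicophores,
        "complementary": cfg.complementary,
        "signal_strength": cfg.signal_strength,
        "files": ["compounds.csv", "peaks.json"] + (["images/"] if write_images else []),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
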