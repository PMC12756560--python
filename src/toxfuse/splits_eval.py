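"""Scaffold-based partitioning, metric computation, and cross-split
statistical comparison.

Molecules are grouped by Bemis-Murcko scaffold; whole scaffold groups are
assigned to train/valid/test in an 8:1:1 ratio so that no scaffold appears in
two partitions.  The partitioning is repeated over several seeds and models
are compared across seeds with paired two-tailed t-tests.  ROC-AUC is the
primary metric (macro = unweighted mean over computable endpoints);
supplementary threshold metrics follow the standard confusion-matrix
formulas at sigmoid score ≥ 0.5.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy import stats
from sklearn import metrics as skm

from .chem_io import MISSING, ENDPOINTS, MoleculeRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Scaffolds and splitting
# ---------------------------------------------------------------------------


def bemis_murcko_scaffold(mol) -> str:
    """Canonical Bemis-Murcko scaffold SMILES (ring systems + linkers, side
    chains removed).  Acyclic molecules yield the empty string; by default
    all empty scaffolds form one shared group."""
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol, includeChirality=False)


@dataclass
class SplitAssignment:
    seed: int
    scaffold_of: dict[str, str]
    partition_of: dict[str, str]

    def ids(self, partition: str) -> list[str]:
        return [i for i, p in self.partition_of.items() if p == partition]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": list(self.partition_of),
             "scaffold": [self.scaffold_of[i] for i in self.partition_of],
             "partition": list(self.partition_of.values())}
        )


def scaffold_split(records: list[MoleculeRecord], seed: int,
                   ratios: tuple[float, float, float] = (8, 1, 1),
                   shuffle: bool = True,
                   pool_empty_scaffolds: bool = True) -> SplitAssignment:
    """Whole-scaffold-group partitioning at the given ratio.

    Groups are shuffled by the seed (``shuffle=False`` gives the common
    deterministic largest-first variant) and assigned greedily: fill train
    until its molecule count first reaches its quota, then valid, remainder
    test.  Requires ≥3 distinct scaffold groups.
    """
    scaffold_of: dict[str, str] = {}
    groups: dict[str, list[str]] = {}
    for r in records:
        scaf = bemis_murcko_scaffold(r.mol)
        scaffold_of[r.id] = scaf
        key = scaf if (scaf or not pool_empty_scaffolds) else ""
        groups.setdefault(key, []).append(r.id)
    if len(groups) < 3:
        raise ValueError(
            f"need >=3 distinct scaffold groups to split, found {len(groups)}"
        )
    keys = sorted(groups)
    rng = np.random.Generator(np.random.PCG64(seed))
    if shuffle:
        order = [keys[i] for i in rng.permutation(len(keys))]
    else:
        order = sorted(keys, key=lambda k: (-len(groups[k]), k))
    n = len(records)
    quota = np.array(ratios, dtype=np.float64)
    quota = quota / quota.sum() * n
    partition_of: dict[str, str] = {}
    counts = {"train": 0, "valid": 0, "test": 0}
    part_iter = ["train", "valid", "test"]
    current = 0
    for key in order:
        ids = groups[key]
        name = part_iter[current]
        for i in ids:
            partition_of[i] = name
        counts[name] += len(ids)
        while current < 2 and counts[part_iter[current]] >= quota[current]:
            current += 1
    # guarantee non-empty partitions (tiny datasets): steal trailing groups
    for name in ("valid", "test"):
        if counts[name] == 0:
            donor = max(counts, key=lambda k: counts[k])
            donor_groups = [k for k in order
                            if partition_of[groups[k][0]] == donor]
            steal = donor_groups[-1]
            for i in groups[steal]:
                partition_of[i] = name
            counts[name] += len(groups[steal])
            counts[donor] -= len(groups[steal])
            logger.info("moved scaffold group to empty partition %s", name)
    return SplitAssignment(seed, scaffold_of, partition_of)


def split_indices(records: list[MoleculeRecord], split: SplitAssignment):
    """(train, valid, test) integer index arrays into ``records``."""
    pos = {r.id: i for i, r in enumerate(records)}
    return tuple(
        np.array([pos[i] for i in split.ids(p)], dtype=np.int64)
        for p in ("train", "valid", "test")
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def roc_auc(scores, labels) -> float | None:
    """Area under the ROC curve; equals P(score⁺ > score⁻) + ½·P(tie).

    Returns ``None`` (undefined) when only one class is present; callers
    exclude such endpoints from the macro average."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(labels)) < 2:
        return None
    return float(skm.roc_auc_score(labels, scores))


def macro_roc_auc(scores: np.ndarray, labels: np.ndarray) -> float | None:
    """Unweighted mean AUC over endpoints with both classes observed.

    ``labels`` may contain MISSING entries; they are excluded per endpoint.
    Returns None when no endpoint is computable."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    aucs = []
    for t in range(labels.shape[1]):
        obs = labels[:, t] != MISSING
        if obs.sum() == 0:
            continue
        auc = roc_auc(scores[obs, t], labels[obs, t])
        if auc is None:
            logger.debug("endpoint %d single-class; skipped in macro", t)
            continue
        aucs.append(auc)
    return float(np.mean(aucs)) if aucs else None


def per_endpoint_auc(scores: np.ndarray, labels: np.ndarray,
                     endpoints=None) -> dict[str, float | None]:
    endpoints = endpoints or ENDPOINTS
    out = {}
    for t, name in enumerate(endpoints):
        obs = labels[:, t] != MISSING
        out[name] = roc_auc(scores[obs, t], labels[obs, t]) if obs.any() else None
    return out


def threshold_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Confusion-matrix metrics at ``score >= threshold``."""
    labels = np.asarray(labels).astype(int)
    pred = (np.asarray(scores, dtype=np.float64) >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            "accuracy": skm.accuracy_score(labels, pred),
            "balanced_accuracy": skm.balanced_accuracy_score(labels, pred),
            "kappa": skm.cohen_kappa_score(labels, pred),
            "mcc": skm.matthews_corrcoef(labels, pred),
            "sensitivity": sens,
            "specificity": spec,
        }


def paired_t_test(metric_a, metric_b) -> float:
    """Two-tailed paired t-test p-value with degenerate-case conventions:
    identical vectors → 1.0; zero-variance nonzero difference → 0.0 (both
    logged as warnings)."""
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of >=2 values")
    d = a - b
    if np.allclose(d, 0.0, atol=0.0):
        warnings.warn("identical metric vectors; p-value reported as 1.0")
        return 1.0
    if np.isclose(d.std(ddof=1), 0.0):
        warnings.warn("zero-variance nonzero difference; p-value reported as 0.0")
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)


# ---------------------------------------------------------------------------
# Benchmark matrix (ablation harness)
# ---------------------------------------------------------------------------


def ablation_subsets(mode: str = "full") -> list[tuple[str, ...]]:
    """Model rows: singles (4) + pairs (6) + the graph/smiles/image triple +
    the full quad under ``full``; singles + quad under ``reduced``."""
    mods = ("graph", "smiles", "image", "spectrum")
    singles = [(m,) for m in mods]
    quad = [mods]
    if mode == "reduced":
        return singles + quad
    pairs = [tuple(c) for c in itertools.combinations(mods, 2)]
    triple = [("graph", "smiles", "image")]
    return singles + pairs + triple + quad


def subset_name(subset: tuple[str, ...]) -> str:
    return "+".join(subset)


@dataclass
class MetricsReport:
    """Per-(seed, model, endpoint) AUCs, per-(seed, model) macro AUCs and
    threshold metrics, cross-seed summary with paired p-values vs the full
    model, and per-seed attention summaries."""

    per_endpoint: pd.DataFrame
    per_seed: pd.DataFrame
    summary: pd.DataFrame
    attention: pd.DataFrame | None = None

    def to_csv(self, directory) -> None:
        from pathlib import Path
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.per_endpoint.to_csv(directory / "per_endpoint.csv", index=False)
        self.per_seed.to_csv(directory / "per_seed.csv", index=False)
        self.summary.to_csv(directory / "summary.csv", index=False)
        if self.attention is not None:
            self.attention.to_csv(directory / "attention.csv", index=False)


def format_mean_sd(mean: float, sd: float) -> str:
    return f"{mean:.3f}±{sd:.3f}"


def benchmark_matrix(records, seeds, subsets=None, enc_cfgs=None,
                     encoder_train_cfg=None, fusion_train_cfg_=None,
                     fusion_cfg_kw=None, split_kw=None) -> MetricsReport:
    """Train and evaluate every (seed, modality-subset) cell.

    For each seed: scaffold-split, train the union of needed encoders once,
    evaluate each single-modality probe, then train one fusion model per
    multi-modality subset on the frozen encoders.  Emits per-endpoint and
    macro test AUCs, cross-seed mean ± sd, and paired t-test p-values of each
    row against the full four-modality model (when present).
    """
    from .chem_io import build_vocab
    from .training import (FeaturizedDataset, TrainConfig, train_encoder,
                           train_fusion, fusion_scores, _eval_scores,
                           fusion_train_config)
    from .fusion import FusionConfig, extract_attention_summary

    subsets = subsets or ablation_subsets("full")
    enc_cfgs = enc_cfgs or {}
    encoder_train_cfg = encoder_train_cfg or TrainConfig()
    fusion_train_cfg_ = fusion_train_cfg_ or fusion_train_config()
    fusion_cfg_kw = dict(fusion_cfg_kw or {})
    split_kw = dict(split_kw or {})
    needed = sorted({m for s in subsets for m in s})
    vocab = build_vocab(r.smiles for r in records)
    ds = FeaturizedDataset(records, vocab, need=tuple(needed))

    ep_rows, seed_rows, attn_frames = [], [], []
    for seed in seeds:
        split = scaffold_split(records, seed, **split_kw)
        tr, va, te = split_indices(records, split)
        import dataclasses as _dc
        enc_cfg_seeded = _dc.replace(encoder_train_cfg, seed=seed)
        fus_cfg_seeded = _dc.replace(fusion_train_cfg_, seed=seed)
        encoders = {}
        for m in needed:
            encoders[m], _ = train_encoder(m, ds, tr, va, enc_cfgs.get(m),
                                           enc_cfg_seeded)
        for subset in subsets:
            name = subset_name(subset)
            if len(subset) == 1:
                m = subset[0]
                idx = te
                if m == "spectrum":
                    idx = te[ds.spectrum_present[te]]
                scores = _eval_scores(encoders[m], ds, idx)
                labels = ds.labels[idx]
            else:
                fcfg = FusionConfig(active_modalities=subset, **fusion_cfg_kw)
                model, _ = train_fusion(encoders, ds, tr, va, fcfg, fus_cfg_seeded)
                scores, attn = fusion_scores(model, encoders, ds, te)
                labels = ds.labels[te]
                attn_frames.append(
                    extract_attention_summary([attn], subset, split_seed=seed)
                    .assign(model=name))
            ep_auc = per_endpoint_auc(scores, labels)
            for ep, auc in ep_auc.items():
                ep_rows.append({"seed": seed, "model": name, "endpoint": ep,
                                "auc": np.nan if auc is None else auc})
            flat_obs = (labels != MISSING).reshape(-1)
            thr = threshold_metrics(scores.reshape(-1)[flat_obs],
                                    labels.reshape(-1)[flat_obs])
            seed_rows.append({"seed": seed, "model": name,
                              "macro_auc": macro_roc_auc(scores, labels),
                              **thr})

    per_endpoint = pd.DataFrame(ep_rows)
    per_seed = pd.DataFrame(seed_rows)
    full_name = subset_name(tuple(m for m in ("graph", "smiles", "image", "spectrum")))
    summary_rows = []
    full_macro = (per_seed[per_seed.model == full_name]
                  .sort_values("seed")["macro_auc"].to_numpy()
                  if full_name in set(per_seed.model) else None)
    for name, sub in per_seed.groupby("model", sort=False):
        vals = sub.sort_values("seed")["macro_auc"].to_numpy(dtype=np.float64)
        finite = vals[np.isfinite(vals)]
        mean = float(finite.mean()) if finite.size else np.nan
        sd = float(finite.std(ddof=1)) if finite.size > 1 else 0.0
        row = {"model": name, "mean_auc": mean, "sd_auc": sd,
               "formatted": format_mean_sd(mean, sd)}
        if full_macro is not None and name != full_name and len(vals) >= 2:
            row["p_vs_full"] = paired_t_test(vals, full_macro)
        elif name == full_name:
            row["p_vs_full"] = np.nan
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)
    attention = pd.concat(attn_frames, ignore_index=True) if attn_frames else None
    return MetricsReport(per_endpoint, per_seed, summary, attention)


# ---------------------------------------------------------------------------
# Fingerprint export hook (chemical-space analyses)
# ---------------------------------------------------------------------------


def morgan_fingerprints(records, n_bits: int = 2048, radius: int = 2) -> np.ndarray:
    """2048-bit Morgan fingerprints (radius 2) for external visualization."""
    gen = AllChem.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = np.zeros((len(records), n_bits), dtype=np.uint8)
    for i, r in enumerate(records):
        fp = gen.GetFingerprint(r.mol)
        out[i] = np.frombuffer(bytes(fp.ToBitString(), "ascii"), dtype=np.uint8) - ord("0")
    return out
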