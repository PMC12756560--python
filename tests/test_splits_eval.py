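"""Scaffold splitting, ROC/threshold metrics, paired tests, benchmark
bookkeeping."""

import numpy as np
import pytest
from rdkit import Chem

import toxfuse as tf
from toxfuse.chem_io import MISSING, MoleculeRecord
from toxfuse.splits_eval import ablation_subsets, format_mean_sd, subset_name


def rec(i, smiles):
    return MoleculeRecord(f"r{i}", smiles, np.zeros(12, np.float32),
                          mol=Chem.MolFromSmiles(smiles))


# ---------------------------------------------------------------------------
# scaffolds
# ---------------------------------------------------------------------------


def test_bemis_murcko_side_chains_stripped():
    scaf = tf.bemis_murcko_scaffold(Chem.MolFromSmiles("c1ccccc1CCN"))
    assert Chem.CanonSmiles(scaf) == Chem.CanonSmiles("c1ccccc1")


def test_bemis_murcko_acyclic_is_empty_and_groups_match():
    assert tf.bemis_murcko_scaffold(Chem.MolFromSmiles("CCO")) == ""
    a = tf.bemis_murcko_scaffold(Chem.MolFromSmiles("c1ccccc1"))
    b = tf.bemis_murcko_scaffold(Chem.MolFromSmiles("Cc1ccccc1C"))
    assert a == b


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

_TEN_SINGLETONS = [
    "c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "C1CCCCC1",
    "C1CCCC1", "C1CCNCC1", "C1CCOCC1", "c1cncnc1", "c1ccc2ccccc2c1",
]


@pytest.mark.parametrize("seed", [0, 1, 7])
def test_ten_singleton_scaffolds_split_8_1_1(seed):
    records = [rec(i, s) for i, s in enumerate(_TEN_SINGLETONS)]
    split = tf.scaffold_split(records, seed)
    sizes = {p: len(split.ids(p)) for p in ("train", "valid", "test")}
    assert sizes == {"train": 8, "valid": 1, "test": 1}


def test_shared_scaffold_always_copartitioned():
    records = [rec(i, s) for i, s in enumerate(_TEN_SINGLETONS)]
    records += [rec(10, "Cc1ccccc1"), rec(11, "CCc1ccccc1")]
    for seed in range(5):
        split = tf.scaffold_split(records, seed)
        parts = {split.partition_of[r.id]
                 for r in records if Chem.CanonSmiles(
                     tf.bemis_murcko_scaffold(r.mol) or "C") == "c1ccccc1"}
        assert len(parts) == 1


def test_split_requires_three_scaffolds():
    records = [rec(0, "CCO"), rec(1, "CCC"), rec(2, "c1ccccc1")]
    with pytest.raises(ValueError, match="scaffold"):
        tf.scaffold_split(records, 0)  # acyclics pool into one group -> 2


def test_deterministic_variant_is_size_sorted():
    records = [rec(i, s) for i, s in enumerate(_TEN_SINGLETONS)]
    records += [rec(10 + i, "Cc1ccccc1" + "C" * i) for i in range(4)]
    s1 = tf.scaffold_split(records, 0, shuffle=False)
    s2 = tf.scaffold_split(records, 99, shuffle=False)
    assert s1.partition_of == s2.partition_of  # seed-independent


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def pairwise_auc_oracle(scores, labels):
    """O(n²) enumeration: wins + half-credit ties over all +/- pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        return None
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_roc_auc_examples():
    assert tf.roc_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)
    assert tf.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
    assert tf.roc_auc([0.5, 0.6], [1, 1]) is None


def test_roc_auc_matches_pairwise_oracle_with_ties():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(2, 50))
        scores = rng.choice([0.1, 0.2, 0.5, 0.7, 0.7, 0.9], size=n)
        labels = rng.integers(0, 2, size=n)
        want = pairwise_auc_oracle(scores, labels)
        got = tf.roc_auc(scores, labels)
        if want is None:
            assert got is None
        else:
            assert got == pytest.approx(want, abs=1e-12)


def test_macro_auc_skips_single_class_and_order_invariant():
    rng = np.random.default_rng(1)
    scores = rng.random((30, 12))
    labels = rng.integers(0, 2, size=(30, 12)).astype(np.float32)
    labels[:, 5] = 1.0  # single-class endpoint skipped
    labels[rng.random((30, 12)) < 0.3] = MISSING
    m = tf.macro_roc_auc(scores, labels)
    perm = rng.permutation(12)
    assert tf.macro_roc_auc(scores[:, perm], labels[:, perm]) == pytest.approx(m)


def test_threshold_metrics_confusion_arithmetic():
    # TP=2, FP=1, TN=6, FN=1
    labels = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
    scores = [0.9, 0.8, 0.1, 0.7, 0.2, 0.2, 0.3, 0.1, 0.05, 0.4]
    m = tf.threshold_metrics(scores, labels)
    assert m["sensitivity"] == pytest.approx(2 / 3)
    assert m["specificity"] == pytest.approx(6 / 7)
    assert m["accuracy"] == pytest.approx(0.8)


def test_threshold_metrics_perfect_and_chance():
    perfect = tf.threshold_metrics([0.9, 0.9, 0.1, 0.1], [1, 1, 0, 0])
    assert perfect["kappa"] == 1.0 and perfect["mcc"] == 1.0
    chance = tf.threshold_metrics([0.1, 0.2, 0.3, 0.2], [1, 0, 0, 0])
    assert chance["kappa"] == 0.0


def test_paired_t_conventions_and_closed_form():
    with pytest.warns(UserWarning):
        assert tf.paired_t_test([1, 2, 3], [1, 2, 3]) == 1.0
    with pytest.warns(UserWarning):
        assert tf.paired_t_test([2, 3, 4], [1, 2, 3]) == 0.0
    a = np.array([0.5, -0.3, 0.8, 0.2, -0.1])
    b = np.zeros(5)
    # closed form: t = mean(d) / (sd(d)/sqrt(n)), p = 2·(1 − F_t(|t|; n−1))
    d = a - b
    t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
    from scipy import stats
    want = 2 * stats.t.sf(abs(t), df=4)
    assert tf.paired_t_test(a, b) == pytest.approx(want, abs=1e-12)


def test_ablation_enumeration_and_formatting():
    full = ablation_subsets("full")
    assert len(full) == 12  # C(4,1) + C(4,2) + triple + quad
    assert ("graph", "smiles", "image") in full
    assert len(ablation_subsets("reduced")) == 5
    assert subset_name(("graph", "smiles")) == "graph+smiles"
    assert format_mean_sd(0.8311, 0.0229) == "0.831±0.023"


def test_benchmark_matrix_bookkeeping(records60):
    enc_cfgs = {
        "graph": tf.GraphEncoderConfig(hidden_dim=12, n_layers=2,
                                       output_dim=8, dropout=0.0),
        "smiles": tf.SmilesEncoderConfig(hidden_dim=12, n_layers=1, n_heads=2,
                                         output_dim=8, dropout=0.0),
    }
    tcfg = tf.TrainConfig(max_epochs=2, patience=1, lr=3e-3)
    fcfg = tf.fusion_train_config(max_epochs=2, patience=1, lr=3e-3)
    report = tf.benchmark_matrix(
        records60, seeds=[0], subsets=[("graph",), ("graph", "smiles")],
        enc_cfgs=enc_cfgs, encoder_train_cfg=tcfg, fusion_train_cfg_=fcfg,
        fusion_cfg_kw={"common_dim": 16, "n_heads": 2, "dropout": 0.0})
    # exactly 12 endpoint rows + 1 macro per (seed, model)
    for name in ("graph", "graph+smiles"):
        sub = report.per_endpoint.query("model == @name")
        assert len(sub) == 12
        seed_row = report.per_seed.query("model == @name")
        assert len(seed_row) == 1
    # reported mean equals the mean of per-seed macro AUCs
    for row in report.summary.itertuples():
        vals = report.per_seed.query("model == @row.model")["macro_auc"]
        assert row.mean_auc == pytest.approx(vals.mean(), abs=1e-12)
    assert report.attention is not None
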