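"""Masked multi-task objective and the two-phase training protocol."""

import numpy as np
import pandas as pd
import pytest

import toxfuse as tf
from toxfuse import nn
from toxfuse.chem_io import MISSING
from toxfuse.training import LabelMask, _eval_scores, masked_multitask_loss

from conftest import tiny_graph_cfg, tiny_smiles_cfg, tiny_spectrum_cfg


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def test_loss_single_observed_entry_closed_form():
    logits = nn.Parameter(np.zeros((1, 12)))
    labels = np.full((1, 12), MISSING, dtype=np.float32)
    labels[0, 3] = 1.0
    loss = masked_multitask_loss(logits, LabelMask.from_labels(labels))
    assert loss.item() == pytest.approx(np.log(2.0), abs=1e-6)  # −ln σ(0)


def test_loss_all_missing_is_zero_with_zero_gradients():
    logits = nn.Parameter(np.random.default_rng(0).normal(size=(4, 12)))
    labels = np.full((4, 12), MISSING, dtype=np.float32)
    loss = masked_multitask_loss(logits, LabelMask.from_labels(labels))
    assert loss.item() == 0.0
    loss.backward()
    assert logits.grad is None or np.all(logits.grad == 0)


def test_loss_invariant_to_values_in_masked_slots():
    rng = np.random.default_rng(1)
    z = rng.normal(size=(3, 12)).astype(np.float32)
    labels = (rng.random((3, 12)) < 0.5).astype(np.float32)
    observed = rng.random((3, 12)) < 0.6
    lm1 = LabelMask(np.where(observed, labels, 0.0).astype(np.float32), observed)
    lm2 = LabelMask(np.where(observed, labels, 1.0).astype(np.float32), observed)

    p1 = nn.Parameter(z.copy())
    l1 = masked_multitask_loss(p1, lm1)
    l1.backward()
    p2 = nn.Parameter(z.copy())
    l2 = masked_multitask_loss(p2, lm2)
    l2.backward()
    assert l1.item() == l2.item()
    assert np.array_equal(p1.grad, p2.grad)
    # masked entries get exactly zero gradient
    assert np.all(p1.grad[~observed] == 0)


def test_loss_gradient_zero_for_all_missing_sample():
    rng = np.random.default_rng(2)
    p = nn.Parameter(rng.normal(size=(2, 12)))
    labels = np.stack([np.full(12, MISSING), np.ones(12)]).astype(np.float32)
    loss = masked_multitask_loss(p, LabelMask.from_labels(labels))
    loss.backward()
    assert np.all(p.grad[0] == 0)
    assert np.abs(p.grad[1]).max() > 0


def test_per_task_mean_variant_differs_under_imbalance():
    rng = np.random.default_rng(3)
    p = nn.Parameter(rng.normal(size=(4, 12)))
    labels = (rng.random((4, 12)) < 0.5).astype(np.float32)
    labels[:3, 0] = MISSING  # task 0 observed once, others 4 times
    lm = LabelMask.from_labels(labels)
    a = masked_multitask_loss(p, lm, per_task_mean=False).item()
    b = masked_multitask_loss(p, lm, per_task_mean=True).item()
    assert a != pytest.approx(b, abs=1e-9)


# ---------------------------------------------------------------------------
# encoder phase
# ---------------------------------------------------------------------------


def test_train_encoder_bookkeeping_and_restoration(ds60):
    idx = np.arange(len(ds60))
    cfg = tf.TrainConfig(max_epochs=6, patience=5, lr=3e-3, seed=0)
    probed, log = tf.train_encoder("graph", ds60, idx, idx,
                                   tiny_graph_cfg(), cfg)
    assert list(log.columns) == ["epoch", "train_loss", "valid_auc", "best_auc"]
    # reported best validation AUC is non-decreasing over the log
    assert (np.diff(log["best_auc"].to_numpy()) >= -1e-12).all()
    # restored weights reproduce the best recorded validation AUC
    scores = _eval_scores(probed, ds60, idx)
    auc = tf.macro_roc_auc(scores, ds60.labels[idx])
    assert auc == pytest.approx(log["best_auc"].iloc[-1], abs=1e-9)


def test_train_encoder_seed_determinism(ds60):
    idx = np.arange(len(ds60))
    cfg = tf.TrainConfig(max_epochs=3, patience=2, lr=3e-3, seed=9,
                         augment_images=False)
    _, log1 = tf.train_encoder("graph", ds60, idx, idx, tiny_graph_cfg(), cfg)
    _, log2 = tf.train_encoder("graph", ds60, idx, idx, tiny_graph_cfg(), cfg)
    pd.testing.assert_frame_equal(log1, log2)


def test_train_encoder_spectrum_restricted_to_available(ds60):
    idx = np.arange(len(ds60))
    cfg = tf.TrainConfig(max_epochs=2, patience=1, lr=3e-3, seed=0)
    probed, log = tf.train_encoder("spectrum", ds60, idx, idx,
                                   tiny_spectrum_cfg(), cfg)
    assert len(log) >= 1  # trains without touching spectrum-absent records


# ---------------------------------------------------------------------------
# fusion phase
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def trained_encoders(ds60, vocab60):
    idx = np.arange(len(ds60))
    cfg = tf.TrainConfig(max_epochs=2, patience=1, lr=3e-3, seed=1)
    return {
        m: tf.train_encoder(m, ds60, idx, idx, ecfg, cfg)[0]
        for m, ecfg in (("graph", tiny_graph_cfg()),
                        ("smiles", tiny_smiles_cfg(vocab60)),
                        ("spectrum", tiny_spectrum_cfg()))
    }


def test_train_fusion_freezes_encoders_and_moves_missing_token(
        trained_encoders, ds60):
    before = {m: {k: v.copy() for k, v in p.encoder.state_dict().items()}
              for m, p in trained_encoders.items()}
    idx = np.arange(len(ds60))
    fcfg = tf.FusionConfig(common_dim=16, n_heads=2, dropout=0.0,
                           active_modalities=("graph", "smiles", "spectrum"))
    tcfg = tf.fusion_train_config(max_epochs=2, patience=1, lr=3e-3, seed=1)
    model, log = tf.train_fusion(trained_encoders, ds60, idx, idx, fcfg, tcfg)
    for m, p in trained_encoders.items():
        for k, v in p.encoder.state_dict().items():
            assert np.array_equal(v, before[m][k]), (m, k)
    # the dataset mixes spectrum-present/absent records, so the token trains
    assert np.linalg.norm(model.missing_token.data) > 0
    assert len(log) >= 1


def test_train_fusion_single_modality_path(trained_encoders, ds60):
    idx = np.arange(len(ds60))
    fcfg = tf.FusionConfig(common_dim=16, n_heads=2, dropout=0.0,
                           active_modalities=("graph",))
    tcfg = tf.fusion_train_config(max_epochs=2, patience=1, lr=3e-3, seed=2)
    model, _ = tf.train_fusion(trained_encoders, ds60, idx, idx, fcfg, tcfg)
    scores, attn = tf.fusion_scores(model, trained_encoders, ds60, idx)
    assert scores.shape == (len(idx), 12)
    assert np.allclose(attn, 1.0)


def test_train_fusion_requires_trained_encoders(trained_encoders, ds60):
    idx = np.arange(len(ds60))
    fcfg = tf.FusionConfig(active_modalities=("graph", "image"))
    with pytest.raises(ValueError, match="image"):
        tf.train_fusion(trained_encoders, ds60, idx, idx, fcfg,
                        tf.fusion_train_config(max_epochs=2, patience=1))


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------


def test_hyperparameter_search_contracts():
    space = {"lr": [1e-3, 3e-3], "dropout": [0.0, 0.1]}
    calls = []

    def fake_eval(cfg):
        calls.append(cfg)
        return cfg["lr"]

    best, trials = tf.hyperparameter_search(space, budget=1, seed=0,
                                            eval_fn=fake_eval)
    assert best == calls[0] and len(trials) == 1

    best4, trials4 = tf.hyperparameter_search(space, budget=8, seed=1,
                                              eval_fn=fake_eval)
    assert best4["lr"] == 3e-3  # maximizes the (here known) objective
    assert len(trials4) == 8
    b1, _ = tf.hyperparameter_search(space, budget=3, seed=2, eval_fn=fake_eval)
    b2, _ = tf.hyperparameter_search(space, budget=3, seed=2, eval_fn=fake_eval)
    assert b1 == b2  # seed determinism

    degenerate = {"lr": [5e-4]}
    best_d, _ = tf.hyperparameter_search(degenerate, budget=2, seed=0,
                                         eval_fn=lambda c: 0.0)
    assert best_d == {"lr": 5e-4}
    with pytest.raises(ValueError):
        tf.hyperparameter_search(space, budget=0, seed=0, eval_fn=fake_eval)
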