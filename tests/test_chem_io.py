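"""Deterministic featurization: parsing, graphs, tokens, images, spectra."""

import json

import numpy as np
import pytest

import toxfuse as tf
from toxfuse.chem_io import IMAGENET_MEAN, NODE_DIM, MISSING


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("smiles,valid,n_atoms", [
    ("CCO", True, 3),
    ("Oc1c(I)cc(Cl)c2cccnc12", True, 13),  # fused hydroxy-halo-quinoline
    ("C1CC", False, None),  # unclosed ring
    ("not a molecule", False, None),
    ("", False, None),
])
def test_parse_and_validate(smiles, valid, n_atoms):
    mol = tf.parse_and_validate(smiles)
    if valid:
        assert mol is not None and mol.GetNumAtoms() == n_atoms
    else:
        assert mol is None


# ---------------------------------------------------------------------------
# graph featurization
# ---------------------------------------------------------------------------


def test_single_heavy_atom_graph_is_edgeless():
    g = tf.featurize_graph(tf.parse_and_validate("C"))
    assert g.node_features.shape == (1, NODE_DIM)
    assert g.edge_index.shape == (2, 0)
    assert g.edge_attr.shape == (0, 4)


def test_ethanol_graph_bonds_by_hand():
    g = tf.featurize_graph(tf.parse_and_validate("CCO"))
    assert g.node_features.shape == (3, NODE_DIM)
    assert g.edge_index.shape == (2, 4)  # 2 bonds -> 4 directed edges
    single = [1.0, 0.0, 0.0, 0.0]
    assert np.array_equal(g.edge_attr, np.array([single] * 4, dtype=np.float32))
    # both directions of each bond are adjacent in the list
    assert np.array_equal(g.edge_index[:, 0], g.edge_index[::-1, 1])


def test_benzene_graph_aromatic_enumeration():
    g = tf.featurize_graph(tf.parse_and_validate("c1ccccc1"))
    assert g.node_features.shape[0] == 6
    aromatic_col = g.node_features[:, -3]  # aromatic flag slot
    assert np.all(aromatic_col == 1.0)
    assert g.edge_index.shape == (2, 12)
    aromatic = [0.0, 0.0, 0.0, 1.0]
    assert np.array_equal(g.edge_attr, np.array([aromatic] * 12, dtype=np.float32))


def test_edge_list_closed_under_reversal(records60):
    for r in records60[:20]:
        g = tf.featurize_graph(r.mol)
        fwd = {(int(s), int(d)) for s, d in g.edge_index.T}
        assert {(d, s) for s, d in fwd} == fwd
        # paired directed edges carry identical bond one-hots
        assert np.array_equal(g.edge_attr[0::2], g.edge_attr[1::2])
        assert np.all(g.edge_attr.sum(axis=1) == 1.0)


def test_featurizer_determinism(records60):
    r = records60[0]
    g1, g2 = tf.featurize_graph(r.mol), tf.featurize_graph(r.mol)
    assert np.array_equal(g1.node_features, g2.node_features)
    assert np.array_equal(g1.edge_index, g2.edge_index)


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------


def test_tokenize_bracket_and_two_char_elements():
    assert tf.tokenize("[nH]") == ["[nH]"]
    assert tf.tokenize("ClBr") == ["Cl", "Br"]
    assert tf.tokenize("CCO") == ["C", "C", "O"]


def test_tokenize_smiles_pad_truncate():
    vocab = tf.build_vocab(["CCO"])
    ts = tf.tokenize_smiles("CCO", vocab)
    assert ts.ids.shape == (202,) and ts.mask.shape == (202,)
    assert ts.mask.sum() == 3
    assert np.all(ts.ids[3:] == vocab["<pad>"])
    long = tf.tokenize_smiles("C" * 300, vocab)
    assert long.mask.sum() == 202


def test_token_mask_is_prefix_and_pad_consistent(records60, vocab60):
    rng = np.random.default_rng(0)
    tokens = [t for t in vocab60 if not t.startswith("<")]
    for _ in range(1000):
        smi = "".join(rng.choice(tokens, size=rng.integers(1, 40)))
        ts = tf.tokenize_smiles(smi, vocab60)
        n = int(ts.mask.sum())
        assert n >= 1
        assert np.all(ts.mask[:n] == 1) and np.all(ts.mask[n:] == 0)
        assert np.all(ts.ids[n:] == vocab60["<pad>"])
        assert np.all(ts.ids[:n] != vocab60["<pad>"])


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def test_render_deterministic_and_distinct():
    cco = tf.render_image(tf.parse_and_validate("CCO"))
    cco2 = tf.render_image(tf.parse_and_validate("CCO"))
    benzene = tf.render_image(tf.parse_and_validate("c1ccccc1"))
    assert cco.shape == (224, 224, 3)
    assert np.array_equal(cco, cco2)
    assert not np.array_equal(cco, benzene)
    # white background dominates a small-molecule depiction
    assert (cco == 255).all(axis=2).mean() > 0.9


def test_normalize_mean_image_gives_zero_tensor():
    img = np.ones((224, 224, 3)) * IMAGENET_MEAN
    t = tf.normalize_image(img)
    assert np.abs(t).max() < 1e-6


def test_normalize_white_image_red_channel():
    t = tf.normalize_image(np.ones((224, 224, 3)))
    assert t[0, 0, 0] == pytest.approx((1 - 0.485) / 0.229, abs=1e-4)
    assert t.shape == (3, 224, 224)


def test_normalize_roundtrip_and_determinism():
    rng = np.random.default_rng(1)
    img = rng.random((224, 224, 3))
    t1, t2 = tf.normalize_image(img), tf.normalize_image(img)
    assert np.array_equal(t1, t2)
    back = tf.denormalize_image(t1)
    assert np.abs(back - img).max() < 1e-6


def test_augmentation_uses_rng_and_keeps_shape():
    rng = np.random.default_rng(3)
    img = tf.render_image(tf.parse_and_validate("c1ccc(Cl)cc1"))
    t = tf.normalize_image(img, augment=True, rng=rng)
    assert t.shape == (3, 224, 224)
    with pytest.raises(ValueError):
        tf.normalize_image(img, augment=True, rng=None)


# ---------------------------------------------------------------------------
# spectrum binning
# ---------------------------------------------------------------------------


def test_bin_spectrum_index_arithmetic():
    bits = tf.bin_spectrum([128.5, 170.2])
    assert bits.shape == (260,)
    assert set(np.where(bits)[0]) == {148, 190}  # +20 ppm grid offset


def test_bin_spectrum_same_bin_collapse_and_clamp():
    assert tf.bin_spectrum([10.0, 10.4]).sum() == 1
    low = tf.bin_spectrum([-100.0])
    assert low[0] == 1 and low.sum() == 1
    high = tf.bin_spectrum([999.0])
    assert high[-1] == 1 and high.sum() == 1


def test_bin_spectrum_popcount_bound(records60):
    for r in records60:
        if not r.has_spectrum:
            continue
        bits = tf.bin_spectrum(r.peaks)
        assert bits.sum() <= len(r.peaks)


def test_bin_spectrum_empty_is_error():
    with pytest.raises(ValueError):
        tf.bin_spectrum([])


# ---------------------------------------------------------------------------
# dataset loading
# ---------------------------------------------------------------------------


def _write_table(path, rows):
    cols = ["id", "smiles"] + tf.ENDPOINTS
    lines = [",".join(cols)]
    for row in rows:
        lines.append(",".join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def test_load_dataset_filters_joins_and_missing(tmp_path):
    rows = [
        ["m1", "CCO"] + [1] * 12,
        ["m2", "c1ccccc1"] + [0] * 12,
        ["m3", "C1CC"] + [1] * 12,  # invalid -> dropped
        ["m4", "CC(C)=O"] + [-1] * 12,  # all missing
        ["m5", "CCN"] + [""] + [0] * 11,  # empty cell -> missing
    ]
    csv = tmp_path / "compounds.csv"
    _write_table(csv, rows)
    first = tmp_path / "first.json"
    second = tmp_path / "second.json"
    first.write_text(json.dumps({"m1": [12.0, 130.0]}))
    second.write_text(json.dumps({"m1": [99.0], "m2": [128.1]}))
    records, summary = tf.load_dataset(csv, [first, second])
    assert summary.n_rows == 5 and summary.n_valid == 4 and summary.n_rejected == 1
    assert summary.n_with_spectrum == 2
    by_id = {r.id: r for r in records}
    assert by_id["m1"].peaks == [12.0, 130.0]  # first source wins
    assert by_id["m2"].peaks == [128.1]
    assert np.all(by_id["m4"].labels == MISSING)
    assert by_id["m5"].labels[0] == MISSING and by_id["m5"].labels[1] == 0


def test_load_dataset_rejects_duplicates_and_bad_labels(tmp_path):
    csv = tmp_path / "dup.csv"
    _write_table(csv, [["a", "CCO"] + [0] * 12, ["a", "CCN"] + [1] * 12])
    with pytest.raises(ValueError, match="duplicate"):
        tf.load_dataset(csv)
    csv2 = tmp_path / "bad.csv"
    _write_table(csv2, [["a", "CCO"] + [2] + [0] * 11])
    with pytest.raises(ValueError, match="label"):
        tf.load_dataset(csv2)
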