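import numpy as np
import pytest

import toxfuse as tf


@pytest.fixture(scope="session")
def records60():
    """Small deterministic synthetic benchmark shared across tests."""
    return tf.make_records(tf.SynthConfig(n_molecules=60, seed=5))


@pytest.fixture(scope="session")
def vocab60(records60):
    return tf.build_vocab(r.smiles for r in records60)


@pytest.fixture(scope="session")
def ds60(records60, vocab60):
    return tf.FeaturizedDataset(records60, vocab60,
                                need=("graph", "smiles", "spectrum"))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def tiny_graph_cfg(**kw):
    base = dict(hidden_dim=16, n_layers=2, output_dim=12, dropout=0.0)
    base.update(kw)
    return tf.GraphEncoderConfig(**base)


def tiny_smiles_cfg(vocab, **kw):
    base = dict(hidden_dim=16, n_layers=1, n_heads=2, output_dim=12,
                dropout=0.0, vocab_size=len(vocab))
    base.update(kw)
    return tf.SmilesEncoderConfig(**base)


def tiny_spectrum_cfg(**kw):
    base = dict(conv_widths=(8, 16), backbone_dim=32, output_dim=12, dropout=0.0)
    base.update(kw)
    return tf.SpectrumEncoderConfig(**base)


def tiny_image_cfg(**kw):
    base = dict(widths=(4, 8, 8), backbone_dim=32, output_dim=12, dropout=0.0)
    base.update(kw)
    return tf.ImageEncoderConfig(**base)
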