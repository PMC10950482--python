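"""Model contract: encoding, MHSA observation point, scores, training."""

import numpy as np
import pytest

from headig.model import (
    ClassScoreFn,
    ToyEncoderConfig,
    TransformerEncoderClassifier,
    class_score,
    encode,
    mhsa_output,
    train_toy_model,
)

SEQ = "ACDEFGHIKLMNPQRSTVWYACDEF"


@pytest.fixture(scope="module")
def model():
    return TransformerEncoderClassifier(ToyEncoderConfig(seed=11))


def test_encode_shape_and_special_token_mask(model):
    enc = encode(model, SEQ)
    assert enc.length == len(SEQ) + 2
    assert enc.special_mask.sum() == 2
    assert enc.special_mask[0] and enc.special_mask[-1]
    assert enc.embedding.shape == (len(SEQ) + 2, model.d_model)


def test_encode_rejects_empty_and_unknown_tokens(model):
    with pytest.raises(ValueError, match="empty"):
        encode(model, "")
    with pytest.raises(ValueError, match=r"'1' at position 3"):
        encode(model, "AC1DEF")
    with pytest.raises(ValueError, match="max_seq_len"):
        encode(model, "A" * (model.max_seq_len + 1))


def test_encode_is_deterministic(model):
    e1, e2 = encode(model, SEQ), encode(model, SEQ)
    np.testing.assert_array_equal(e1.embedding, e2.embedding)


def test_mhsa_output_shape_and_bounds(model):
    enc = encode(model, SEQ)
    out = mhsa_output(model, enc, 0)
    assert out.shape == enc.embedding.shape
    with pytest.raises(ValueError, match="out of range"):
        mhsa_output(model, enc, model.n_layers)


def test_zeroing_one_heads_value_projection_zeroes_exactly_its_block():
    m = TransformerEncoderClassifier(ToyEncoderConfig(seed=11))
    dh = m.head_dim
    h = 1
    m.params["0.Wv"][:, h * dh : (h + 1) * dh] = 0.0
    m.params["0.bv"][h * dh : (h + 1) * dh] = 0.0
    out = mhsa_output(m, m.encode(SEQ), 0)
    assert np.abs(out[:, h * dh : (h + 1) * dh]).max() == 0.0
    for other in (0, 2, 3):
        assert np.abs(out[:, other * dh : (other + 1) * dh]).max() > 0.0


def test_block_locality_of_head_parameters():
    """Perturbing head h's value weights changes only block h of the output."""
    base = TransformerEncoderClassifier(ToyEncoderConfig(seed=11))
    pert = TransformerEncoderClassifier(ToyEncoderConfig(seed=11))
    dh = base.head_dim
    h = 2
    pert.params["0.Wv"][:, h * dh : (h + 1) * dh] += 0.5
    enc = base.encode(SEQ)
    diff = mhsa_output(pert, enc, 0) - mhsa_output(base, enc, 0)
    changed = np.abs(diff).max(axis=0) > 1e-12
    expected = np.zeros(base.d_model, dtype=bool)
    expected[h * dh : (h + 1) * dh] = True
    np.testing.assert_array_equal(changed, expected)


def test_class_score_kinds_and_validation(model):
    enc = encode(model, SEQ)
    prob = class_score(model, enc, ClassScoreFn(0, "probability"))
    assert 0.0 <= prob <= 1.0
    logits = [class_score(model, enc, ClassScoreFn(c, "logit")) for c in (0, 1)]
    probs = [class_score(model, enc, ClassScoreFn(c, "probability")) for c in (0, 1)]
    # softmax is monotone per class: the larger logit has the larger probability
    assert (logits[0] > logits[1]) == (probs[0] > probs[1])
    with pytest.raises(ValueError, match="class index"):
        class_score(model, enc, ClassScoreFn(model.n_classes, "logit"))
    with pytest.raises(ValueError, match="score_kind"):
        ClassScoreFn(0, "oddity")


def test_forward_batch_rows_are_independent(model):
    enc = encode(model, SEQ)
    other = encode(model, SEQ[::-1])
    both = np.stack([enc.embedding, other.embedding])
    fp = model.forward_batch(both, ClassScoreFn(1, "logit"))
    single = model.forward_batch(enc.embedding, ClassScoreFn(1, "logit"))
    np.testing.assert_allclose(fp.scores[0], single.scores[0], atol=1e-12)
    np.testing.assert_allclose(fp.grad_embedding[0], single.grad_embedding[0],
                               atol=1e-12)


def test_checkpoint_roundtrip(tmp_path, model):
    path = tmp_path / "toy.npz"
    model.save(path)
    loaded = TransformerEncoderClassifier.load(path)
    assert loaded.config == model.config
    enc = encode(model, SEQ)
    np.testing.assert_array_equal(
        mhsa_output(model, enc, 1), mhsa_output(loaded, enc, 1)
    )


def _tiny_data(rng, n=24, n_classes=2):
    seqs, labels = [], []
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    while len(seqs) < n:
        s = "".join(rng.choice(list(alphabet), size=20))
        if s not in seqs:
            seqs.append(s)
            labels.append(len(seqs) % n_classes)
    return seqs, labels


def test_training_is_deterministic_given_seed():
    rng = np.random.default_rng(0)
    seqs, labels = _tiny_data(rng)
    cfg = ToyEncoderConfig(n_layers=1, d_model=32, d_ff=32, seed=5)
    kw = dict(config=cfg, seed=5, epochs=2, batch_size=8)
    r1 = train_toy_model(seqs[:16], labels[:16], seqs[16:], labels[16:], **kw)
    r2 = train_toy_model(seqs[:16], labels[:16], seqs[16:], labels[16:], **kw)
    for k in r1.model.params:
        np.testing.assert_array_equal(r1.model.params[k], r2.model.params[k])
    assert r1.losses == r2.losses


def test_training_rejects_train_test_overlap():
    rng = np.random.default_rng(1)
    seqs, labels = _tiny_data(rng)
    with pytest.raises(ValueError, match="overlap"):
        train_toy_model(seqs, labels, seqs[:4], labels[:4], epochs=1)
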