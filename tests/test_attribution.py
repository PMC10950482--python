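"""Integrated gradients: closed forms, completeness, conservation, oracles.

`AffineContractModel` is an independently coded implementation of the model
contract (a purely linear encoder) — attribution must run against the
contract alone, and on affine scores IG has a closed form that holds for
any step count.
"""

import numpy as np
import pytest

from headig.attribution import (
    PathSpec,
    attribute_all,
    encoded_path,
    ig_embedding,
    ig_layer_headwise,
    reduce_heads,
)
from headig.model import (
    AttributionModel,
    ClassScoreFn,
    EncodedSequence,
    ForwardPass,
    SeveredSkipModel,
    ToyEncoderConfig,
    TransformerEncoderClassifier,
    Vocabulary,
)

SEQ = "ACDEFGHIKLMNPQRSTVWY"


class AffineContractModel(AttributionModel):
    """Second, independent contract implementation: everything is linear.

    'MHSA output' is emb @ A (blocks of A's columns belong to heads), the
    score is w . mhsa + b — affine in the embedding, so embedding IG equals
    w_eff * (x - x') exactly and the encoded path is a straight line.
    """

    def __init__(self, seed=0, d_model=8, n_heads=2, max_seq_len=40):
        rng = np.random.default_rng(seed)
        self.vocab = Vocabulary()
        self.n_layers = 1
        self.n_heads = n_heads
        self.d_model = d_model
        self.n_classes = 1
        self.max_seq_len = max_seq_len
        self.A = rng.normal(size=(d_model, d_model))
        self.w = rng.normal(size=d_model)
        self.b = 0.7
        self.emb_table = rng.normal(size=(len(self.vocab), d_model))

    def encode(self, sequence):
        ids = np.concatenate(([self.vocab.cls_id],
                              self.vocab.encode_residues(sequence),
                              [self.vocab.eos_id]))
        special = np.isin(ids, [self.vocab.cls_id, self.vocab.eos_id,
                                self.vocab.pad_id, self.vocab.mask_id])
        return EncodedSequence(ids, self.emb_table[ids], special, sequence)

    def baseline_embedding(self, encoded, kind="padding_embedding"):
        base = encoded.embedding.copy()
        if kind == "zero_embedding":
            base[encoded.residue_positions] = 0.0
        else:
            base[encoded.residue_positions] = self.emb_table[self.vocab.pad_id]
        return base

    def forward_batch(self, embeddings, fn, need_grads=True):
        embeddings = np.asarray(embeddings, dtype=np.float64)
        if embeddings.ndim == 2:
            embeddings = embeddings[None]
        mhsa = embeddings @ self.A
        scores = mhsa @ self.w + self.b  # (B, L)
        scores = scores.sum(axis=1)
        if not need_grads:
            return ForwardPass(scores, scores[:, None], None, [mhsa], None)
        grad_mhsa = np.broadcast_to(self.w, mhsa.shape).copy()
        grad_emb = np.broadcast_to(self.A @ self.w, embeddings.shape).copy()
        return ForwardPass(scores, scores[:, None], grad_emb, [mhsa], [grad_mhsa])


@pytest.fixture(scope="module")
def toy():
    return TransformerEncoderClassifier(ToyEncoderConfig(seed=3))


# ---------------------------------------------------------------------------
# embedding-level IG
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("steps", [1, 4, 64])
def test_affine_model_ig_matches_closed_form_for_any_step_count(steps):
    model = AffineContractModel(seed=1)
    enc = model.encode(SEQ)
    spec = PathSpec(steps=steps)
    amap, per_token = ig_embedding(model, enc, ClassScoreFn(0), spec)
    delta = enc.embedding - model.baseline_embedding(enc)
    expected = delta * (model.A @ model.w)
    np.testing.assert_allclose(amap.values, expected, atol=1e-10)
    np.testing.assert_allclose(per_token, expected.sum(axis=1), atol=1e-10)
    assert amap.completeness_gap < 1e-9


def test_baseline_sample_identity_gives_zero_map(toy):
    enc = toy.encode(SEQ)
    spec = PathSpec(baseline_kind="custom", custom_baseline=enc.embedding, steps=8)
    amap, per_token = ig_embedding(toy, enc, ClassScoreFn(0), spec)
    np.testing.assert_array_equal(amap.values, 0.0)
    np.testing.assert_array_equal(per_token, 0.0)


def test_per_token_relevance_converges_with_step_count(toy):
    fn = ClassScoreFn(0, "logit")
    _, coarse = ig_embedding(toy, SEQ, fn, PathSpec(steps=16))
    _, mid = ig_embedding(toy, SEQ, fn, PathSpec(steps=64))
    _, fine = ig_embedding(toy, SEQ, fn, PathSpec(steps=512))
    err_coarse = np.abs(coarse - fine).max()
    err_mid = np.abs(mid - fine).max()
    assert err_mid < err_coarse
    assert err_mid < 1e-3


def test_ig_embedding_matches_independent_naive_implementation(toy):
    """Loop-based trapezoid IG, one forward/backward per alpha node."""
    fn = ClassScoreFn(1, "logit")
    m = 32
    enc = toy.encode(SEQ)
    x = enc.embedding
    x0 = toy.baseline_embedding(enc)
    grads = []
    for k in range(m + 1):
        emb = x0 + (k / m) * (x - x0)
        grads.append(toy.forward_batch(emb[None], fn).grad_embedding[0])
    grads = np.array(grads)
    naive = (0.5 * (grads[:-1] + grads[1:])).mean(axis=0) * (x - x0)
    amap, _ = ig_embedding(toy, enc, fn, PathSpec(steps=m))
    rel = np.abs(naive - amap.values).max() / np.abs(naive).max()
    assert rel < 1e-10


def test_completeness_gap_small_on_toy_model(toy):
    amap, _ = ig_embedding(toy, SEQ, ClassScoreFn(0), PathSpec(steps=256))
    dF = abs(amap.score - amap.baseline_score)
    assert amap.completeness_gap < 0.01 * dF


def test_special_token_positions_have_zero_attribution(toy):
    """Specials are identical in sample and baseline, so the straight path
    never moves them and they receive exactly zero embedding relevance."""
    amap, per_token = ig_embedding(toy, SEQ, ClassScoreFn(0), PathSpec(steps=8))
    assert per_token[amap.special_mask] == pytest.approx(0.0, abs=1e-15)
    assert amap.residue_relevance.shape == (len(SEQ),)


# ---------------------------------------------------------------------------
# encoded paths + layer IG
# ---------------------------------------------------------------------------

def test_encoded_path_endpoints_match_direct_forward(toy):
    enc = toy.encode(SEQ)
    path = encoded_path(toy, 1, enc, PathSpec(steps=5))
    assert path.shape[0] == 6
    fp_base = toy.forward_batch(toy.baseline_embedding(enc)[None],
                                ClassScoreFn(0), need_grads=False)
    fp_samp = toy.forward_batch(enc.embedding[None], ClassScoreFn(0),
                                need_grads=False)
    np.testing.assert_allclose(path[0], fp_base.mhsa[1][0], atol=1e-12)
    np.testing.assert_allclose(path[-1], fp_samp.mhsa[1][0], atol=1e-12)


def test_encoded_path_m1_is_exactly_the_two_endpoints(toy):
    p1 = encoded_path(toy, 0, SEQ, PathSpec(steps=1))
    p4 = encoded_path(toy, 0, SEQ, PathSpec(steps=4))
    assert p1.shape[0] == 2
    np.testing.assert_allclose(p1[0], p4[0], atol=1e-12)
    np.testing.assert_allclose(p1[1], p4[-1], atol=1e-12)


def test_linear_model_encoded_path_is_collinear():
    model = AffineContractModel(seed=2)
    path = encoded_path(model, 0, SEQ, PathSpec(steps=6))
    inc = np.diff(path, axis=0).reshape(6, -1)
    first = inc[0] / np.linalg.norm(inc[0])
    for row in inc[1:]:
        cos = row @ first / np.linalg.norm(row)
        assert cos == pytest.approx(1.0, abs=1e-12)


def test_layer_ig_zero_for_identical_baseline(toy):
    enc = toy.encode(SEQ)
    spec = PathSpec(baseline_kind="custom", custom_baseline=enc.embedding, steps=4)
    lmap, hmap = ig_layer_headwise(toy, 0, enc, ClassScoreFn(0), spec)
    np.testing.assert_array_equal(lmap.values, 0.0)
    np.testing.assert_array_equal(hmap.values, 0.0)


def test_severed_skip_layer_attribution_is_complete():
    """With the skip removed and a linear readout, the MHSA output is the
    only path, so layer attributions must sum to F(x) - F(x')."""
    model = SeveredSkipModel(n_heads=2, d_model=16, seed=4)
    lmap, _ = ig_layer_headwise(model, 0, SEQ, ClassScoreFn(0), PathSpec(steps=128))
    dF = lmap.score - lmap.baseline_score
    assert abs(lmap.values.sum() - dF) < 0.01 * abs(dF)


def test_layer_out_of_range_rejected(toy):
    with pytest.raises(ValueError, match="out of range"):
        ig_layer_headwise(toy, toy.n_layers, SEQ, ClassScoreFn(0))
    with pytest.raises(ValueError, match="out of range"):
        encoded_path(toy, -1, SEQ)


# ---------------------------------------------------------------------------
# head reduction
# ---------------------------------------------------------------------------

def _as_layer_map(values):
    from headig.attribution import AttributionMap

    L = values.shape[0]
    return AttributionMap(0, values, np.zeros(L, dtype=bool), 0.0, 0.0, 0.0)


def test_reduce_heads_block_sum_arithmetic():
    amap = _as_layer_map(np.array([[1.0, 2.0, 3.0, 4.0]]))
    hmap = reduce_heads(amap, 2)
    np.testing.assert_array_equal(hmap.values, [[3.0, 7.0]])


def test_reduce_heads_conserves_totals_on_random_maps():
    rng = np.random.default_rng(0)
    for _ in range(20):
        vals = rng.normal(size=(7, 12))
        hmap = reduce_heads(_as_layer_map(vals), 3)
        np.testing.assert_allclose(hmap.values.sum(axis=1), vals.sum(axis=1),
                                   atol=1e-12)
        assert hmap.values.sum() == pytest.approx(vals.sum())


def test_reduce_heads_rejects_indivisible_width():
    with pytest.raises(ValueError, match="divisible"):
        reduce_heads(_as_layer_map(np.ones((3, 10))), 4)


def test_attribute_all_consistency(toy):
    """One path sweep: head maps conserve their layer maps per position and
    the embedding map agrees with the standalone entry point."""
    fn = ClassScoreFn(0)
    bundle = attribute_all(toy, SEQ, fn, PathSpec(steps=16))
    standalone, _ = ig_embedding(toy, SEQ, fn, PathSpec(steps=16))
    np.testing.assert_allclose(bundle.embedding_map.values, standalone.values,
                               atol=1e-12)
    for lmap, hmap in zip(bundle.layer_maps, bundle.head_maps):
        np.testing.assert_allclose(hmap.values.sum(axis=1),
                                   lmap.values.sum(axis=1), atol=1e-12)
    assert bundle.summed_matrix().shape == (toy.n_layers, toy.n_heads)


def test_contract_sufficiency_headwise_on_affine_model():
    """Layer IG through the independent contract: on the affine model the
    layer attribution equals w * (mhsa(x) - mhsa(x')) exactly."""
    model = AffineContractModel(seed=5)
    enc = model.encode(SEQ)
    lmap, hmap = ig_layer_headwise(model, 0, enc, ClassScoreFn(0), PathSpec(steps=3))
    delta_h = (enc.embedding - model.baseline_embedding(enc)) @ model.A
    np.testing.assert_allclose(lmap.values, model.w * delta_h, atol=1e-10)
    np.testing.assert_allclose(hmap.values.sum(axis=1), (model.w * delta_h).sum(axis=1),
                               atol=1e-10)
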