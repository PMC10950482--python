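"""Integrated-gradients attribution, at the embedding layer and per head.

The attribution for feature i is the line integral of the score gradient
along a path gamma from a baseline x' (gamma(0)) to the sample x (gamma(1)):

    IG_i = integral_0^1  dF(gamma(a))/dgamma_i * dgamma_i/da  da

For embedding-level attribution the path is the conventional straight line
in embedding space. For head-specific attribution the target is a layer's
multi-head self-attention (MHSA) output, *before* the output projection:
the same straight embedding path is pushed through the encoder and becomes
a generally curvilinear path h(a) at the MHSA output. Keeping the single
embedding-anchored path for every layer is what makes attributions across
layers comparable (it varies the skip-connection input consistently); the
price is only the symmetry axiom, not completeness or sensitivity.

The integral is discretized on a uniform alpha grid. The layer integral is
a Riemann-Stieltjes sum: gradients wrt the MHSA output contracted with
finite differences of h(a). Summing contiguous blocks of width
d_model/n_heads over the feature axis reduces a seq x d_model layer map to
a seq x n_heads map — one relevance sequence per head — because the
pre-projection MHSA output is the concatenation of per-head outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AttributionModel, ClassScoreFn, EncodedSequence

__all__ = [
    "PathSpec",
    "AttributionMap",
    "HeadAttributionMap",
    "AttributionBundle",
    "ig_embedding",
    "ig_layer_headwise",
    "encoded_path",
    "reduce_heads",
    "attribute_all",
]


@dataclass(frozen=True)
class PathSpec:
    """Straight-line integration path specification.

    baseline_kind: "padding_embedding" (default; the conventional 'absence'
    token, in-distribution for sequence models), "zero_embedding", or
    "custom" with an explicit baseline array.
    """

    baseline_kind: str = "padding_embedding"
    steps: int = 64
    rule: str = "trapezoid"  # "trapezoid" | "left_riemann"
    custom_baseline: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.rule not in ("trapezoid", "left_riemann"):
            raise ValueError(f"unknown integration rule {self.rule!r}")
        if self.baseline_kind == "custom" and self.custom_baseline is None:
            raise ValueError("custom baseline requires custom_baseline array")

    def baseline_for(self, model: AttributionModel, enc: EncodedSequence) -> np.ndarray:
        if self.baseline_kind == "custom":
            base = np.asarray(self.custom_baseline, dtype=np.float64)
            if base.shape != enc.embedding.shape:
                raise ValueError(
                    f"custom baseline shape {base.shape} != embedding shape "
                    f"{enc.embedding.shape}"
                )
            return base
        return model.baseline_embedding(enc, self.baseline_kind)


@dataclass
class AttributionMap:
    """Signed relevance per position and feature dimension for one layer."""

    layer: int | str                 # layer index or "embedding"
    values: np.ndarray               # (L, d_model)
    special_mask: np.ndarray         # (L,) bool
    score: float                     # F(x)
    baseline_score: float            # F(x')
    completeness_gap: float = np.nan # |sum(values) - (F(x) - F(x'))|

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("attribution map contains non-finite entries")

    @property
    def per_token(self) -> np.ndarray:
        """Per-position relevance: sum over the feature axis, (L,)."""
        return self.values.sum(axis=1)

    @property
    def residue_relevance(self) -> np.ndarray:
        """Per-residue relevance with special-token positions removed."""
        return self.per_token[~self.special_mask]


@dataclass
class HeadAttributionMap:
    """Per-position, per-head relevance for one layer, (L, n_heads)."""

    layer: int
    values: np.ndarray
    special_mask: np.ndarray

    @property
    def residue_values(self) -> np.ndarray:
        return self.values[~self.special_mask]

    def summed(self) -> np.ndarray:
        """Relevance per head summed along the sequence (residues only)."""
        return self.residue_values.sum(axis=0)


@dataclass
class AttributionBundle:
    """All maps of one (sequence, class) pair from a single path sweep."""

    sequence_id: str
    class_index: int
    embedding_map: AttributionMap
    layer_maps: list[AttributionMap]
    head_maps: list[HeadAttributionMap]
    special_mask: np.ndarray

    def summed_matrix(self) -> np.ndarray:
        """n_layers x n_heads matrix of sequence-summed head relevances."""
        return np.stack([hm.summed() for hm in self.head_maps])


def _resolve(model: AttributionModel, tokens: str | EncodedSequence) -> EncodedSequence:
    return tokens if isinstance(tokens, EncodedSequence) else model.encode(tokens)


def _path_sweep(
    model: AttributionModel,
    enc: EncodedSequence,
    fn: ClassScoreFn,
    path: PathSpec,
    need_grads: bool = True,
    chunk: int = 64,
):
    """Forward (and backward) passes at all alpha nodes of the path.

    Returns (alphas, scores, grad_emb, mhsa_values, mhsa_grads) where the
    stacked arrays have leading dimension m+1.
    """
    x = enc.embedding
    x0 = path.baseline_for(model, enc)
    m = path.steps
    alphas = np.linspace(0.0, 1.0, m + 1)
    embs = x0[None] + alphas[:, None, None] * (x - x0)[None]
    scores = np.empty(m + 1)
    grad_emb = np.empty_like(embs) if need_grads else None
    n_layers = model.n_layers
    mhsa_vals = [np.empty_like(embs[..., : model.d_model]) for _ in range(n_layers)]
    mhsa_grads = (
        [np.empty_like(embs[..., : model.d_model]) for _ in range(n_layers)]
        if need_grads
        else None
    )
    for start in range(0, m + 1, chunk):
        sl = slice(start, min(start + chunk, m + 1))
        fp = model.forward_batch(embs[sl], fn, need_grads=need_grads)
        scores[sl] = fp.scores
        for l in range(n_layers):
            mhsa_vals[l][sl] = fp.mhsa[l]
        if need_grads:
            grad_emb[sl] = fp.grad_embedding
            for l in range(n_layers):
                mhsa_grads[l][sl] = fp.mhsa_grads[l]
    if not np.all(np.isfinite(scores)):
        bad = int(np.flatnonzero(~np.isfinite(scores))[0])
        raise FloatingPointError(f"non-finite score at alpha step {bad}")
    return alphas, scores, grad_emb, mhsa_vals, mhsa_grads


def _integrate_straight(
    grads: np.ndarray, delta: np.ndarray, rule: str
) -> np.ndarray:
    """IG along the straight embedding path: integral(grad) * (x - x')."""
    m = grads.shape[0] - 1
    if rule == "trapezoid":
        w = np.full(m + 1, 1.0 / m)
        w[0] = w[-1] = 0.5 / m
    else:  # left_riemann
        w = np.full(m + 1, 1.0 / m)
        w[-1] = 0.0
    avg_grad = np.tensordot(w, grads, axes=(0, 0))
    return avg_grad * delta


def _integrate_stieltjes(
    grads: np.ndarray, values: np.ndarray, rule: str
) -> np.ndarray:
    """Riemann-Stieltjes sum: gradients contracted with increments of h(a)."""
    dh = np.diff(values, axis=0)
    if rule == "trapezoid":
        g = 0.5 * (grads[:-1] + grads[1:])
    else:
        g = grads[:-1]
    return (g * dh).sum(axis=0)


def ig_embedding(
    model: AttributionModel,
    tokens: str | EncodedSequence,
    fn: ClassScoreFn,
    path: PathSpec = PathSpec(),
) -> tuple[AttributionMap, np.ndarray]:
    """Embedding-level integrated gradients.

    Returns the full (L, d_model) map and its per-token reduction; the map
    carries the completeness gap |sum(IG) - (F(x) - F(x'))|.
    """
    enc = _resolve(model, tokens)
    _, scores, grad_emb, _, _ = _path_sweep(model, enc, fn, path)
    delta = enc.embedding - path.baseline_for(model, enc)
    values = _integrate_straight(grad_emb, delta, path.rule)
    gap = abs(values.sum() - (scores[-1] - scores[0]))
    amap = AttributionMap(
        layer="embedding",
        values=values,
        special_mask=enc.special_mask,
        score=float(scores[-1]),
        baseline_score=float(scores[0]),
        completeness_gap=float(gap),
    )
    return amap, amap.per_token


def encoded_path(
    model: AttributionModel,
    layer: int,
    tokens: str | EncodedSequence,
    path: PathSpec = PathSpec(),
) -> np.ndarray:
    """The MHSA-output trajectory h(alpha_k), shape (m+1, L, d_model).

    h(alpha_0) is the MHSA output at the baseline embedding and h(alpha_m)
    at the sample embedding; in between the path is generally curvilinear.
    """
    if not (0 <= layer < model.n_layers):
        raise ValueError(f"layer {layer} out of range [0, {model.n_layers})")
    enc = _resolve(model, tokens)
    _, _, _, mhsa_vals, _ = _path_sweep(model, enc, fn=ClassScoreFn(0, "logit"),
                                        path=path, need_grads=False)
    return mhsa_vals[layer]


def reduce_heads(amap: AttributionMap, n_heads: int) -> HeadAttributionMap:
    """Sum contiguous feature blocks of width d_model/n_heads per head."""
    L, d = amap.values.shape
    if d % n_heads:
        raise ValueError(f"d_model={d} not divisible by n_heads={n_heads}")
    if amap.layer == "embedding":
        raise ValueError("head reduction applies to layer maps, not embedding maps")
    values = amap.values.reshape(L, n_heads, d // n_heads).sum(axis=2)
    return HeadAttributionMap(int(amap.layer), values, amap.special_mask)


def ig_layer_headwise(
    model: AttributionModel,
    layer: int,
    tokens: str | EncodedSequence,
    fn: ClassScoreFn,
    path: PathSpec = PathSpec(),
) -> tuple[AttributionMap, HeadAttributionMap]:
    """Layer IG at one MHSA output, plus its per-head block reduction."""
    if not (0 <= layer < model.n_layers):
        raise ValueError(f"layer {layer} out of range [0, {model.n_layers})")
    enc = _resolve(model, tokens)
    _, scores, _, mhsa_vals, mhsa_grads = _path_sweep(model, enc, fn, path)
    values = _integrate_stieltjes(mhsa_grads[layer], mhsa_vals[layer], path.rule)
    amap = AttributionMap(
        layer=layer,
        values=values,
        special_mask=enc.special_mask,
        score=float(scores[-1]),
        baseline_score=float(scores[0]),
        completeness_gap=float(abs(values.sum() - (scores[-1] - scores[0]))),
    )
    return amap, reduce_heads(amap, model.n_heads)


def attribute_all(
    model: AttributionModel,
    tokens: str | EncodedSequence,
    fn: ClassScoreFn,
    path: PathSpec = PathSpec(),
    sequence_id: str = "",
) -> AttributionBundle:
    """Embedding map plus every layer's head map from one path sweep.

    All layers share the identical alpha grid and embedding endpoints, so
    the per-layer attributions are mutually consistent by construction.
    """
    enc = _resolve(model, tokens)
    _, scores, grad_emb, mhsa_vals, mhsa_grads = _path_sweep(model, enc, fn, path)
    delta = enc.embedding - path.baseline_for(model, enc)
    emb_values = _integrate_straight(grad_emb, delta, path.rule)
    emb_map = AttributionMap(
        layer="embedding",
        values=emb_values,
        special_mask=enc.special_mask,
        score=float(scores[-1]),
        baseline_score=float(scores[0]),
        completeness_gap=float(abs(emb_values.sum() - (scores[-1] - scores[0]))),
    )
    layer_maps: list[AttributionMap] = []
    head_maps: list[HeadAttributionMap] = []
    for l in range(model.n_layers):
        values = _integrate_stieltjes(mhsa_grads[l], mhsa_vals[l], path.rule)
        lmap = AttributionMap(
            layer=l,
            values=values,
            special_mask=enc.special_mask,
            score=float(scores[-1]),
            baseline_score=float(scores[0]),
            completeness_gap=float(abs(values.sum() - (scores[-1] - scores[0]))),
        )
        layer_maps.append(lmap)
        head_maps.append(reduce_heads(lmap, model.n_heads))
    return AttributionBundle(
        sequence_id=sequence_id or getattr(enc, "sequence", ""),
        class_index=fn.class_index,
        embedding_map=emb_map,
        layer_maps=layer_maps,
        head_maps=head_maps,
        special_mask=enc.special_mask,
    )
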