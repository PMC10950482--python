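"""Toy transformer encoder and the model contract used by attribution.

The contract (`AttributionModel`) is what the attribution engine sees: a
model exposes its geometry (layers, heads, model width), token encoding
into an embedding matrix, and a batched forward pass that returns the class
score together with gradients with respect to the embeddings and to every
layer's multi-head self-attention (MHSA) output.

The MHSA observation point is the concatenation of the per-head outputs
*before* the output projection, so contiguous blocks of width
``d_model / n_heads`` in the last dimension belong to single heads. This is
what makes the block-wise reduction of a layer attribution map to per-head
relevance meaningful; after the output projection the heads are mixed.

`TransformerEncoderClassifier` is a small BERT-style encoder (post-layer-norm,
GELU feed-forward, learned positions, CLS pooling) trained from scratch with
Adam on protein classification; it is deliberately desk-scale (default
2 layers x 4 heads x 64 dims) so exhaustive per-head analyses run in seconds.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._autodiff import Tensor, concat, gelu, layer_norm, softmax

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

CLS, EOS, PAD, MASK = "[CLS]", "[EOS]", "[PAD]", "[MASK]"
SPECIAL_TOKENS = (CLS, EOS, PAD, MASK)


class Vocabulary:
    """Residue tokens (20 amino acids + X) plus the four special tokens."""

    def __init__(self) -> None:
        self.tokens: tuple[str, ...] = SPECIAL_TOKENS + tuple(PROTEIN_ALPHABET) + ("X",)
        self.index = {t: i for i, t in enumerate(self.tokens)}
        self.cls_id = self.index[CLS]
        self.eos_id = self.index[EOS]
        self.pad_id = self.index[PAD]
        self.mask_id = self.index[MASK]

    def __len__(self) -> int:
        return len(self.tokens)

    def encode_residues(self, sequence: str) -> np.ndarray:
        """Map a residue string to token ids; reject unknown symbols by name."""
        if len(sequence) == 0:
            raise ValueError("cannot encode an empty sequence")
        ids = np.empty(len(sequence), dtype=np.int64)
        for pos, ch in enumerate(sequence):
            tid = self.index.get(ch)
            if tid is None or ch in SPECIAL_TOKENS:
                raise ValueError(
                    f"unknown residue token {ch!r} at position {pos + 1} (1-based)"
                )
            ids[pos] = tid
        return ids


@dataclass(frozen=True)
class ClassScoreFn:
    """The scalar function F to explain: one class's logit or probability."""

    class_index: int
    score_kind: str = "logit"  # "logit" | "probability"

    def __post_init__(self) -> None:
        if self.score_kind not in ("logit", "probability"):
            raise ValueError(f"unknown score_kind {self.score_kind!r}")


@dataclass
class EncodedSequence:
    """A tokenized sequence with its embedding and special-token bookkeeping."""

    token_ids: np.ndarray          # (L,) including [CLS] ... [EOS]
    embedding: np.ndarray          # (L, d_model)
    special_mask: np.ndarray       # (L,) bool, True at special-token positions
    sequence: str

    @property
    def length(self) -> int:
        return int(self.token_ids.shape[0])

    @property
    def residue_positions(self) -> np.ndarray:
        return np.flatnonzero(~self.special_mask)


@dataclass
class ForwardPass:
    """Scores plus (optionally) gradients at the embedding and MHSA nodes."""

    scores: np.ndarray                        # (B,)
    logits: np.ndarray                        # (B, n_classes)
    grad_embedding: np.ndarray | None         # (B, L, d_model)
    mhsa: list[np.ndarray]                    # per layer, (B, L, d_model)
    mhsa_grads: list[np.ndarray] | None       # per layer, (B, L, d_model)


class AttributionModel(ABC):
    """Contract every attribution target must satisfy."""

    vocab: Vocabulary
    n_layers: int
    n_heads: int
    d_model: int
    n_classes: int
    max_seq_len: int

    @property
    def head_dim(self) -> int:
        if self.d_model % self.n_heads:
            raise ValueError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
            )
        return self.d_model // self.n_heads

    @abstractmethod
    def encode(self, sequence: str) -> EncodedSequence:
        """Tokenize + embed one residue string."""

    @abstractmethod
    def baseline_embedding(
        self, encoded: EncodedSequence, kind: str = "padding_embedding"
    ) -> np.ndarray:
        """Baseline x' for the IG path: residue positions replaced by the
        'absence' embedding (padding token or zeros); special tokens kept."""

    @abstractmethod
    def forward_batch(
        self,
        embeddings: np.ndarray,
        fn: ClassScoreFn,
        need_grads: bool = True,
    ) -> ForwardPass:
        """Run (B, L, d_model) embeddings through the network.

        Returns the class scores and, if requested, gradients of the summed
        score with respect to the embeddings and to each layer's MHSA
        output (rows of the batch are independent, so the summed-score
        gradient restricted to sample b equals that sample's gradient).
        """


# ---------------------------------------------------------------------------
# Toy encoder
# ---------------------------------------------------------------------------

@dataclass
class ToyEncoderConfig:
    n_layers: int = 2
    n_heads: int = 4
    d_model: int = 64
    d_ff: int = 128
    n_classes: int = 2
    max_seq_len: int = 128
    dropout: float = 0.0
    positional: str = "sinusoidal"   # "sinusoidal" | "learned"
    pooling: str = "mean"            # "mean" | "cls"
    attention_init: str = "local"    # "local" | "random"
    local_init_gain: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


class TransformerEncoderClassifier(AttributionModel):
    """BERT-style encoder classifier, parameters initialized from the seed."""

    def __init__(self, config: ToyEncoderConfig):
        self.config = config
        self.vocab = Vocabulary()
        self.n_layers = config.n_layers
        self.n_heads = config.n_heads
        self.d_model = config.d_model
        self.n_classes = config.n_classes
        self.max_seq_len = config.max_seq_len
        self.params: dict[str, np.ndarray] = self._init_params(config)

    def _init_params(self, cfg: ToyEncoderConfig) -> dict[str, np.ndarray]:
        rng = np.random.default_rng(cfg.seed)
        d, ff = cfg.d_model, cfg.d_ff

        def xavier(fan_in: int, fan_out: int) -> np.ndarray:
            std = np.sqrt(2.0 / (fan_in + fan_out))
            return rng.normal(0.0, std, size=(fan_in, fan_out))

        # unit-scale embeddings + Xavier weights give O(1) attention logits
        # at initialization; without an embedding layer-norm, tiny BERT-style
        # 0.02 scales leave first-layer attention uniform and untrainable
        p: dict[str, np.ndarray] = {}
        if cfg.positional == "learned":
            p["tok_emb"] = rng.normal(0.0, 1.0, size=(len(self.vocab), d))
            p["pos_emb"] = rng.normal(0.0, 1.0, size=(cfg.max_seq_len, d))
        elif cfg.positional == "sinusoidal":
            # concatenated (not additive) sinusoids: positions occupy the
            # first d/2 dims, token identity the rest. Relative offsets of
            # sinusoids are expressible as linear maps, and keeping them in
            # their own subspace lets attention form clean position kernels
            tok = np.zeros((len(self.vocab), d))
            tok[:, d // 2 :] = rng.normal(0.0, 1.0, size=(len(self.vocab), d // 2))
            p["tok_emb"] = tok
            pos = np.arange(cfg.max_seq_len)[:, None]
            pe = np.zeros((cfg.max_seq_len, d))
            angles = pos * self._pe_freqs(cfg)[None, :]
            d_pe = d // 2
            pe[:, 0 : d_pe : 2] = np.sin(angles)
            pe[:, 1 : d_pe : 2] = np.cos(angles)
            p["pos_emb"] = pe
        else:
            raise ValueError(f"unknown positional kind {cfg.positional!r}")
        for l in range(cfg.n_layers):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[f"{l}.{name}"] = xavier(d, d)
            if cfg.attention_init == "local":
                if cfg.positional != "sinusoidal":
                    raise ValueError("local attention init needs sinusoidal PE")
                self._apply_local_attention_init(p, l, cfg, rng)
            elif cfg.attention_init != "random":
                raise ValueError(f"unknown attention_init {cfg.attention_init!r}")
            for name in ("bq", "bk", "bv", "bo"):
                p[f"{l}.{name}"] = np.zeros(d)
            p[f"{l}.ln1_g"] = np.ones(d)
            p[f"{l}.ln1_b"] = np.zeros(d)
            p[f"{l}.W1"] = xavier(d, ff)
            p[f"{l}.b1"] = np.zeros(ff)
            p[f"{l}.W2"] = xavier(ff, d)
            p[f"{l}.b2"] = np.zeros(d)
            p[f"{l}.ln2_g"] = np.ones(d)
            p[f"{l}.ln2_b"] = np.zeros(d)
        p["Wc"] = xavier(d, cfg.n_classes)
        p["bc"] = np.zeros(cfg.n_classes)
        return p

    @staticmethod
    def _pe_freqs(cfg: ToyEncoderConfig) -> np.ndarray:
        """Geometric frequency ladder spanning wavelengths ~4 .. 2*max_len.

        The classic base-10000 ladder targets sequences of thousands of
        tokens; at desk scale most of its planes would be constant over the
        sequence and useless for position discrimination.
        """
        n_planes = (cfg.d_model // 2) // 2
        w_min, w_max = 4.0, 2.0 * cfg.max_seq_len
        wavelengths = w_min * (w_max / w_min) ** (np.arange(n_planes) / (n_planes - 1))
        return 2.0 * np.pi / wavelengths

    def _apply_local_attention_init(
        self, p: dict[str, np.ndarray], layer: int, cfg: ToyEncoderConfig,
        rng: np.random.Generator,
    ) -> None:
        """Locality-biased Wq/Wk initialization (trainable, content-free).

        Sinusoidal encodings satisfy PE_{j+delta} = R_delta PE_j with R_delta
        a blockwise rotation, so seeding head h's query projection with the
        rotation for a small offset delta_h (and its key projection with the
        matching identity) makes the head attend to a fixed relative offset
        at initialization. This is an inductive bias toward local,
        shift-invariant receptive fields — the prerequisite for learning
        contiguous-motif detectors from a few hundred sequences — and bakes
        in nothing about any class. Gradient descent is free to reshape it.
        """
        d, dh = cfg.d_model, cfg.d_model // cfg.n_heads
        g = cfg.local_init_gain
        offsets = [(-1, 1, -2, 2, -3, 3)[h % 6] for h in range(cfg.n_heads)]
        d_pe = d // 2
        freqs = self._pe_freqs(cfg)
        Wq = 0.02 * rng.normal(size=(d, d))
        Wk = 0.02 * rng.normal(size=(d, d))
        for h, delta in enumerate(offsets):
            for m in range(min(dh, d_pe) // 2):  # the highest-frequency planes
                omega = freqs[m]
                phi = omega * delta
                r_sin, r_cos = 2 * m, 2 * m + 1          # embedding dims
                c_sin, c_cos = h * dh + 2 * m, h * dh + 2 * m + 1
                # q_i = PE_{i - delta} restricted to the selected planes
                Wq[r_sin, c_sin] += g * np.cos(phi)
                Wq[r_cos, c_sin] += -g * np.sin(phi)
                Wq[r_sin, c_cos] += g * np.sin(phi)
                Wq[r_cos, c_cos] += g * np.cos(phi)
                Wk[r_sin, c_sin] += g
                Wk[r_cos, c_cos] += g
        p[f"{layer}.Wq"] = Wq
        p[f"{layer}.Wk"] = Wk

    # -- encoding ----------------------------------------------------------
    def token_ids_for(self, sequence: str) -> np.ndarray:
        ids = self.vocab.encode_residues(sequence)
        full = np.concatenate(([self.vocab.cls_id], ids, [self.vocab.eos_id]))
        if full.shape[0] > self.max_seq_len:
            raise ValueError(
                f"sequence of length {len(sequence)} exceeds max_seq_len="
                f"{self.max_seq_len} after special tokens"
            )
        return full

    def embed_ids(self, token_ids: np.ndarray) -> np.ndarray:
        L = token_ids.shape[0]
        return self.params["tok_emb"][token_ids] + self.params["pos_emb"][:L]

    def encode(self, sequence: str) -> EncodedSequence:
        ids = self.token_ids_for(sequence)
        special = np.isin(
            ids,
            [self.vocab.cls_id, self.vocab.eos_id, self.vocab.pad_id, self.vocab.mask_id],
        )
        return EncodedSequence(ids, self.embed_ids(ids), special, sequence)

    def baseline_embedding(
        self, encoded: EncodedSequence, kind: str = "padding_embedding"
    ) -> np.ndarray:
        base = encoded.embedding.copy()
        res = encoded.residue_positions
        if kind == "padding_embedding":
            pad_vec = self.params["tok_emb"][self.vocab.pad_id]
            base[res] = pad_vec + self.params["pos_emb"][res]
        elif kind == "zero_embedding":
            base[res] = 0.0
        else:
            raise ValueError(f"unknown baseline kind {kind!r}")
        return base

    # -- forward -----------------------------------------------------------
    def _forward_graph(
        self,
        emb: Tensor,
        attn_valid: np.ndarray | None,
        params: dict[str, Tensor],
    ) -> tuple[Tensor, list[Tensor]]:
        """Build the graph: returns (logits (B, C), per-layer MHSA nodes)."""
        B, L, d = emb.shape
        H, dh = self.n_heads, self.head_dim
        scale = 1.0 / np.sqrt(dh)
        if attn_valid is None:
            attn_valid = np.ones((B, L), dtype=bool)
        # additive mask on the key axis; detached constant
        key_mask = np.where(attn_valid, 0.0, -1e9)[:, None, None, :]  # (B,1,1,L)

        x = emb
        mhsa_nodes: list[Tensor] = []
        for l in range(self.n_layers):
            q = (x @ params[f"{l}.Wq"] + params[f"{l}.bq"]).reshape(B, L, H, dh).swapaxes(1, 2)
            k = (x @ params[f"{l}.Wk"] + params[f"{l}.bk"]).reshape(B, L, H, dh).swapaxes(1, 2)
            v = (x @ params[f"{l}.Wv"] + params[f"{l}.bv"]).reshape(B, L, H, dh).swapaxes(1, 2)
            scores = (q @ k.swapaxes(2, 3)) * scale + Tensor(key_mask)
            attn = softmax(scores, axis=-1)                     # (B,H,L,L)
            ctx = (attn @ v).swapaxes(1, 2).reshape(B, L, d)    # concat heads
            mhsa_nodes.append(ctx)                              # pre-projection
            a = ctx @ params[f"{l}.Wo"] + params[f"{l}.bo"]
            x = layer_norm(x + a, params[f"{l}.ln1_g"], params[f"{l}.ln1_b"])
            f = gelu(x @ params[f"{l}.W1"] + params[f"{l}.b1"]) @ params[f"{l}.W2"] + params[f"{l}.b2"]
            x = layer_norm(x + f, params[f"{l}.ln2_g"], params[f"{l}.ln2_b"])
        if self.config.pooling == "cls":
            pooled = x[:, 0, :]
        else:  # masked mean over valid positions
            w = attn_valid.astype(np.float64)
            w = w / w.sum(axis=1, keepdims=True)
            pooled = (x * Tensor(w[:, :, None])).sum(axis=1)
        logits = pooled @ params["Wc"] + params["bc"]
        return logits, mhsa_nodes

    @staticmethod
    def _score_from_logits(logits: Tensor, fn: ClassScoreFn) -> Tensor:
        n_classes = logits.shape[-1]
        if not (0 <= fn.class_index < n_classes):
            raise ValueError(
                f"class index {fn.class_index} out of range for {n_classes} classes"
            )
        if fn.score_kind == "logit":
            return logits[:, fn.class_index]
        return softmax(logits, axis=-1)[:, fn.class_index]

    def forward_batch(
        self,
        embeddings: np.ndarray,
        fn: ClassScoreFn,
        need_grads: bool = True,
        attn_valid: np.ndarray | None = None,
    ) -> ForwardPass:
        embeddings = np.asarray(embeddings, dtype=np.float64)
        if embeddings.ndim == 2:
            embeddings = embeddings[None]
        emb = Tensor(embeddings, requires_grad=need_grads)
        params = {k: Tensor(v) for k, v in self.params.items()}
        logits, mhsa_nodes = self._forward_graph(emb, attn_valid, params)
        score = self._score_from_logits(logits, fn)
        if not need_grads:
            return ForwardPass(score.data.copy(), logits.data.copy(), None,
                               [m.data.copy() for m in mhsa_nodes], None)
        total = score.sum()
        total.backward()
        if emb.grad is None or not np.all(np.isfinite(emb.grad)):
            raise FloatingPointError("non-finite gradient in forward_batch")
        return ForwardPass(
            scores=score.data.copy(),
            logits=logits.data.copy(),
            grad_embedding=emb.grad.copy(),
            mhsa=[m.data.copy() for m in mhsa_nodes],
            mhsa_grads=[m.grad.copy() for m in mhsa_nodes],
        )

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: parameters + config (JSON) in one .npz."""
        payload = dict(self.params)
        payload["__config__"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
        )
        np.savez(path, **payload)

    @classmethod
    def load(cls, path: str | Path) -> "TransformerEncoderClassifier":
        with np.load(path) as z:
            cfg = ToyEncoderConfig(**json.loads(bytes(z["__config__"]).decode()))
            model = cls(cfg)
            for k in model.params:
                model.params[k] = z[k]
        return model


# -- spec-surface convenience wrappers --------------------------------------

def encode(model: AttributionModel, sequence: str) -> EncodedSequence:
    return model.encode(sequence)


def mhsa_output(
    model: AttributionModel, encoded: EncodedSequence | np.ndarray, layer: int
) -> np.ndarray:
    """Pre-projection concatenated head outputs of one layer, (L, d_model)."""
    if not (0 <= layer < model.n_layers):
        raise ValueError(f"layer {layer} out of range [0, {model.n_layers})")
    emb = encoded.embedding if isinstance(encoded, EncodedSequence) else encoded
    fp = model.forward_batch(emb[None], ClassScoreFn(0, "logit"), need_grads=False)
    return fp.mhsa[layer][0]


def class_score(
    model: AttributionModel, encoded: EncodedSequence | np.ndarray, fn: ClassScoreFn
) -> float:
    emb = encoded.embedding if isinstance(encoded, EncodedSequence) else encoded
    fp = model.forward_batch(emb[None], fn, need_grads=False)
    return float(fp.scores[0])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: TransformerEncoderClassifier
    test_accuracy: float
    train_accuracy: float
    losses: list[float] = field(default_factory=list)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0,
                 frozen: frozenset[str] = frozenset()):
        self.params = params
        self.frozen = frozen
        self.weight_decay = weight_decay
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            if k in self.frozen:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            update = mh / (np.sqrt(vh) + self.eps)
            if self.weight_decay and k[0].isdigit() and ".W" in k:
                update = update + self.weight_decay * self.params[k]  # AdamW
            self.params[k] -= self.lr * update


def _pad_batch(model: TransformerEncoderClassifier,
               ids_list: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    L = max(len(i) for i in ids_list)
    B = len(ids_list)
    ids = np.full((B, L), model.vocab.pad_id, dtype=np.int64)
    valid = np.zeros((B, L), dtype=bool)
    for b, seq_ids in enumerate(ids_list):
        ids[b, : len(seq_ids)] = seq_ids
        valid[b, : len(seq_ids)] = True
    return ids, valid


def _batch_loss_and_grads(
    model: TransformerEncoderClassifier,
    ids: np.ndarray,
    valid: np.ndarray,
    labels: np.ndarray,
) -> tuple[float, float, dict[str, np.ndarray]]:
    B, L = ids.shape
    params = {k: Tensor(v, requires_grad=True) for k, v in model.params.items()}
    emb = params["tok_emb"][ids] + params["pos_emb"][:L]
    logits, _ = model._forward_graph(emb, valid, params)
    probs = softmax(logits, axis=-1)
    picked = probs[np.arange(B), labels]
    loss = -(picked.log().mean())
    if not np.isfinite(loss.data):
        raise FloatingPointError("non-finite training loss")
    loss.backward()
    grads = {k: t.grad if t.grad is not None else np.zeros_like(t.data)
             for k, t in params.items()}
    acc = float(np.mean(np.argmax(logits.data, axis=-1) == labels))
    return float(loss.data), acc, grads


def train_toy_model(
    sequences: Sequence[str],
    labels: Sequence[int],
    test_sequences: Sequence[str],
    test_labels: Sequence[int],
    config: ToyEncoderConfig | None = None,
    seed: int = 0,
    epochs: int = 30,
    batch_size: int = 16,
    lr: float = 2e-3,
    mask_augment_p: float = 0.15,
    weight_decay: float = 0.01,
    target_accuracy: float | None = None,
) -> TrainResult:
    """Train the toy encoder from scratch; deterministic given seed + config.

    Light random residue masking (``mask_augment_p``) regularizes training
    and teaches the [MASK] token its 'no information' meaning, which the
    substitution faithfulness experiment exploits.
    """
    overlap = set(sequences) & set(test_sequences)
    if overlap:
        raise ValueError(f"train/test sequences overlap ({len(overlap)} shared)")
    config = config or ToyEncoderConfig(seed=seed)
    model = TransformerEncoderClassifier(config)
    rng = np.random.default_rng(seed)
    frozen = frozenset({"pos_emb"}) if config.positional == "sinusoidal" else frozenset()
    opt = _Adam(model.params, lr=lr, weight_decay=weight_decay, frozen=frozen)
    ids_all = [model.token_ids_for(s) for s in sequences]
    y_all = np.asarray(labels, dtype=np.int64)
    losses: list[float] = []
    n = len(ids_all)
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            ids, valid = _pad_batch(model, [ids_all[i] for i in idx])
            if mask_augment_p > 0:
                maskable = valid & (ids >= len(SPECIAL_TOKENS))
                hit = (rng.random(ids.shape) < mask_augment_p) & maskable
                ids = np.where(hit, model.vocab.mask_id, ids)
            loss, _, grads = _batch_loss_and_grads(model, ids, valid, y_all[idx])
            opt.step(grads)
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)
        if target_accuracy is not None:
            acc = evaluate_accuracy(model, sequences, labels)
            if acc >= target_accuracy:
                break
    train_acc = evaluate_accuracy(model, sequences, labels)
    test_acc = evaluate_accuracy(model, test_sequences, test_labels)
    return TrainResult(model, test_acc, train_acc, losses)


def evaluate_accuracy(
    model: TransformerEncoderClassifier,
    sequences: Iterable[str],
    labels: Iterable[int],
    batch_size: int = 32,
) -> float:
    seqs, ys = list(sequences), np.asarray(list(labels))
    preds = predict_classes(model, seqs, batch_size=batch_size)
    return float(np.mean(preds == ys))


def predict_classes(
    model: TransformerEncoderClassifier, sequences: Sequence[str], batch_size: int = 32
) -> np.ndarray:
    ids_all = [model.token_ids_for(s) for s in sequences]
    out = np.empty(len(ids_all), dtype=np.int64)
    for start in range(0, len(ids_all), batch_size):
        chunk = ids_all[start : start + batch_size]
        ids, valid = _pad_batch(model, chunk)
        params = {k: Tensor(v) for k, v in model.params.items()}
        emb = Tensor(model.params["tok_emb"][ids] + model.params["pos_emb"][: ids.shape[1]])
        logits, _ = model._forward_graph(emb, valid, params)
        out[start : start + len(chunk)] = np.argmax(logits.data, axis=-1)
    return out


# ---------------------------------------------------------------------------
# Degenerate severed-skip model
# ---------------------------------------------------------------------------

class SeveredSkipModel(AttributionModel):
    """One MHSA block with the residual skip removed and a linear readout.

    Every path from the embeddings to the score runs through the MHSA
    output, and everything downstream of it is linear, so the layer
    attribution total must equal F(x) - F(x') (completeness transfers to
    the only path). Used to validate layer-level IG.
    """

    def __init__(self, n_heads: int = 2, d_model: int = 16, max_seq_len: int = 64,
                 seed: int = 0):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.vocab = Vocabulary()
        self.n_layers = 1
        self.n_heads = n_heads
        self.d_model = d_model
        self.n_classes = 1
        self.max_seq_len = max_seq_len
        rng = np.random.default_rng(seed)
        d = d_model
        self.params = {
            "tok_emb": rng.normal(0.0, 0.5, size=(len(self.vocab), d)),
            "pos_emb": rng.normal(0.0, 0.5, size=(max_seq_len, d)),
            "Wq": rng.normal(0.0, 0.3, size=(d, d)),
            "Wk": rng.normal(0.0, 0.3, size=(d, d)),
            "Wv": rng.normal(0.0, 0.3, size=(d, d)),
            "Wo": rng.normal(0.0, 0.3, size=(d, d)),
            "w_out": rng.normal(0.0, 0.5, size=d),
        }

    def encode(self, sequence: str) -> EncodedSequence:
        ids = self.vocab.encode_residues(sequence)
        ids = np.concatenate(([self.vocab.cls_id], ids, [self.vocab.eos_id]))
        if ids.shape[0] > self.max_seq_len:
            raise ValueError("sequence too long")
        emb = self.params["tok_emb"][ids] + self.params["pos_emb"][: ids.shape[0]]
        special = np.isin(ids, [self.vocab.cls_id, self.vocab.eos_id,
                                self.vocab.pad_id, self.vocab.mask_id])
        return EncodedSequence(ids, emb, special, sequence)

    def baseline_embedding(self, encoded: EncodedSequence,
                           kind: str = "padding_embedding") -> np.ndarray:
        base = encoded.embedding.copy()
        res = encoded.residue_positions
        if kind == "padding_embedding":
            base[res] = (self.params["tok_emb"][self.vocab.pad_id]
                         + self.params["pos_emb"][res])
        elif kind == "zero_embedding":
            base[res] = 0.0
        else:
            raise ValueError(f"unknown baseline kind {kind!r}")
        return base

    def forward_batch(self, embeddings: np.ndarray, fn: ClassScoreFn,
                      need_grads: bool = True) -> ForwardPass:
        if fn.class_index != 0:
            raise ValueError("severed-skip model has a single output class")
        embeddings = np.asarray(embeddings, dtype=np.float64)
        if embeddings.ndim == 2:
            embeddings = embeddings[None]
        B, L, d = embeddings.shape
        H, dh = self.n_heads, d // self.n_heads
        emb = Tensor(embeddings, requires_grad=need_grads)
        q = (emb @ Tensor(self.params["Wq"])).reshape(B, L, H, dh).swapaxes(1, 2)
        k = (emb @ Tensor(self.params["Wk"])).reshape(B, L, H, dh).swapaxes(1, 2)
        v = (emb @ Tensor(self.params["Wv"])).reshape(B, L, H, dh).swapaxes(1, 2)
        attn = softmax((q @ k.swapaxes(2, 3)) * (1.0 / np.sqrt(dh)), axis=-1)
        ctx = (attn @ v).swapaxes(1, 2).reshape(B, L, d)   # MHSA observation point
        out = ctx @ Tensor(self.params["Wo"])              # no skip, all linear below
        score = out.mean(axis=1) @ Tensor(self.params["w_out"])   # (B,)
        if fn.score_kind == "probability":
            score = 1.0 / ((-score).exp() + 1.0)
        if not need_grads:
            return ForwardPass(score.data.copy(), score.data[:, None].copy(),
                               None, [ctx.data.copy()], None)
        score.sum().backward()
        return ForwardPass(score.data.copy(), score.data[:, None].copy(),
                           emb.grad.copy(), [ctx.data.copy()], [ctx.grad.copy()])
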