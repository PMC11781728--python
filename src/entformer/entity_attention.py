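"""Gated entity-aware transformer encoder and classification head.

Each encoder layer runs multi-head self-attention under two additive
masks computed from the same scaled dot-product scores:

* a **global** mask that only removes [PAD] positions, giving the standard
  attention matrix S_glob, and
* a **local** mask that additionally restricts both query and key to
  medically relevant entity tokens (Symptom / Location / Disease), giving
  an entity-restricted matrix S_local.

A per-token sigmoid gate g = sigma(W_g^T h + b_g), computed once per layer
from the layer's input hidden state and shared across heads, fuses the two
row-stochastic matrices convexly before they are applied to the values:

    O_k = (g * S_local + (1 - g) * S_glob) V_k

Rows of S_local whose query token is not an entity have empty support;
they are returned as all-zero rows, so the fused row sums to (1 - g) there
and the local path carries no gradient.  Layers outside ``entity_layers``
run plain masked attention and never evaluate the gate.  The layer stack
is post-LN (residual addition followed by layer normalisation), and the
FFN uses the exact-erf GELU with a 4x hidden expansion.  The final [CLS]
state feeds a softmax classification layer.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .data_model import (MEDICAL_ENTITY_TYPES, EntityType, TaggedSequence, Vocabulary)
from .embedding_block import EmbeddingTables, embed_batch

NEG_INF = -np.inf


# ---------------------------------------------------------------------------
# Configuration and parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the encoder.

    ``entity_layers`` is a set of 1-based layer indices counted from the
    bottom of the stack; those layers use gated entity-aware attention.
    ``enabled_entity_types`` supports knockout ablations: a type removed
    from the set is collapsed to OTHERS both in the entity embedding
    lookup and in the local mask.
    """

    vocab_size: int
    n_layers: int = 2
    n_heads: int = 4
    hidden_size: int = 64
    n_classes: int = 4
    max_len: int = 128
    entity_layers: frozenset[int] = frozenset({1, 2})
    use_entity_embedding: bool = True
    enabled_entity_types: frozenset[EntityType] = MEDICAL_ENTITY_TYPES
    dropout: float = 0.1
    attention_dropout: float = 0.1
    layer_norm_eps: float = 1e-12
    init_std: float = 0.02

    def __post_init__(self):
        if self.hidden_size % self.n_heads != 0:
            raise ValueError("hidden_size must be divisible by n_heads")
        if not set(self.entity_layers) <= set(range(1, self.n_layers + 1)):
            raise ValueError("entity_layers must be 1-based indices within the stack")
        if not set(self.enabled_entity_types) <= MEDICAL_ENTITY_TYPES:
            raise ValueError("enabled_entity_types must be a subset of {SYMPTOM, LOCATION, DISEASE}")
        object.__setattr__(self, "entity_layers", frozenset(self.entity_layers))
        object.__setattr__(self, "enabled_entity_types",
                           frozenset(EntityType(t) for t in self.enabled_entity_types))

    @property
    def head_size(self) -> int:
        return self.hidden_size // self.n_heads

    @classmethod
    def paper_scale(cls, vocab_size: int, n_classes: int = 4) -> "ModelConfig":
        """BERT-base geometry with entity-aware attention on layers 7-9."""
        return cls(vocab_size=vocab_size, n_layers=12, n_heads=12, hidden_size=768,
                   n_classes=n_classes, max_len=512, entity_layers=frozenset({7, 8, 9}))

    def to_dict(self) -> dict:
        return {
            "vocab_size": self.vocab_size, "n_layers": self.n_layers,
            "n_heads": self.n_heads, "hidden_size": self.hidden_size,
            "n_classes": self.n_classes, "max_len": self.max_len,
            "entity_layers": sorted(self.entity_layers),
            "use_entity_embedding": self.use_entity_embedding,
            "enabled_entity_types": sorted(int(t) for t in self.enabled_entity_types),
            "dropout": self.dropout, "attention_dropout": self.attention_dropout,
            "layer_norm_eps": self.layer_norm_eps, "init_std": self.init_std,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["entity_layers"] = frozenset(d["entity_layers"])
        d["enabled_entity_types"] = frozenset(EntityType(t) for t in d["enabled_entity_types"])
        return cls(**d)


@dataclass
class LayerParams:
    """All learned tensors of one encoder layer."""

    Wq: Tensor
    bq: Tensor
    Wk: Tensor
    bk: Tensor
    Wv: Tensor
    bv: Tensor
    Wg: Tensor   # (d, 1) gate weight, one gate per layer shared across heads
    bg: Tensor   # (1,)
    Wo: Tensor   # (d, d) output projection over concatenated heads
    bo: Tensor
    W1: Tensor   # (d, 4d)
    b1: Tensor
    W2: Tensor   # (4d, d)
    b2: Tensor
    ln1_gamma: Tensor
    ln1_beta: Tensor
    ln2_gamma: Tensor
    ln2_beta: Tensor

    @classmethod
    def init(cls, d: int, rng: np.random.Generator, std: float = 0.02) -> "LayerParams":
        def w(*shape):
            return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)

        def b(*shape):
            return Tensor(np.zeros(shape), requires_grad=True)

        return cls(
            Wq=w(d, d), bq=b(d), Wk=w(d, d), bk=b(d), Wv=w(d, d), bv=b(d),
            Wg=w(d, 1), bg=b(1), Wo=w(d, d), bo=b(d),
            W1=w(d, 4 * d), b1=b(4 * d), W2=w(4 * d, d), b2=b(d),
            ln1_gamma=Tensor(np.ones(d), requires_grad=True), ln1_beta=b(d),
            ln2_gamma=Tensor(np.ones(d), requires_grad=True), ln2_beta=b(d),
        )

    def named(self, prefix: str) -> dict[str, Tensor]:
        return {f"{prefix}.{name}": getattr(self, name)
                for name in ("Wq", "bq", "Wk", "bk", "Wv", "bv", "Wg", "bg", "Wo", "bo",
                             "W1", "b1", "W2", "b2",
                             "ln1_gamma", "ln1_beta", "ln2_gamma", "ln2_beta")}


@dataclass
class ClassifierParams:
    Wp: Tensor  # (d, C)
    bp: Tensor  # (C,)

    @classmethod
    def init(cls, d: int, n_classes: int, rng: np.random.Generator, std: float = 0.02) -> "ClassifierParams":
        return cls(Wp=Tensor(rng.normal(0.0, std, size=(d, n_classes)), requires_grad=True),
                   bp=Tensor(np.zeros(n_classes), requires_grad=True))

    def named(self, prefix: str = "cls") -> dict[str, Tensor]:
        return {f"{prefix}.Wp": self.Wp, f"{prefix}.bp": self.bp}


@dataclass
class ModelParams:
    """Full parameter set: embedding tables, L layers, classification head."""

    embeddings: EmbeddingTables
    layers: list[LayerParams]
    classifier: ClassifierParams

    @classmethod
    def init(cls, config: ModelConfig, rng: np.random.Generator) -> "ModelParams":
        d = config.hidden_size
        return cls(
            embeddings=EmbeddingTables.init(config.vocab_size, config.max_len, d, rng,
                                            std=config.init_std, dropout=config.dropout,
                                            ln_eps=config.layer_norm_eps),
            layers=[LayerParams.init(d, rng, config.init_std) for _ in range(config.n_layers)],
            classifier=ClassifierParams.init(d, config.n_classes, rng, config.init_std),
        )

    def named(self) -> dict[str, Tensor]:
        out = self.embeddings.named()
        for i, layer in enumerate(self.layers):
            out.update(layer.named(f"layer{i}"))
        out.update(self.classifier.named())
        return out

    def copy(self) -> "ModelParams":
        import copy as _copy
        clone = _copy.deepcopy(self)
        for t in clone.named().values():
            t.grad = None
        return clone


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

@dataclass
class MaskPair:
    """Additive 0/-inf masks: global (pads only) and local (entities only)."""

    m_glob: np.ndarray
    m_local: np.ndarray


def build_global_mask(pad_flags: Sequence[bool]) -> np.ndarray:
    """(i, j) is admissible iff neither position is a pad."""
    keep = ~np.asarray(pad_flags, dtype=bool)
    ok = np.outer(keep, keep)
    return np.where(ok, 0.0, NEG_INF)


def build_local_mask(entity_types: Sequence[EntityType], pad_flags: Sequence[bool],
                     enabled_types: Iterable[EntityType] = MEDICAL_ENTITY_TYPES) -> np.ndarray:
    """(i, j) is admissible iff both positions carry an enabled medical
    entity type and neither is a pad."""
    enabled = frozenset(EntityType(t) for t in enabled_types)
    if not enabled <= MEDICAL_ENTITY_TYPES:
        raise ValueError("enabled_types must be a subset of {SYMPTOM, LOCATION, DISEASE}")
    types = np.asarray([int(t) for t in entity_types])
    keep = ~np.asarray(pad_flags, dtype=bool)
    is_ent = np.isin(types, [int(t) for t in enabled]) & keep
    ok = np.outer(is_ent, is_ent)
    return np.where(ok, 0.0, NEG_INF)


def build_masks(seq: TaggedSequence, config: ModelConfig) -> MaskPair:
    return MaskPair(
        m_glob=build_global_mask(seq.pad_flags),
        m_local=build_local_mask(seq.entity_types, seq.pad_flags, config.enabled_entity_types),
    )


def _masks_batch(entity_ids: np.ndarray, pad: np.ndarray,
                 enabled: frozenset[EntityType]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised masks for a batch: (B, 1, n, n) for head broadcasting."""
    keep = ~pad
    glob_ok = keep[:, :, None] & keep[:, None, :]
    is_ent = np.isin(entity_ids, [int(t) for t in enabled]) & keep
    loc_ok = is_ent[:, :, None] & is_ent[:, None, :]
    m_glob = np.where(glob_ok, 0.0, NEG_INF)[:, None, :, :]
    m_local = np.where(loc_ok, 0.0, NEG_INF)[:, None, :, :]
    return m_glob, m_local


# ---------------------------------------------------------------------------
# Functional single-sequence operations (eval-mode, numpy in / numpy out)
# ---------------------------------------------------------------------------

def masked_softmax(scores: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row-wise softmax restricted to unmasked support; fully masked rows
    come back as all-zero rows."""
    return ag.masked_softmax(Tensor(scores), np.asarray(mask, dtype=np.float64)).data


def compute_gate(hidden: np.ndarray, Wg: np.ndarray, bg: np.ndarray | float) -> np.ndarray:
    """Per-token gate g = sigma(W_g^T h + b_g) as an n-vector."""
    z = np.asarray(hidden) @ np.asarray(Wg).reshape(-1, 1) + np.asarray(bg).reshape(1)
    return 1.0 / (1.0 + np.exp(-z[:, 0]))


def entity_aware_head(hidden: np.ndarray, masks: MaskPair,
                      Wq: np.ndarray, bq: np.ndarray, Wk: np.ndarray, bk: np.ndarray,
                      Wv: np.ndarray, bv: np.ndarray, gate: np.ndarray) -> np.ndarray:
    """One attention head with gated local/global fusion: returns O_k (n, d_k)."""
    q = hidden @ Wq + bq
    k = hidden @ Wk + bk
    v = hidden @ Wv + bv
    scores = (q @ k.T) / np.sqrt(q.shape[-1])
    s_glob = masked_softmax(scores, masks.m_glob)
    s_local = masked_softmax(scores, masks.m_local)
    g = np.asarray(gate)[:, None]
    return (g * s_local + (1.0 - g) * s_glob) @ v


# ---------------------------------------------------------------------------
# Differentiable forward pass
# ---------------------------------------------------------------------------

@dataclass
class LayerTrace:
    """Recorded attention internals of one layer (eval-mode introspection)."""

    s_glob: np.ndarray                 # (H, n, n)
    s_local: np.ndarray | None         # (H, n, n) or None for plain layers
    gate: np.ndarray | None            # (n,) or None
    fused: np.ndarray                  # (H, n, n) matrices applied to values
    head_outputs: np.ndarray           # (H, n, d_k)
    projected: np.ndarray              # (n, d) after the output projection


@dataclass
class AttentionTrace:
    """Per-layer traces of one forward pass on a single sequence."""

    layers: list[LayerTrace] = field(default_factory=list)


class _BatchTrace:
    """Internal collector used by the batched forward."""

    def __init__(self):
        self.records: list[dict] = []


@dataclass
class Batch:
    token_ids: np.ndarray   # (B, n) int
    entity_ids: np.ndarray  # (B, n) int, EntityType values
    segment_ids: np.ndarray  # (B, n) int
    pad: np.ndarray         # (B, n) bool
    labels: np.ndarray      # (B,) int


def batchify(seqs: Sequence[TaggedSequence], pad_to: int | None = None) -> Batch:
    """Stack sequences into id arrays, right-padding to the batch maximum
    (pad id 0, entity OTHERS, segment 0)."""
    n = pad_to if pad_to is not None else max(len(s) for s in seqs)
    B = len(seqs)
    token_ids = np.zeros((B, n), dtype=np.int64)
    entity_ids = np.zeros((B, n), dtype=np.int64)
    segment_ids = np.zeros((B, n), dtype=np.int64)
    pad = np.ones((B, n), dtype=bool)
    labels = np.zeros(B, dtype=np.int64)
    for i, s in enumerate(seqs):
        m = len(s)
        if m > n:
            raise ValueError(f"sequence of length {m} exceeds batch length {n}")
        token_ids[i, :m] = s.token_ids
        entity_ids[i, :m] = [int(t) for t in s.entity_types]
        segment_ids[i, :m] = s.segment_ids
        pad[i, :m] = s.pad_flags
        labels[i] = s.label
    return Batch(token_ids, entity_ids, segment_ids, pad, labels)


def _heads(x: Tensor, B: int, n: int, H: int, dk: int) -> Tensor:
    return x.reshape(B, n, H, dk).transpose(0, 2, 1, 3)


def _mhsa(x: Tensor, p: LayerParams, m_glob: np.ndarray, m_local: np.ndarray,
          entity_aware: bool, config: ModelConfig, train: bool,
          rng: np.random.Generator | None, trace: _BatchTrace | None) -> Tensor:
    B, n, d = x.shape
    H, dk = config.n_heads, config.head_size
    q = _heads(x @ p.Wq + p.bq, B, n, H, dk)
    k = _heads(x @ p.Wk + p.bk, B, n, H, dk)
    v = _heads(x @ p.Wv + p.bv, B, n, H, dk)
    scores = ag.matmul(q, k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
    s_glob = ag.masked_softmax(scores, m_glob)
    gate = None
    if entity_aware:
        gate = ag.sigmoid(x @ p.Wg + p.bg)          # (B, n, 1)
        g4 = gate.reshape(B, 1, n, 1)
        s_local = ag.masked_softmax(scores, m_local)
        fused = g4 * s_local + (1.0 - g4) * s_glob
    else:
        s_local = None
        fused = s_glob
    fused = ag.dropout(fused, config.attention_dropout, rng, train)
    ctx = ag.matmul(fused, v)                       # (B, H, n, dk)
    out = ctx.transpose(0, 2, 1, 3).reshape(B, n, d) @ p.Wo + p.bo
    if trace is not None:
        trace.records.append({
            "s_glob": s_glob.data.copy(),
            "s_local": None if s_local is None else s_local.data.copy(),
            "gate": None if gate is None else gate.data[..., 0].copy(),
            "fused": fused.data.copy(),
            "head_outputs": ctx.data.copy(),
            "projected": out.data.copy(),
        })
    return out


def _ffn(x: Tensor, p: LayerParams) -> Tensor:
    return ag.gelu(x @ p.W1 + p.b1) @ p.W2 + p.b2


def _encoder_layer(x: Tensor, p: LayerParams, m_glob: np.ndarray, m_local: np.ndarray,
                   entity_aware: bool, config: ModelConfig, train: bool,
                   rng: np.random.Generator | None, trace: _BatchTrace | None) -> Tensor:
    a = _mhsa(x, p, m_glob, m_local, entity_aware, config, train, rng, trace)
    x = ag.layer_norm(x + ag.dropout(a, config.dropout, rng, train),
                      p.ln1_gamma, p.ln1_beta, config.layer_norm_eps)
    f = _ffn(x, p)
    return ag.layer_norm(x + ag.dropout(f, config.dropout, rng, train),
                         p.ln2_gamma, p.ln2_beta, config.layer_norm_eps)


def _effective_entity_ids(entity_ids: np.ndarray, enabled: frozenset[EntityType]) -> np.ndarray:
    """Collapse disabled entity types to OTHERS (knockout ablations)."""
    if enabled == MEDICAL_ENTITY_TYPES:
        return entity_ids
    keep = np.isin(entity_ids, [int(t) for t in enabled])
    return np.where(keep, entity_ids, int(EntityType.OTHERS))


def encode_batch(params: ModelParams, batch: Batch, config: ModelConfig,
                 train: bool = False, rng: np.random.Generator | None = None,
                 trace: _BatchTrace | None = None) -> Tensor:
    """Run the full encoder on a batch; returns hidden states (B, n, d)."""
    entity_ids = _effective_entity_ids(batch.entity_ids, config.enabled_entity_types)
    m_glob, m_local = _masks_batch(entity_ids, batch.pad, config.enabled_entity_types)
    x = embed_batch(params.embeddings, batch.token_ids, entity_ids, batch.segment_ids,
                    use_entity_embedding=config.use_entity_embedding, train=train, rng=rng)
    for i, layer in enumerate(params.layers, start=1):
        x = _encoder_layer(x, layer, m_glob, m_local, i in config.entity_layers,
                           config, train, rng, trace)
    return x


def forward_logits(params: ModelParams, batch: Batch, config: ModelConfig,
                   train: bool = False, rng: np.random.Generator | None = None,
                   trace: _BatchTrace | None = None) -> Tensor:
    hidden = encode_batch(params, batch, config, train, rng, trace)
    h_cls = ag.take_row(hidden, 0)
    return h_cls @ params.classifier.Wp + params.classifier.bp


# -- single-sequence public wrappers ----------------------------------------

def mhsa_forward(hidden: np.ndarray, masks: MaskPair, layer: LayerParams,
                 config: ModelConfig, entity_aware: bool = True) -> np.ndarray:
    """Eval-mode multi-head self-attention on one n x d hidden matrix."""
    x = Tensor(np.asarray(hidden)[None, ...])
    out = _mhsa(x, layer, masks.m_glob[None, None], masks.m_local[None, None],
                entity_aware, config, train=False, rng=None, trace=None)
    return out.data[0]


def ffn_forward(hidden: np.ndarray, layer: LayerParams) -> np.ndarray:
    """Position-wise FFN: W2^T GELU(W1^T x + b1) + b2 (exact-erf GELU)."""
    return _ffn(Tensor(np.asarray(hidden)), layer).data


def encoder_layer_forward(hidden: np.ndarray, masks: MaskPair, layer: LayerParams,
                          config: ModelConfig, entity_aware: bool = True) -> np.ndarray:
    """One post-LN encoder layer in eval mode on an n x d matrix."""
    x = Tensor(np.asarray(hidden)[None, ...])
    out = _encoder_layer(x, layer, masks.m_glob[None, None], masks.m_local[None, None],
                         entity_aware, config, train=False, rng=None, trace=None)
    return out.data[0]


def encoder_forward(seq: TaggedSequence, params: ModelParams, config: ModelConfig,
                    record_trace: bool = False) -> tuple[np.ndarray, np.ndarray, AttentionTrace | None]:
    """Full eval-mode encoder pass on one sequence.

    Returns (hidden_states (n, d), h_cls (d,), trace or None).
    """
    batch = batchify([seq])
    collector = _BatchTrace() if record_trace else None
    hidden = encode_batch(params, batch, config, train=False, trace=collector)
    trace = None
    if collector is not None:
        trace = AttentionTrace(layers=[
            LayerTrace(
                s_glob=r["s_glob"][0],
                s_local=None if r["s_local"] is None else r["s_local"][0],
                gate=None if r["gate"] is None else r["gate"][0],
                fused=r["fused"][0],
                head_outputs=r["head_outputs"][0],
                projected=r["projected"][0],
            )
            for r in collector.records
        ])
    return hidden.data[0], hidden.data[0, 0], trace


def classify(h_cls: np.ndarray, classifier: ClassifierParams) -> np.ndarray:
    """Softmax class probabilities from the [CLS] hidden state."""
    z = np.asarray(h_cls) @ classifier.Wp.data + classifier.bp.data
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def predict_proba_batch(params: ModelParams, seqs: Sequence[TaggedSequence],
                        config: ModelConfig, batch_size: int = 64) -> np.ndarray:
    """Eval-mode class probabilities for a list of sequences."""
    probs = []
    for start in range(0, len(seqs), batch_size):
        chunk = seqs[start:start + batch_size]
        logits = forward_logits(params, batchify(chunk), config, train=False).data
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs.append(e / e.sum(axis=1, keepdims=True))
    return np.concatenate(probs, axis=0)


# ---------------------------------------------------------------------------
# Checkpoint IO: one zip archive holding config, vocabulary and weights
# ---------------------------------------------------------------------------

def save_checkpoint(path, params: ModelParams, config: ModelConfig,
                    vocab: Vocabulary | None = None) -> None:
    named = params.named()
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("config.json", json.dumps(config.to_dict()))
        if vocab is not None:
            zf.writestr("vocab.json", json.dumps(vocab.tokens()))
        buf = io.BytesIO()
        np.savez(buf, **{k: t.data for k, t in named.items()})
        zf.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path) -> tuple[ModelParams, ModelConfig, Vocabulary | None]:
    with zipfile.ZipFile(path) as zf:
        config = ModelConfig.from_dict(json.loads(zf.read("config.json")))
        vocab = None
        if "vocab.json" in zf.namelist():
            tokens = json.loads(zf.read("vocab.json"))
            vocab = Vocabulary(tokens[4:])  # first four are the reserved specials
        arrays = np.load(io.BytesIO(zf.read("weights.npz")))
        params = ModelParams.init(config, np.random.default_rng(0))
        for name, tensor in params.named().items():
            tensor.data = np.array(arrays[name])
    return params, config, vocab
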