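"""Input embedding block: token + position + segment + entity-type sum.

On top of the standard three-way transformer embedding sum, every token
also looks up an embedding for its medical entity type (Symptom, Location,
Disease, or Others).  The four vectors are summed, layer-normalised and
(in training) dropped out.  With the entity table held at zero the block
reduces exactly to the vanilla three-way embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .data_model import EntityType, TaggedSequence

N_ENTITY_TYPES = 4  # rows ordered [OTHERS, SYMPTOM, LOCATION, DISEASE]


@dataclass
class EmbeddingTables:
    """Learned lookup tables and post-sum normalisation parameters."""

    token: Tensor          # (|V|, d)
    position: Tensor       # (n_max, d)
    segment: Tensor        # (2, d)
    entity: Tensor         # (4, d), row order fixed by EntityType values
    ln_gamma: Tensor       # (d,)
    ln_beta: Tensor        # (d,)
    dropout: float = 0.1
    ln_eps: float = 1e-12

    @classmethod
    def init(cls, vocab_size: int, n_max: int, d: int, rng: np.random.Generator,
             std: float = 0.02, dropout: float = 0.1, ln_eps: float = 1e-12) -> "EmbeddingTables":
        """BERT-style initialisation: N(0, std) tables; the OTHERS row of the
        entity table starts at zero so a sparse-entity model starts near
        vanilla behaviour."""
        entity = rng.normal(0.0, std, size=(N_ENTITY_TYPES, d))
        entity[EntityType.OTHERS] = 0.0
        return cls(
            token=Tensor(rng.normal(0.0, std, size=(vocab_size, d)), requires_grad=True),
            position=Tensor(rng.normal(0.0, std, size=(n_max, d)), requires_grad=True),
            segment=Tensor(rng.normal(0.0, std, size=(2, d)), requires_grad=True),
            entity=Tensor(entity, requires_grad=True),
            ln_gamma=Tensor(np.ones(d), requires_grad=True),
            ln_beta=Tensor(np.zeros(d), requires_grad=True),
            dropout=dropout,
            ln_eps=ln_eps,
        )

    def named(self, prefix: str = "emb") -> dict[str, Tensor]:
        return {f"{prefix}.token": self.token, f"{prefix}.position": self.position,
                f"{prefix}.segment": self.segment, f"{prefix}.entity": self.entity,
                f"{prefix}.ln_gamma": self.ln_gamma, f"{prefix}.ln_beta": self.ln_beta}


def embed_batch(tables: EmbeddingTables, token_ids: np.ndarray, entity_ids: np.ndarray,
                segment_ids: np.ndarray, use_entity_embedding: bool = True,
                train: bool = False, rng: np.random.Generator | None = None) -> Tensor:
    """Differentiable embedding of an id batch: (B, n) int arrays -> (B, n, d)."""
    n = token_ids.shape[-1]
    if token_ids.max(initial=0) >= tables.token.shape[0]:
        raise ValueError("token id out of table range")
    if n > tables.position.shape[0]:
        raise ValueError(f"sequence length {n} exceeds position table {tables.position.shape[0]}")
    e = ag.embedding(tables.token, token_ids) + ag.embedding(tables.position, np.arange(n))
    e = e + ag.embedding(tables.segment, segment_ids)
    if use_entity_embedding:
        e = e + ag.embedding(tables.entity, entity_ids)
    e = ag.layer_norm(e, tables.ln_gamma, tables.ln_beta, tables.ln_eps)
    return ag.dropout(e, tables.dropout, rng, train)


def embed(seq: TaggedSequence, tables: EmbeddingTables, train_mode: bool = False,
          rng: np.random.Generator | None = None) -> np.ndarray:
    """Embed one TaggedSequence: returns the n x d matrix of initial hidden
    vectors.  Deterministic in eval mode (train_mode=False)."""
    out = embed_batch(
        tables,
        np.asarray(seq.token_ids)[None, :],
        np.asarray([int(t) for t in seq.entity_types])[None, :],
        np.asarray(seq.segment_ids)[None, :],
        train=train_mode,
        rng=rng,
    )
    return out.data[0]
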