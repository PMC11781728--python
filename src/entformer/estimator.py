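"""Scikit-learn style estimator around the entity-aware encoder.

``EntityTransformerClassifier`` follows the sklearn estimator contract
(``get_params``/``set_params``, ``fit``/``predict``/``predict_proba``,
fitted attributes with a trailing underscore), so it composes with
``sklearn.model_selection`` utilities and pipelines.  The input ``X`` is a
sequence of records rather than a numeric matrix: each record is either a
``(tokens, bio_tags)`` pair of flat streams (QA units separated by a
``[SEP]`` token), a ``(qa_pairs,)``-style list of units, an already
assembled :class:`~entformer.data_model.TaggedSequence`, or a
:class:`~entformer.synthetic_data.SyntheticRecord`.
"""

from __future__ import annotations

import numbers
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .data_model import (TaggedSequence, Vocabulary, assemble_input,
                         pad_and_truncate, split_qa)
from .entity_attention import (MEDICAL_ENTITY_TYPES, EntityType, ModelConfig,
                               predict_proba_batch)
from .synthetic_data import SyntheticRecord
from .training import TrainConfig, train


def _as_qa_pairs(record) -> list[tuple[list[str], list[str]]]:
    if isinstance(record, SyntheticRecord):
        return record.qa_pairs
    if isinstance(record, tuple) and len(record) == 2 and record[0] and isinstance(record[0][0], str):
        tokens, tags = record
        return split_qa(tokens, tags)
    return list(record)  # already a list of (tokens, tags) units


class EntityTransformerClassifier(BaseEstimator, ClassifierMixin):
    """Medical-specialty text classifier with entity-aware gated attention.

    Parameters
    ----------
    n_layers, n_heads, hidden_size
        Encoder geometry; ``hidden_size`` must be divisible by ``n_heads``.
    entity_layers
        1-based layer indices using gated entity-aware attention, or
        ``"all"`` / ``"none"``.
    use_entity_embedding
        Whether the embedding block adds the entity-type table.
    enabled_entity_types
        Entity-type names participating in entity features; removing one
        collapses it to OTHERS (knockout ablation).
    max_len
        Sequences are padded/truncated to at most this length.
    learning_rate, batch_size, epochs, weight_decay, warmup_ratio
        Optimisation schedule (Adam with decoupled decay, linear warm-up
        and decay).
    validation_fraction
        If positive, a stratified tail of the training data is held out
        and the best-epoch snapshot by dev macro F1 is kept.
    random_state
        Seeds initialisation, batching and dropout.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in ``fit``.
    vocab_ : Vocabulary
        Corpus-built token vocabulary.
    config_ : ModelConfig
        Resolved encoder configuration.
    params_ : ModelParams
        Learned weights.
    run_record_ : RunRecord
        Per-epoch losses, dev scores and the best-epoch index.
    """

    def __init__(self, n_layers: int = 2, n_heads: int = 4, hidden_size: int = 64,
                 entity_layers="all", use_entity_embedding: bool = True,
                 enabled_entity_types: tuple[str, ...] = ("SYMPTOM", "LOCATION", "DISEASE"),
                 max_len: int = 128, dropout: float = 0.1, attention_dropout: float = 0.1,
                 learning_rate: float = 5e-4, batch_size: int = 16, epochs: int = 10,
                 weight_decay: float = 1e-2, warmup_ratio: float = 0.1,
                 max_grad_norm: float = 1.0, validation_fraction: float = 0.0,
                 random_state: int = 0):
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.hidden_size = hidden_size
        self.entity_layers = entity_layers
        self.use_entity_embedding = use_entity_embedding
        self.enabled_entity_types = enabled_entity_types
        self.max_len = max_len
        self.dropout = dropout
        self.attention_dropout = attention_dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.weight_decay = weight_decay
        self.warmup_ratio = warmup_ratio
        self.max_grad_norm = max_grad_norm
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------
    def _resolve_entity_layers(self) -> frozenset[int]:
        if self.entity_layers == "all":
            return frozenset(range(1, self.n_layers + 1))
        if self.entity_layers in ("none", None):
            return frozenset()
        return frozenset(int(i) for i in self.entity_layers)

    def _sequences(self, X, y=None) -> list[TaggedSequence]:
        seqs = []
        for i, record in enumerate(X):
            if isinstance(record, TaggedSequence):
                seq = record
                if y is not None:
                    seq = TaggedSequence(seq.tokens, seq.token_ids, seq.entity_types,
                                         seq.segment_ids, seq.pad_flags, label=int(y[i]))
            else:
                label = int(y[i]) if y is not None else getattr(record, "label", 0)
                seq = assemble_input(_as_qa_pairs(record), self.vocab_, label)
            seqs.append(pad_and_truncate(seq, min(self.max_len, max(len(seq), 2)), self.vocab_)
                        if len(seq) > self.max_len else seq)
        return seqs

    # -- estimator API ---------------------------------------------------
    def fit(self, X, y=None):
        """Fit on records ``X``; ``y`` defaults to each record's own label."""
        records = list(X)
        if y is None:
            y = [getattr(r, "label", None) for r in records]
            if any(v is None for v in y):
                raise ValueError("y is required when records carry no labels")
        y = np.asarray([int(v) for v in y])
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self.vocab_ = Vocabulary()
        for record in records:
            if isinstance(record, TaggedSequence):
                for tok in record.tokens:
                    if not (tok.startswith("[") and tok.endswith("]")):
                        self.vocab_.add(tok)
            else:
                for tokens, _tags in _as_qa_pairs(record):
                    for tok in tokens:
                        self.vocab_.add(tok)
        self.config_ = ModelConfig(
            vocab_size=len(self.vocab_), n_layers=self.n_layers, n_heads=self.n_heads,
            hidden_size=self.hidden_size, n_classes=len(self.classes_),
            max_len=self.max_len, entity_layers=self._resolve_entity_layers(),
            use_entity_embedding=self.use_entity_embedding,
            enabled_entity_types=frozenset(EntityType[t] if isinstance(t, str) else EntityType(t)
                                           for t in self.enabled_entity_types),
            dropout=self.dropout, attention_dropout=self.attention_dropout,
        )
        seqs = self._sequences(records, y_enc)
        dev = None
        if self.validation_fraction > 0:
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(len(seqs))
            n_dev = max(1, int(round(self.validation_fraction * len(seqs))))
            dev = [seqs[i] for i in order[:n_dev]]
            seqs = [seqs[i] for i in order[n_dev:]]
        tc = TrainConfig(batch_size=self.batch_size, epochs=self.epochs,
                         learning_rate=self.learning_rate, lr_grid=(self.learning_rate,),
                         weight_decay=self.weight_decay, warmup_ratio=self.warmup_ratio,
                         max_grad_norm=self.max_grad_norm, seed=self.random_state)
        self.params_, self.run_record_ = train(self.config_, tc, seqs, dev)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        seqs = self._sequences(list(X))
        return predict_proba_batch(self.params_, seqs, self.config_)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def _more_tags(self):
        return {"X_types": ["list"], "non_deterministic": False}
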