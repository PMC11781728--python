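"""BIO-tagged questionnaire text and its assembly into padded model inputs.

A record is a list of question-answer (QA) units.  Units are concatenated
into one token sequence

    [CLS] QA1 [SEP] QA2 [SEP] ... QAn [SEP]

with a parallel stream of per-token entity types (Symptom / Location /
Disease / Others) taken from BIO tags produced by a medical NER system.
The [CLS] position feeds the specialty classifier; [SEP] closes each unit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

PAD_TOKEN = "[PAD]"
UNK_TOKEN = "[UNK]"
CLS_TOKEN = "[CLS]"
SEP_TOKEN = "[SEP]"


class EntityType(IntEnum):
    """Per-token medical entity type.

    ``OTHERS`` covers untagged tokens, special tokens and padding; the
    medically relevant subset E = {SYMPTOM, LOCATION, DISEASE} is what the
    entity-aware attention mask keys on.  The integer values index the
    entity embedding table, so the order is fixed.
    """

    OTHERS = 0
    SYMPTOM = 1
    LOCATION = 2
    DISEASE = 3


#: The medically relevant entity types (excludes OTHERS).
MEDICAL_ENTITY_TYPES = frozenset({EntityType.SYMPTOM, EntityType.LOCATION, EntityType.DISEASE})

_BIO_SUFFIX = {"SYM": EntityType.SYMPTOM, "LOC": EntityType.LOCATION, "DIS": EntityType.DISEASE}
_SUFFIX_OF = {v: k for k, v in _BIO_SUFFIX.items()}


def bio_to_entity_types(bio_tags: Sequence[str]) -> list[EntityType]:
    """Map BIO tag strings to entity types, position by position.

    ``B-X`` and ``I-X`` both map to type X; ``O`` maps to OTHERS.  An
    ``I-X`` that does not continue a ``B-X``/``I-X`` span is accepted
    leniently (NER output is imperfect) and logged.

    Raises
    ------
    ValueError
        On any tag outside {O} ∪ {B-X, I-X : X ∈ {SYM, LOC, DIS}}, naming
        the offending position.
    """
    out: list[EntityType] = []
    prev_suffix: str | None = None
    for i, tag in enumerate(bio_tags):
        if tag == "O":
            out.append(EntityType.OTHERS)
            prev_suffix = None
            continue
        if len(tag) > 2 and tag[1] == "-" and tag[0] in "BI" and tag[2:] in _BIO_SUFFIX:
            prefix, suffix = tag[0], tag[2:]
            if prefix == "I" and prev_suffix != suffix:
                logger.warning("orphan I-%s at position %d mapped leniently", suffix, i)
            out.append(_BIO_SUFFIX[suffix])
            prev_suffix = suffix
            continue
        raise ValueError(f"malformed BIO tag {tag!r} at position {i}")
    return out


def entity_types_to_bio(types: Sequence[EntityType]) -> list[str]:
    """Re-encode entity types as BIO tags (maximal runs become spans)."""
    tags: list[str] = []
    prev = EntityType.OTHERS
    for t in types:
        if t == EntityType.OTHERS:
            tags.append("O")
        elif t == prev:
            tags.append(f"I-{_SUFFIX_OF[t]}")
        else:
            tags.append(f"B-{_SUFFIX_OF[t]}")
        prev = t
    return tags


class Vocabulary:
    """Bijective token -> id mapping with reserved special-token ids."""

    def __init__(self, tokens: Iterable[str] = ()):
        self._token_to_id: dict[str, int] = {
            PAD_TOKEN: 0, UNK_TOKEN: 1, CLS_TOKEN: 2, SEP_TOKEN: 3,
        }
        for tok in tokens:
            self.add(tok)

    @property
    def pad_id(self) -> int:
        return self._token_to_id[PAD_TOKEN]

    @property
    def unk_id(self) -> int:
        return self._token_to_id[UNK_TOKEN]

    @property
    def cls_id(self) -> int:
        return self._token_to_id[CLS_TOKEN]

    @property
    def sep_id(self) -> int:
        return self._token_to_id[SEP_TOKEN]

    def __len__(self) -> int:
        return len(self._token_to_id)

    def __contains__(self, token: str) -> bool:
        return token in self._token_to_id

    def add(self, token: str) -> int:
        if token not in self._token_to_id:
            self._token_to_id[token] = len(self._token_to_id)
        return self._token_to_id[token]

    def id_of(self, token: str) -> int:
        return self._token_to_id.get(token, self.unk_id)

    def tokens(self) -> list[str]:
        return list(self._token_to_id)

    @classmethod
    def from_records(cls, records: Iterable[Sequence[tuple[Sequence[str], Sequence[str]]]]) -> "Vocabulary":
        """Build a vocabulary from an iterable of QA-unit records."""
        vocab = cls()
        for qa_pairs in records:
            for tokens, _tags in qa_pairs:
                for tok in tokens:
                    vocab.add(tok)
        return vocab


@dataclass
class TaggedSequence:
    """One assembled model input: parallel token / type / segment streams."""

    tokens: list[str]
    token_ids: list[int]
    entity_types: list[EntityType]
    segment_ids: list[int]
    pad_flags: list[bool]
    label: int = 0

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def content_length(self) -> int:
        """Number of non-pad positions."""
        return len(self.tokens) - sum(self.pad_flags)

    def validate(self) -> None:
        n = len(self.tokens)
        streams = (self.token_ids, self.entity_types, self.segment_ids, self.pad_flags)
        if any(len(s) != n for s in streams):
            raise ValueError("per-token streams have unequal lengths")
        if n == 0 or self.tokens[0] != CLS_TOKEN:
            raise ValueError("sequence must start with [CLS]")
        in_pad = False
        for i in range(n):
            if self.pad_flags[i]:
                in_pad = True
                if self.entity_types[i] != EntityType.OTHERS or self.segment_ids[i] != 0:
                    raise ValueError(f"pad position {i} must carry OTHERS/segment 0")
            elif in_pad:
                raise ValueError("padding must be a suffix")
        if self.label < 0:
            raise ValueError("label must be non-negative")


def assemble_input(
    qa_pairs: Sequence[tuple[Sequence[str], Sequence[str]]],
    vocab: Vocabulary,
    label: int = 0,
) -> TaggedSequence:
    """Concatenate QA units into a [CLS] ... [SEP] sequence.

    Each unit is ``(tokens, bio_tags)``.  Segment ids alternate 0/1 per
    unit starting at 0, with [CLS] on segment 0 and each [SEP] attached to
    the unit it closes.  Special tokens carry entity type OTHERS.
    """
    if len(qa_pairs) == 0:
        raise ValueError("at least one QA unit is required")
    tokens: list[str] = [CLS_TOKEN]
    types: list[EntityType] = [EntityType.OTHERS]
    segments: list[int] = [0]
    for u, (unit_tokens, unit_tags) in enumerate(qa_pairs):
        if len(unit_tokens) != len(unit_tags):
            raise ValueError(f"unit {u}: {len(unit_tokens)} tokens vs {len(unit_tags)} tags")
        seg = u % 2
        tokens.extend(unit_tokens)
        types.extend(bio_to_entity_types(unit_tags))
        segments.extend([seg] * len(unit_tokens))
        tokens.append(SEP_TOKEN)
        types.append(EntityType.OTHERS)
        segments.append(seg)
    seq = TaggedSequence(
        tokens=tokens,
        token_ids=[vocab.id_of(t) for t in tokens],
        entity_types=types,
        segment_ids=segments,
        pad_flags=[False] * len(tokens),
        label=label,
    )
    return seq


def pad_and_truncate(seq: TaggedSequence, max_len: int, vocab: Vocabulary) -> TaggedSequence:
    """Return a copy with length exactly ``max_len``.

    Truncation keeps the prefix but always closes the sequence with [SEP];
    padding appends [PAD] positions flagged as pads with type OTHERS.
    """
    if max_len < 2:
        raise ValueError("max_len must be at least 2")
    n = len(seq)
    if n > max_len:
        out = TaggedSequence(
            tokens=seq.tokens[: max_len - 1] + [SEP_TOKEN],
            token_ids=seq.token_ids[: max_len - 1] + [vocab.sep_id],
            entity_types=seq.entity_types[: max_len - 1] + [EntityType.OTHERS],
            segment_ids=seq.segment_ids[: max_len - 1] + [seq.segment_ids[max_len - 2]],
            pad_flags=[False] * max_len,
            label=seq.label,
        )
        return out
    n_pad = max_len - n
    return TaggedSequence(
        tokens=seq.tokens + [PAD_TOKEN] * n_pad,
        token_ids=seq.token_ids + [vocab.pad_id] * n_pad,
        entity_types=seq.entity_types + [EntityType.OTHERS] * n_pad,
        segment_ids=seq.segment_ids + [0] * n_pad,
        pad_flags=[False] * n + [True] * n_pad,
        label=seq.label,
    )


def flatten_qa(qa_pairs: Sequence[tuple[Sequence[str], Sequence[str]]]) -> tuple[list[str], list[str]]:
    """Join QA units into one flat token/tag stream, separating units with
    a [SEP] token tagged ``O`` (the on-disk representation)."""
    tokens: list[str] = []
    tags: list[str] = []
    for i, (unit_tokens, unit_tags) in enumerate(qa_pairs):
        if i > 0:
            tokens.append(SEP_TOKEN)
            tags.append("O")
        tokens.extend(unit_tokens)
        tags.extend(unit_tags)
    return tokens, tags


def split_qa(tokens: Sequence[str], tags: Sequence[str]) -> list[tuple[list[str], list[str]]]:
    """Inverse of :func:`flatten_qa`: split a flat stream at [SEP] tokens."""
    units: list[tuple[list[str], list[str]]] = []
    cur_tok: list[str] = []
    cur_tag: list[str] = []
    for tok, tag in zip(tokens, tags):
        if tok == SEP_TOKEN:
            units.append((cur_tok, cur_tag))
            cur_tok, cur_tag = [], []
        else:
            cur_tok.append(tok)
            cur_tag.append(tag)
    units.append((cur_tok, cur_tag))
    return units


def records_to_sequences(
    records: Sequence[tuple[Sequence[str], Sequence[str], int]],
    vocab: Vocabulary,
    max_len: int | None = None,
) -> list[TaggedSequence]:
    """Assemble flat ``(tokens, bio_tags, label)`` records into model inputs,
    optionally padding/truncating to ``max_len``."""
    seqs = []
    for tokens, tags, label in records:
        seq = assemble_input(split_qa(tokens, tags), vocab, label)
        if max_len is not None:
            seq = pad_and_truncate(seq, max_len, vocab)
        seqs.append(seq)
    return seqs


# ---------------------------------------------------------------------------
# File formats: CoNLL-style two-column token/tag text, and JSON lines.
# Both store the raw (unpadded) token and BIO-tag streams plus a label.
# ---------------------------------------------------------------------------

def write_conll(records: Iterable[tuple[Sequence[str], Sequence[str], int]], path) -> None:
    """Write ``(tokens, bio_tags, label)`` records as blank-line-separated
    two-column blocks, each preceded by a ``# label=<k>`` header."""
    with open(path, "w", encoding="utf-8") as fh:
        for tokens, tags, label in records:
            fh.write(f"# label={label}\n")
            for tok, tag in zip(tokens, tags):
                fh.write(f"{tok} {tag}\n")
            fh.write("\n")


def read_conll(path) -> list[tuple[list[str], list[str], int]]:
    """Inverse of :func:`write_conll`; errors name the offending line."""
    records: list[tuple[list[str], list[str], int]] = []
    tokens: list[str] = []
    tags: list[str] = []
    label: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                if tokens:
                    if label is None:
                        raise ValueError(f"line {lineno}: record without a '# label=' header")
                    records.append((tokens, tags, label))
                    tokens, tags, label = [], [], None
                continue
            if line.startswith("#"):
                if line.startswith("# label="):
                    label = int(line.split("=", 1)[1])
                continue
            cols = line.split()
            if len(cols) != 2:
                raise ValueError(f"line {lineno}: expected 2 columns, got {len(cols)}")
            if label is None:
                raise ValueError(f"line {lineno}: token line before '# label=' header")
            tokens.append(cols[0])
            tags.append(cols[1])
    if tokens:
        if label is None:
            raise ValueError("final record lacks a '# label=' header")
        records.append((tokens, tags, label))
    return records


def write_jsonl(records: Iterable[tuple[Sequence[str], Sequence[str], int]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tokens, tags, label in records:
            fh.write(json.dumps({"tokens": list(tokens), "bio_tags": list(tags),
                                 "label": int(label)}) + "\n")


def read_jsonl(path) -> list[tuple[list[str], list[str], int]]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            obj = json.loads(raw)
            try:
                records.append((list(obj["tokens"]), list(obj["bio_tags"]), int(obj["label"])))
            except KeyError as e:
                raise ValueError(f"line {lineno}: missing field {e}") from e
    return records
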