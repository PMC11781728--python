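"""Synthetic BIO-tagged questionnaire corpora with a planted entity rule.

Real clinical questionnaire data of this kind is private, so this module
generates structurally equivalent corpora: multi-QA records, four
specialty classes, and Symptom / Location / Disease entity mentions at a
configurable frequency ratio (default 10,983 : 8,313 : 850, matching the
entity distribution of the motivating dataset).

**Planted rule.**  Each record carries two latent binary groups, a
location group and a symptom group; its class label is the fixed lookup

    label = 2 * location_group + symptom_group

so the label is decided by the *co-occurrence* of location and symptom
information, and disease mentions are rare, label-irrelevant distractors.

**Ambiguity.**  With probability ``ambiguity`` (rho) an entity mention is
drawn from a shared ambiguous pool instead of a type-specific lexicon.
Every pool token carries two independent attributes: the group it denotes
when used as a location, and the group it denotes when used as a symptom.
An ambiguous location mention of group l emits one pool token with
location-attribute l (tagged B-LOC) *and* one decoy token with
location-attribute 1-l (tagged O, a surface-similar non-entity such as a
negated mention).  Symptom mentions mirror this on the symptom attribute;
ambiguous disease mentions draw any pool token.  Each mention therefore
contributes one token from each half of the pool regardless of the latent
groups, so at rho = 1 the surface token distribution is identical across
all four classes: a model that ignores the supplied BIO tags is at chance,
while the tags identify the real mentions, whose attributes determine the
label exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import flatten_qa

#: Entity-token frequency targets (Symptom : Location : Disease).
DEFAULT_ENTITY_COUNTS = (10983, 8313, 850)

#: The fixed planted lookup table mapping (location_group, symptom_group)
#: to a class label; surjective onto the four classes.
PLANTED_RULE = {(0, 0): 0, (0, 1): 1, (1, 0): 2, (1, 1): 3}


def planted_label(location_group: int, symptom_group: int) -> int:
    """The planted class rule: label = 2 * location_group + symptom_group."""
    if location_group not in (0, 1) or symptom_group not in (0, 1):
        raise ValueError("latent groups must be 0 or 1")
    return PLANTED_RULE[(location_group, symptom_group)]


@dataclass(frozen=True)
class GeneratorConfig:
    """Corpus generation parameters.

    ``entity_proportions`` are the target shares of Symptom, Location and
    Disease among entity *mentions*; ``ambiguity`` is the probability that
    a mention's surface form is shared across entity types and therefore
    only interpretable through its BIO tag.
    """

    n_samples: int = 1000
    n_classes: int = 4
    qa_pairs_per_sample: tuple[int, int] = (2, 4)
    tokens_per_answer: tuple[int, int] = (4, 8)
    entity_proportions: tuple[float, float, float] = tuple(
        np.asarray(DEFAULT_ENTITY_COUNTS) / sum(DEFAULT_ENTITY_COUNTS))
    entity_events_per_sample: tuple[int, int] = (4, 7)
    ambiguity: float = 1.0
    n_fillers: int = 40
    entries_per_group: int = 8
    n_ambiguous: int = 16
    class_prior: tuple[float, float, float, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        p = np.asarray(self.entity_proportions, dtype=float)
        if p.shape != (3,) or (p <= 0).any() or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("entity_proportions must be 3 positive values summing to 1")
        if not 0.0 <= self.ambiguity <= 1.0:
            raise ValueError("ambiguity must lie in [0, 1]")
        if self.n_classes != 4:
            raise ValueError("the planted (location x symptom) rule defines exactly 4 classes")
        if self.n_samples <= 0 or self.entity_events_per_sample[0] < 2:
            raise ValueError("need a positive sample count and at least 2 entity events "
                             "(one location and one symptom) per record")
        if self.n_ambiguous < 4 or self.n_ambiguous % 4:
            raise ValueError("n_ambiguous must be a positive multiple of 4")
        if self.class_prior is not None:
            q = np.asarray(self.class_prior, dtype=float)
            if q.shape != (4,) or (q < 0).any() or abs(q.sum() - 1.0) > 1e-8:
                raise ValueError("class_prior must be 4 non-negative values summing to 1")

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples, "n_classes": self.n_classes,
            "qa_pairs_per_sample": list(self.qa_pairs_per_sample),
            "tokens_per_answer": list(self.tokens_per_answer),
            "entity_proportions": list(self.entity_proportions),
            "entity_events_per_sample": list(self.entity_events_per_sample),
            "ambiguity": self.ambiguity, "n_fillers": self.n_fillers,
            "entries_per_group": self.entries_per_group, "n_ambiguous": self.n_ambiguous,
            "class_prior": None if self.class_prior is None else list(self.class_prior),
            "seed": self.seed,
        }


@dataclass
class AmbiguousToken:
    surface: str
    location_group: int   # group denoted when the token is a location mention
    symptom_group: int    # group denoted when the token is a symptom mention


@dataclass
class Lexicon:
    """Surface vocabulary: grouped type-specific phrase lists, fillers, and
    the shared ambiguous pool.  Phrases are token tuples (1 or 2 tokens)."""

    symptom_groups: list[list[tuple[str, ...]]]
    location_groups: list[list[tuple[str, ...]]]
    disease: list[tuple[str, ...]]
    fillers: list[str]
    ambiguous: list[AmbiguousToken]

    @classmethod
    def build(cls, config: GeneratorConfig) -> "Lexicon":
        def group_entries(base: str, g: int) -> list[tuple[str, ...]]:
            entries: list[tuple[str, ...]] = []
            for i in range(config.entries_per_group):
                if i < 2:
                    # a two-token phrase sharing its head with a one-token
                    # entry, so longest-match tagging is exercised
                    entries.append((f"{base}{g}_{i}", f"{base}{g}_{i}b"))
                    entries.append((f"{base}{g}_{i}",))
                else:
                    entries.append((f"{base}{g}_{i}",))
            return entries

        per_cat = config.n_ambiguous // 4
        ambiguous = [AmbiguousToken(f"amb_{u}{v}_{i}", u, v)
                     for u in (0, 1) for v in (0, 1) for i in range(per_cat)]
        return cls(
            symptom_groups=[group_entries("sym", g) for g in (0, 1)],
            location_groups=[group_entries("loc", g) for g in (0, 1)],
            disease=[(f"dis_{i}",) for i in range(config.entries_per_group)],
            fillers=[f"w{i}" for i in range(config.n_fillers)],
            ambiguous=ambiguous,
        )

    def phrases_of_type(self, suffix: str) -> list[tuple[str, ...]]:
        """All unambiguous phrases of one BIO type suffix (SYM/LOC/DIS)."""
        if suffix == "SYM":
            return [p for g in self.symptom_groups for p in g]
        if suffix == "LOC":
            return [p for g in self.location_groups for p in g]
        if suffix == "DIS":
            return list(self.disease)
        raise ValueError(f"unknown entity suffix {suffix!r}")

    def ambiguous_surfaces(self) -> set[str]:
        return {t.surface for t in self.ambiguous}


@dataclass
class SyntheticRecord:
    """One generated questionnaire record."""

    qa_pairs: list[tuple[list[str], list[str]]]
    label: int
    location_group: int
    symptom_group: int

    def flat(self) -> tuple[list[str], list[str], int]:
        tokens, tags = flatten_qa(self.qa_pairs)
        return tokens, tags, self.label


def _pick(rng: np.random.Generator, items: Sequence):
    return items[rng.integers(len(items))]


def _mention_runs(rng, lexicon, suffix: str, group: int | None,
                  ambiguous: bool) -> list[tuple[list[str], list[str]]]:
    """Token/tag runs emitted by one entity mention (plus its decoy, if
    the mention is ambiguous)."""
    if not ambiguous:
        if suffix == "DIS":
            phrase = _pick(rng, lexicon.disease)
        elif suffix == "SYM":
            phrase = _pick(rng, lexicon.symptom_groups[group])
        else:
            phrase = _pick(rng, lexicon.location_groups[group])
        tags = [f"B-{suffix}"] + [f"I-{suffix}"] * (len(phrase) - 1)
        return [(list(phrase), tags)]
    pool = lexicon.ambiguous
    if suffix == "DIS":
        tok = _pick(rng, pool)
        return [([tok.surface], ["B-DIS"])]
    if suffix == "SYM":
        real = _pick(rng, [t for t in pool if t.symptom_group == group])
        decoy = _pick(rng, [t for t in pool if t.symptom_group == 1 - group])
    else:
        real = _pick(rng, [t for t in pool if t.location_group == group])
        decoy = _pick(rng, [t for t in pool if t.location_group == 1 - group])
    return [([real.surface], [f"B-{suffix}"]), ([decoy.surface], ["O"])]


def _generate_record(rng: np.random.Generator, config: GeneratorConfig,
                     lexicon: Lexicon) -> SyntheticRecord:
    if config.class_prior is None:
        label = int(rng.integers(4))
    else:
        label = int(rng.choice(4, p=np.asarray(config.class_prior, dtype=float)))
    loc_group, sym_group = label >> 1, label & 1

    # entity mentions: i.i.d. types at the target proportions, redrawn until
    # at least one symptom and one location mention are present
    lo, hi = config.entity_events_per_sample
    p = np.asarray(config.entity_proportions, dtype=float)
    while True:
        n_events = int(rng.integers(lo, hi + 1))
        types = rng.choice(3, size=n_events, p=p)  # 0=SYM, 1=LOC, 2=DIS
        if (types == 0).any() and (types == 1).any():
            break

    runs: list[tuple[list[str], list[str]]] = []
    for t in types:
        suffix = ("SYM", "LOC", "DIS")[t]
        group = {"SYM": sym_group, "LOC": loc_group, "DIS": None}[suffix]
        ambiguous = bool(rng.random() < config.ambiguity)
        runs.extend(_mention_runs(rng, lexicon, suffix, group, ambiguous))

    # distribute the mention runs over the answers of the QA units
    n_pairs = int(rng.integers(config.qa_pairs_per_sample[0], config.qa_pairs_per_sample[1] + 1))
    owners = rng.integers(n_pairs, size=len(runs))
    qa_pairs: list[tuple[list[str], list[str]]] = []
    t_lo, t_hi = config.tokens_per_answer
    for u in range(n_pairs):
        q_tokens = [str(_pick(rng, lexicon.fillers)) for _ in range(int(rng.integers(2, 5)))]
        answer_runs = [runs[i] for i in np.flatnonzero(owners == u)]
        n_answer = int(rng.integers(t_lo, t_hi + 1))
        n_fill = max(0, n_answer - sum(len(r[0]) for r in answer_runs))
        answer_runs += [([str(_pick(rng, lexicon.fillers))], ["O"]) for _ in range(n_fill)]
        order = rng.permutation(len(answer_runs))
        a_tokens = [tok for i in order for tok in answer_runs[i][0]]
        a_tags = [tag for i in order for tag in answer_runs[i][1]]
        tokens = q_tokens + a_tokens
        tags = ["O"] * len(q_tokens) + a_tags
        qa_pairs.append((tokens, tags))
    return SyntheticRecord(qa_pairs=qa_pairs, label=label,
                           location_group=loc_group, symptom_group=sym_group)


def generate_corpus(config: GeneratorConfig,
                    lexicon: Lexicon | None = None) -> list[SyntheticRecord]:
    """Generate ``config.n_samples`` records; deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lexicon = lexicon if lexicon is not None else Lexicon.build(config)
    return [_generate_record(rng, config, lexicon) for _ in range(config.n_samples)]


def entity_token_counts(records: Sequence[SyntheticRecord]) -> dict[str, int]:
    """Count entity tokens by type over a corpus (from the BIO tags)."""
    counts = {"SYM": 0, "LOC": 0, "DIS": 0}
    for rec in records:
        for _tokens, tags in rec.qa_pairs:
            for tag in tags:
                if tag != "O":
                    counts[tag[2:]] += 1
    return counts


def lexicon_tag(tokens: Sequence[str], lexicon: Lexicon) -> list[str]:
    """Dictionary-based stand-in for a medical NER model.

    Greedy longest-match left to right over the unambiguous lexicon
    phrases; matched spans emit B-X / I-X.  Ambiguous-pool surfaces emit
    ``O``: their type cannot be resolved from the surface form, which is
    exactly why externally supplied tags are informative.
    """
    phrase_type: dict[tuple[str, ...], str] = {}
    for suffix in ("SYM", "LOC", "DIS"):
        for phrase in lexicon.phrases_of_type(suffix):
            phrase_type[tuple(phrase)] = suffix
    max_len = max((len(p) for p in phrase_type), default=1)
    ambiguous = lexicon.ambiguous_surfaces()
    tags = ["O"] * len(tokens)
    i = 0
    while i < len(tokens):
        if tokens[i] in ambiguous:
            i += 1
            continue
        matched = 0
        for span in range(min(max_len, len(tokens) - i), 0, -1):
            suffix = phrase_type.get(tuple(tokens[i:i + span]))
            if suffix is not None:
                tags[i] = f"B-{suffix}"
                for j in range(i + 1, i + span):
                    tags[j] = f"I-{suffix}"
                matched = span
                break
        i += matched if matched else 1
    return tags


def write_corpus(records: Sequence[SyntheticRecord], path, fmt: str = "jsonl",
                 config: GeneratorConfig | None = None, manifest_path=None) -> None:
    """Write a corpus in one of the data_model formats, plus an optional
    manifest recording the generating configuration."""
    from . import data_model

    flat = [r.flat() for r in records]
    if fmt == "jsonl":
        data_model.write_jsonl(flat, path)
    elif fmt == "conll":
        data_model.write_conll(flat, path)
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")
    if manifest_path is not None and config is not None:
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump({"format": fmt, "n_records": len(records),
                       "config": config.to_dict()}, fh, indent=2)
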