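import numpy as np
import pytest
from dataclasses import replace

from entformer import (EntityType, GeneratorConfig, ModelConfig, Vocabulary,
                       assemble_input, generate_corpus)
from entformer.data_model import MEDICAL_ENTITY_TYPES
from entformer.training import TrainConfig, macro_f1_of, train

# Study conditions of the planted-signal experiment: 2,500 records with the
# entity type fully undecidable from surface form (rho = 1), small encoder
# profile (L=2, H=4, d=64), at most 10 training epochs; 500 held-out records.
PLANTED_N = 2500
PLANTED_TEST = 500
PLANTED_DEV = 200
PLANTED_EPOCHS = 6


def planted_dataset(seed: int):
    cfg = GeneratorConfig(n_samples=PLANTED_N, ambiguity=1.0, seed=seed)
    records = generate_corpus(cfg)
    vocab = Vocabulary.from_records([r.qa_pairs for r in records])
    seqs = [assemble_input(r.qa_pairs, vocab, r.label) for r in records]
    test = seqs[-PLANTED_TEST:]
    dev = seqs[:PLANTED_DEV]
    tr = seqs[PLANTED_DEV:-PLANTED_TEST]
    base = ModelConfig(vocab_size=len(vocab))
    return {"records": records, "vocab": vocab, "train": tr, "dev": dev,
            "test": test, "base_config": base}


def planted_variant(base: ModelConfig, name: str) -> ModelConfig:
    E = MEDICAL_ENTITY_TYPES
    variants = {
        "full": base,
        "blind": replace(base, use_entity_embedding=False, entity_layers=frozenset()),
        "wo_location": replace(base, enabled_entity_types=frozenset(E - {EntityType.LOCATION})),
        "wo_symptom": replace(base, enabled_entity_types=frozenset(E - {EntityType.SYMPTOM})),
        "wo_disease": replace(base, enabled_entity_types=frozenset(E - {EntityType.DISEASE})),
    }
    return variants[name]


@pytest.fixture(scope="session")
def planted_runs():
    """Lazily train (seed, variant) models on the planted corpus and cache
    the outcome so several acceptance checks can share one training run."""
    data_cache: dict[int, dict] = {}
    run_cache: dict[tuple[int, str], dict] = {}

    def get(seed: int, variant: str) -> dict:
        key = (seed, variant)
        if key not in run_cache:
            if seed not in data_cache:
                data_cache[seed] = planted_dataset(seed)
            data = data_cache[seed]
            config = planted_variant(data["base_config"], variant)
            tc = TrainConfig.small_profile(epochs=PLANTED_EPOCHS, seed=seed)
            params, record = train(config, tc, data["train"], data["dev"])
            run_cache[key] = {
                "params": params, "record": record, "config": config,
                "test": data["test"],
                "test_macro_f1": macro_f1_of(params, data["test"], config),
            }
        return run_cache[key]

    return get


@pytest.fixture(scope="session")
def tiny_corpus():
    """A small unambiguous corpus for smoke training and IO tests."""
    cfg = GeneratorConfig(n_samples=200, ambiguity=0.0, seed=7)
    records = generate_corpus(cfg)
    vocab = Vocabulary.from_records([r.qa_pairs for r in records])
    seqs = [assemble_input(r.qa_pairs, vocab, r.label) for r in records]
    return {"records": records, "vocab": vocab, "seqs": seqs, "config": cfg}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
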