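"""End-to-end orchestration: synth -> build-kg -> train-kge -> train-clf ->
evaluate, with one global seed threaded deterministically through every
stage. Re-running with the same config reproduces every metric report
byte-identically.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from kdsd.errors import ConfigError
from kdsd.kg import build_kg, kg_stats, write_triples, write_vocab
from kdsd.kge import (KGETrainConfig, evaluate_link_prediction,
                      kg_baseline_predict, split_triples, train_kge)
from kdsd.metrics import evaluate_batch
from kdsd.model import (ClassifierTrainConfig, EncoderConfig, KDSDClassifier,
                        Vocab)
from kdsd.records import (EMRRecord, build_input_sequence,
                          extract_chief_entities, tokenize, write_records)
from kdsd.synth import (SynthConfig, World, generate_records, generate_world,
                        split_records, write_world)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    synth: SynthConfig = SynthConfig()
    kge: KGETrainConfig = KGETrainConfig(dim=32, epochs=150)
    encoder: EncoderConfig = EncoderConfig()
    train: ClassifierTrainConfig = ClassifierTrainConfig()
    test_fraction: float = 0.2
    kge_test_fraction: float = 0.1
    max_length: int = 256
    fusion_enabled: bool = True
    run_kg_baseline: bool = True
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        self.synth.validate()
        self.kge.validate()
        self.encoder.validate()
        self.train.validate()
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError("test_fraction must lie in (0,1)")


def _stage_seeds(seed: int) -> dict[str, int]:
    """Distinct deterministic child seeds for every stochastic stage."""
    ss = np.random.SeedSequence(seed)
    names = ("synth", "split", "kge", "encoder", "train")
    states = ss.generate_state(len(names))
    return {n: int(s % (2**31 - 1)) for n, s in zip(names, states)}


def record_entities(rec: EMRRecord, kg, chief_lexicon: dict[str, str]
                    ) -> list[str]:
    """Symptom tokens plus extracted chief entities, for KG linking."""
    ents = [tok for _, text in rec.symptom_fields for tok in tokenize(text)]
    if chief_lexicon and rec.chief_complaint:
        res = extract_chief_entities(rec.chief_complaint, chief_lexicon)
        ents.extend(e.entity_id for e in res.entities)
    return ents


def run(config: RunConfig) -> dict:
    """Execute all enabled stages; returns (and optionally writes) the
    manifest of artifacts, seeds, and metric reports."""
    config.validate()
    seeds = _stage_seeds(config.seed)
    t0 = time.time()
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # -- synthesize + split
    synth_cfg = replace(config.synth, seed=seeds["synth"])
    world = generate_world(synth_cfg)
    records = generate_records(world, synth_cfg)
    train_recs, test_recs, n_moved = split_records(
        records, config.test_fraction, enforce_label_rule=True,
        seed=seeds["split"])
    log.info("split: %d train / %d test records (%d moved by label rule)",
             len(train_recs), len(test_recs), n_moved)

    # -- knowledge graph from training records
    kg = build_kg(train_recs, world.nature_lexicon, world.location_lexicon,
                  chief_lexicon=world.chief_lexicon)
    stats = kg_stats(kg)

    # -- KG embeddings + link-prediction evaluation
    kge_cfg = replace(config.kge, seed=seeds["kge"])
    kge_train, kge_test = split_triples(kg, config.kge_test_fraction,
                                        seed=seeds["kge"])
    emb = train_kge(kg, kge_cfg, triples=kge_train)
    linkpred = {
        mode: evaluate_link_prediction(kge_test, emb, kg, mode=mode).to_dict()
        for mode in ("filtered", "raw")}

    # -- input sequences + classifier
    label_space = kg.label_space
    train_seqs = [build_input_sequence(r, kg, config.max_length)
                  for r in train_recs]
    test_seqs = [build_input_sequence(r, kg, config.max_length)
                 for r in test_recs]
    vocab = Vocab.build(train_seqs, min_freq=config.encoder.min_token_freq)
    enc_cfg = replace(config.encoder, max_len=config.max_length,
                      seed=seeds["encoder"])
    model = KDSDClassifier(label_space, vocab, enc_cfg, entity_emb=emb,
                           fusion_enabled=config.fusion_enabled)
    train_cfg = replace(config.train, seed=seeds["train"])
    history = model.fit(
        train_seqs, [r.gold_labels for r in train_recs], train_cfg,
        val_sequences=test_seqs, val_targets=[r.gold_labels for r in test_recs])

    scores = np.stack([model.predict(s) for s in test_seqs])
    truths = np.stack([model.labels_to_vector(r.gold_labels)
                       for r in test_recs])
    metrics_kdsd = evaluate_batch(scores, truths).to_dict()

    # -- KG-only baseline
    metrics_baseline = None
    if config.run_kg_baseline:
        base_scores = np.stack([
            kg_baseline_predict(
                record_entities(r, kg, world.chief_lexicon), emb, kg,
                label_space)
            for r in test_recs])
        metrics_baseline = evaluate_batch(base_scores, truths).to_dict()

    manifest = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "counts": {
            "records": len(records),
            "train_records": len(train_recs),
            "test_records": len(test_recs),
            "moved_by_label_rule": n_moved,
            "kge_train_triples": len(kge_train),
            "kge_test_triples": len(kge_test),
            "labels": len(label_space),
        },
        "kg_stats": stats,
        "link_prediction": linkpred,
        "fusion_enabled": config.fusion_enabled,
        "final_train_loss": history["loss"][-1],
        "val_p_at_1": history["val_p_at_1"][-1],
        "metrics_kdsd": metrics_kdsd,
        "metrics_kg_baseline": metrics_baseline,
        "wall_seconds": round(time.time() - t0, 2),
    }

    if out is not None:
        write_world(world, out / "world.json")
        write_records(train_recs, out / "train_records.jsonl")
        write_records(test_recs, out / "test_records.jsonl")
        write_triples(kg, out / "triples.tsv")
        write_vocab(kg, out / "entities.tsv")
        emb.save(out / "embeddings.npz", out / "embeddings.json")
        model.save(out / "model.npz", out / "model.json")
        _dump(metrics_kdsd, out / "metrics_kdsd.json")
        if metrics_baseline is not None:
            _dump(metrics_baseline, out / "metrics_kg_baseline.json")
        manifest_to_write = dict(manifest)
        manifest_to_write.pop("wall_seconds")  # timing is not reproducible
        _dump(manifest_to_write, out / "manifest.json")
    return manifest


def _dump(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
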