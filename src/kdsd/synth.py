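"""Synthetic clinical worlds for end-to-end testing of the diagnosis pipeline.

A *world* is a set of latent syndromes. Each syndrome owns a symptom set, a
chief-complaint set, and nature/location label sets; its surface string is
the concatenation of its label tokens, so syndrome decomposition is
well-defined by construction. Records are sampled by choosing a syndrome,
emitting its symptoms across the five symptom fields and its chief entities
(with neutral filler words) as the chief complaint, and attaching the
syndrome's labels as gold truth. Noise optionally swaps one symptom token
per record for a uniformly random vocabulary symptom.

Symbolic tokens (``sym_0042``, ``cc_0007``, ``nat_003``, ``loc_002``) stand
in for clinical surface strings; the whole pipeline is script-agnostic
because all matching is token-level.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from math import comb

import numpy as np

from kdsd.errors import ConfigError
from kdsd.records import SYMPTOM_FIELDS, EMRRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthConfig:
    n_syndromes: int = 5
    n_symptom_vocab: int = 20
    n_chief_vocab: int = 10
    n_nature_labels: int = 4
    n_location_labels: int = 4
    symptoms_per_syndrome: int = 4
    chiefs_per_syndrome: int = 2
    natures_per_syndrome: int = 2
    locations_per_syndrome: int = 2
    noise_rate: float = 0.0
    n_records: int = 100
    syndrome_skew: float = 0.0  # 0 = uniform syndrome sampling
    #: syndromes per family; families share a symptom/chief pool so related
    #: syndromes overlap heavily (None = independent draws from full vocab)
    group_size: int | None = None
    n_filler_words: int = 6     # non-entity words mixed into chief complaints
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_syndromes", "n_symptom_vocab", "n_chief_vocab",
                     "n_nature_labels", "n_location_labels",
                     "symptoms_per_syndrome", "chiefs_per_syndrome",
                     "natures_per_syndrome", "locations_per_syndrome",
                     "n_records"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ConfigError(f"noise_rate {self.noise_rate} outside [0,1]")
        if self.symptoms_per_syndrome > self.n_symptom_vocab:
            raise ConfigError(
                f"symptoms_per_syndrome ({self.symptoms_per_syndrome}) exceeds "
                f"n_symptom_vocab ({self.n_symptom_vocab})")
        if self.chiefs_per_syndrome > self.n_chief_vocab:
            raise ConfigError(
                f"chiefs_per_syndrome ({self.chiefs_per_syndrome}) exceeds "
                f"n_chief_vocab ({self.n_chief_vocab})")
        if self.natures_per_syndrome > self.n_nature_labels:
            raise ConfigError(
                f"natures_per_syndrome ({self.natures_per_syndrome}) exceeds "
                f"n_nature_labels ({self.n_nature_labels})")
        if self.locations_per_syndrome > self.n_location_labels:
            raise ConfigError(
                f"locations_per_syndrome ({self.locations_per_syndrome}) "
                f"exceeds n_location_labels ({self.n_location_labels})")
        n_combos = (comb(self.n_nature_labels, self.natures_per_syndrome)
                    * comb(self.n_location_labels, self.locations_per_syndrome))
        if n_combos < self.n_syndromes:
            raise ConfigError(
                f"only {n_combos} distinct label combinations available for "
                f"{self.n_syndromes} syndromes")
        if self.group_size is not None:
            if self.group_size < 1:
                raise ConfigError("group_size must be a positive integer")
            n_groups = -(-self.n_syndromes // self.group_size)
            if self.n_symptom_vocab // n_groups < self.symptoms_per_syndrome:
                raise ConfigError(
                    f"symptom pool per group "
                    f"({self.n_symptom_vocab // n_groups}) smaller than "
                    f"symptoms_per_syndrome ({self.symptoms_per_syndrome})")
            if self.n_chief_vocab // n_groups < self.chiefs_per_syndrome:
                raise ConfigError(
                    f"chief pool per group ({self.n_chief_vocab // n_groups}) "
                    f"smaller than chiefs_per_syndrome "
                    f"({self.chiefs_per_syndrome})")


@dataclass(frozen=True)
class Syndrome:
    name: str
    surface: str
    symptoms: tuple[str, ...]
    chiefs: tuple[str, ...]
    natures: tuple[str, ...]
    locations: tuple[str, ...]


@dataclass(frozen=True)
class World:
    symptom_vocab: tuple[str, ...]
    chief_vocab: tuple[str, ...]
    nature_vocab: tuple[str, ...]
    location_vocab: tuple[str, ...]
    filler_vocab: tuple[str, ...]
    syndromes: tuple[Syndrome, ...]

    @property
    def nature_lexicon(self) -> dict[str, str]:
        return {t: t for t in self.nature_vocab}

    @property
    def location_lexicon(self) -> dict[str, str]:
        return {t: t for t in self.location_vocab}

    @property
    def chief_lexicon(self) -> dict[str, str]:
        return {t: t for t in self.chief_vocab}


def generate_world(config: SynthConfig) -> World:
    """Draw a world deterministically from ``config.seed``.

    Each syndrome's symptom/chief sets are drawn without replacement from
    their vocabularies; label combinations are distinct across syndromes so
    every syndrome surface string is unique.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    symptom_vocab = tuple(f"sym_{i:04d}" for i in range(config.n_symptom_vocab))
    chief_vocab = tuple(f"cc_{i:04d}" for i in range(config.n_chief_vocab))
    nature_vocab = tuple(f"nat_{i:03d}" for i in range(config.n_nature_labels))
    location_vocab = tuple(f"loc_{i:03d}" for i in range(config.n_location_labels))
    filler_vocab = tuple(f"w_{i:02d}" for i in range(config.n_filler_words))

    if config.group_size is not None:
        n_groups = -(-config.n_syndromes // config.group_size)
        sym_pools = np.array_split(
            rng.permutation(config.n_symptom_vocab), n_groups)
        chief_pools = np.array_split(
            rng.permutation(config.n_chief_vocab), n_groups)

    seen_combos: set[tuple] = set()
    syndromes: list[Syndrome] = []
    for s in range(config.n_syndromes):
        if config.group_size is not None:
            g = s // config.group_size
            sym_src, chief_src = sym_pools[g], chief_pools[g]
        else:
            sym_src = np.arange(config.n_symptom_vocab)
            chief_src = np.arange(config.n_chief_vocab)
        symptoms = tuple(sorted(rng.choice(
            sym_src, size=config.symptoms_per_syndrome,
            replace=False).tolist()))
        chiefs = tuple(sorted(rng.choice(
            chief_src, size=config.chiefs_per_syndrome,
            replace=False).tolist()))
        while True:
            natures = tuple(sorted(rng.choice(
                config.n_nature_labels, size=config.natures_per_syndrome,
                replace=False)))
            locations = tuple(sorted(rng.choice(
                config.n_location_labels, size=config.locations_per_syndrome,
                replace=False)))
            if (natures, locations) not in seen_combos:
                seen_combos.add((natures, locations))
                break
        nat_toks = tuple(nature_vocab[i] for i in natures)
        loc_toks = tuple(location_vocab[i] for i in locations)
        surface = " ".join(nat_toks + loc_toks)
        syndromes.append(Syndrome(
            name=f"syn_{s:03d}",
            surface=surface,
            symptoms=tuple(symptom_vocab[i] for i in symptoms),
            chiefs=tuple(chief_vocab[i] for i in chiefs),
            natures=nat_toks,
            locations=loc_toks,
        ))
    return World(symptom_vocab, chief_vocab, nature_vocab, location_vocab,
                 filler_vocab, tuple(syndromes))


def _syndrome_weights(world: World, skew: float) -> np.ndarray:
    n = len(world.syndromes)
    if skew <= 0:
        return np.full(n, 1.0 / n)
    w = np.arange(1, n + 1, dtype=float) ** skew
    return w / w.sum()


def generate_records(world: World, config: SynthConfig,
                     rng: np.random.Generator | None = None
                     ) -> list[EMRRecord]:
    """Sample ``config.n_records`` records from the world.

    Symptom tokens are distributed round-robin over the five symptom fields.
    With probability ``noise_rate`` one symptom token is replaced by a
    uniformly random vocabulary symptom (the replacement may coincide with
    the original). Gold labels are always the owning syndrome's labels —
    noise perturbs symptoms only.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    weights = _syndrome_weights(world, config.syndrome_skew)
    records: list[EMRRecord] = []
    for i in range(config.n_records):
        syn = world.syndromes[rng.choice(len(world.syndromes), p=weights)]
        symptoms = list(syn.symptoms)
        if config.noise_rate > 0 and rng.random() < config.noise_rate:
            j = int(rng.integers(len(symptoms)))
            symptoms[j] = world.symptom_vocab[
                int(rng.integers(len(world.symptom_vocab)))]
        fields: dict[str, list[str]] = {f: [] for f in SYMPTOM_FIELDS}
        for j, tok in enumerate(symptoms):
            fields[SYMPTOM_FIELDS[j % len(SYMPTOM_FIELDS)]].append(tok)
        symptom_fields = tuple(
            (name, " ".join(toks)) for name, toks in fields.items() if toks)
        chief_words: list[str] = []
        for tok in syn.chiefs:
            chief_words.append(
                world.filler_vocab[int(rng.integers(len(world.filler_vocab)))])
            chief_words.append(tok)
        records.append(EMRRecord(
            record_id=f"r_{i:06d}",
            symptom_fields=symptom_fields,
            chief_complaint=" ".join(chief_words),
            syndrome=syn.surface,
            gold_natures=frozenset(syn.natures),
            gold_locations=frozenset(syn.locations),
        ))
    return records


def split_records(records: list[EMRRecord], test_fraction: float = 0.2,
                  enforce_label_rule: bool = True, seed: int = 0
                  ) -> tuple[list[EMRRecord], list[EMRRecord], int]:
    """Random train/test split enforcing the label-coverage rule.

    Only test records whose every gold label also occurs in the training
    split stay in the test set; violating records are moved to training and
    counted. Returns (train, test, n_moved).
    """
    if not 0.0 < test_fraction < 1.0:
        raise ConfigError(f"test_fraction {test_fraction} outside (0,1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    n_test = max(1, int(round(test_fraction * len(records))))
    test_idx = set(order[:n_test].tolist())
    train = [records[i] for i in range(len(records)) if i not in test_idx]
    test = [records[i] for i in range(len(records)) if i in test_idx]
    n_moved = 0
    if enforce_label_rule:
        train_labels: set[str] = set()
        for r in train:
            train_labels |= r.gold_labels
        kept: list[EMRRecord] = []
        for r in test:
            if r.gold_labels <= train_labels:
                kept.append(r)
            else:
                train.append(r)
                train_labels |= r.gold_labels
                n_moved += 1
        test = kept
        if n_moved:
            log.info("split_records: moved %d test records with unseen "
                     "labels into training", n_moved)
    return train, test, n_moved


# ---------------------------------------------------------------------------
# world sidecar persistence (for oracle checks)


def write_world(world: World, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(asdict(world), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_world(path) -> World:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    syndromes = tuple(
        Syndrome(name=s["name"], surface=s["surface"],
                 symptoms=tuple(s["symptoms"]), chiefs=tuple(s["chiefs"]),
                 natures=tuple(s["natures"]), locations=tuple(s["locations"]))
        for s in obj["syndromes"])
    return World(
        symptom_vocab=tuple(obj["symptom_vocab"]),
        chief_vocab=tuple(obj["chief_vocab"]),
        nature_vocab=tuple(obj["nature_vocab"]),
        location_vocab=tuple(obj["location_vocab"]),
        filler_vocab=tuple(obj["filler_vocab"]),
        syndromes=syndromes)
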