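"""Syndrome decomposition and construction of the four-relation medical KG.

The graph has five entity categories (symptom, chief_complaint, syndrome,
nature, location) and four typed relations:

    chief entity --chief_complaint_syndrome--> syndrome
    symptom      --symptom_syndrome-->         syndrome
    syndrome     --syndrome_nature-->          nature label
    syndrome     --syndrome_location-->        location label

A syndrome string such as "damp-heat obstructing the meridian" decomposes,
via nature/location lexicons, into its disease-nature labels (damp-heat,
obstruction) and disease-location labels (meridians); those label entities
form the multilabel prediction space downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from kdsd.errors import DataError
from kdsd.records import EMRRecord, extract_chief_entities, tokenize

log = logging.getLogger(__name__)

REL_CHIEF = "chief_complaint_syndrome"
REL_SYMPTOM = "symptom_syndrome"
REL_NATURE = "syndrome_nature"
REL_LOCATION = "syndrome_location"
RELATIONS = (REL_CHIEF, REL_SYMPTOM, REL_NATURE, REL_LOCATION)
CATEGORIES = ("symptom", "chief_complaint", "syndrome", "nature", "location")

#: (head category, tail category) signature of each relation
REL_SIGNATURE = {
    REL_CHIEF: ("chief_complaint", "syndrome"),
    REL_SYMPTOM: ("symptom", "syndrome"),
    REL_NATURE: ("syndrome", "nature"),
    REL_LOCATION: ("syndrome", "location"),
}

#: relation whose tail is the given label category
LABEL_RELATION = {"nature": REL_NATURE, "location": REL_LOCATION}


@dataclass(frozen=True, order=True)
class Triple:
    head: str
    relation: str
    tail: str


@dataclass
class KGraph:
    """Entity vocabulary (id -> category) plus a set of typed triples."""

    entities: dict[str, str] = field(default_factory=dict)
    triples: set[Triple] = field(default_factory=set)

    def add_entity(self, entity_id: str, category: str) -> None:
        if category not in CATEGORIES:
            raise DataError(f"unknown category {category!r}")
        prev = self.entities.get(entity_id)
        if prev is not None and prev != category:
            raise DataError(
                f"entity {entity_id!r} registered as both {prev} and {category}")
        self.entities[entity_id] = category

    def add_triple(self, head: str, relation: str, tail: str) -> None:
        if relation not in REL_SIGNATURE:
            raise DataError(f"unknown relation {relation!r}")
        hc, tc = REL_SIGNATURE[relation]
        self.add_entity(head, hc)
        self.add_entity(tail, tc)
        self.triples.add(Triple(head, relation, tail))

    def entity_ids(self) -> list[str]:
        return sorted(self.entities)

    def entities_of(self, category: str) -> list[str]:
        return sorted(e for e, c in self.entities.items() if c == category)

    @property
    def label_space(self) -> list[str]:
        """Nature plus location entities, the multilabel prediction space."""
        return self.entities_of("nature") + self.entities_of("location")

    def __eq__(self, other) -> bool:
        return (isinstance(other, KGraph)
                and self.entities == other.entities
                and self.triples == other.triples)


def _normalize(s: str) -> str:
    return " ".join(s.split())


def decompose_syndrome(syndrome: str,
                       nature_lexicon: dict[str, str],
                       location_lexicon: dict[str, str]
                       ) -> tuple[set[str], set[str]]:
    """Split a syndrome string into its nature and location label sets.

    Greedy longest-match over the union of both lexicons, scanning the
    character/token sequence left to right, so e.g. a "damp-heat" surface
    wins over its "heat" substring. Empty results are logged.
    """
    if not nature_lexicon or not location_lexicon:
        raise DataError("nature and location lexicons must be non-empty")
    toks = tokenize(_normalize(syndrome))
    nat_map = {tuple(tokenize(s)): lab for s, lab in nature_lexicon.items()}
    loc_map = {tuple(tokenize(s)): lab for s, lab in location_lexicon.items()}
    combined = {**nat_map, **loc_map}
    natures: set[str] = set()
    locations: set[str] = set()
    max_len = max(len(k) for k in combined)
    i = 0
    while i < len(toks):
        matched = False
        for length in range(min(max_len, len(toks) - i), 0, -1):
            cand = tuple(toks[i:i + length])
            if cand in nat_map:
                natures.add(nat_map[cand])
            elif cand in loc_map:
                locations.add(loc_map[cand])
            else:
                continue
            i += length
            matched = True
            break
        if not matched:
            i += 1
    if not natures and not locations:
        log.warning("syndrome %r matched no nature/location lexicon entry",
                    syndrome)
    return natures, locations


def build_kg(records: list[EMRRecord],
             nature_lexicon: dict[str, str],
             location_lexicon: dict[str, str],
             chief_lexicon: dict[str, str] | None = None,
             add_inverse: bool = False) -> KGraph:
    """Assemble the knowledge graph from parsed records.

    Each record contributes symptom->syndrome and chief->syndrome edges for
    its entities plus syndrome->label edges from decomposing its syndrome
    string; duplicate triples across records collapse (set semantics).
    Records with an empty syndrome are skipped with a warning. With
    ``add_inverse`` every edge is mirrored under an ``inverse_*`` head/tail
    swap — off by default; training uses the stated direction.
    """
    kg = KGraph()
    skipped = 0
    for rec in records:
        syndrome = _normalize(rec.syndrome)
        if not syndrome:
            skipped += 1
            continue
        for _, text in rec.symptom_fields:
            for tok in tokenize(text):
                kg.add_triple(tok, REL_SYMPTOM, syndrome)
        if chief_lexicon and rec.chief_complaint:
            res = extract_chief_entities(rec.chief_complaint, chief_lexicon)
            for ent in res.entities:
                kg.add_triple(ent.entity_id, REL_CHIEF, syndrome)
        natures, locations = decompose_syndrome(
            syndrome, nature_lexicon, location_lexicon)
        for nat in natures:
            kg.add_triple(syndrome, REL_NATURE, nat)
        for loc in locations:
            kg.add_triple(syndrome, REL_LOCATION, loc)
    if skipped:
        log.warning("build_kg: skipped %d records with empty syndrome", skipped)
    if add_inverse:
        for t in list(kg.triples):
            kg.triples.add(Triple(t.tail, t.relation, t.head))
    return kg


def kg_stats(kg: KGraph) -> dict:
    """Per-category entity counts and per-relation triple counts."""
    ent_counts = {c: 0 for c in CATEGORIES}
    for cat in kg.entities.values():
        ent_counts[cat] += 1
    rel_counts = {r: 0 for r in RELATIONS}
    for t in kg.triples:
        if t.relation in rel_counts:
            rel_counts[t.relation] += 1
    return {
        "entities": ent_counts,
        "n_entities": len(kg.entities),
        "relations": rel_counts,
        "n_triples": len(kg.triples),
    }


# ---------------------------------------------------------------------------
# TSV persistence

TRIPLES_HEADER = "head\trelation\ttail"


def write_triples(kg: KGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(TRIPLES_HEADER + "\n")
        for t in sorted(kg.triples):
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


def write_vocab(kg: KGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity_id\tcategory\n")
        for e in sorted(kg.entities):
            fh.write(f"{e}\t{kg.entities[e]}\n")


def read_kg(triples_path, vocab_path) -> KGraph:
    kg = KGraph()
    with open(vocab_path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() != "entity_id\tcategory":
            raise DataError(f"bad vocab header in {vocab_path}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            eid, cat = line.split("\t")
            kg.add_entity(eid, cat)
    with open(triples_path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() != TRIPLES_HEADER:
            raise DataError(f"bad triples header in {triples_path}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            h, r, t = line.split("\t")
            kg.add_triple(h, r, t)
    return kg
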