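"""EMR record I/O, text segmentation, dictionary entity extraction, and
construction of the model input sequence.

A record carries five symptom text fields (the four examination modalities
plus physical exam), a chief-complaint text, a syndrome string, and gold
nature/location label sets. The model input is character-level:

    [CLS] symptoms [UNK] chief complaint [UNK] [SEP]

with a [UNK] separator after each field so entity spans never cross field
boundaries. Entity mentions are annotated as spans so the knowledge-graph
vectors can later be added to exactly the characters of each mention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from kdsd.errors import ConfigError, DataError

log = logging.getLogger(__name__)

CLS = "[CLS]"
UNK = "[UNK]"
SEP = "[SEP]"

#: canonical symptom-field order: pulse-taking, tongue examination,
#: listening/smelling, inspection, then physical examination.
SYMPTOM_FIELDS = ("pulse", "tongue", "listening_smelling", "inspection",
                  "physical_exam")


def tokenize(text: str) -> list[str]:
    """Character-level tokenization with symbolic-token passthrough.

    Whitespace-separated ASCII chunks (synthetic symbolic tokens such as
    ``sym_0042``) are kept whole — one symbol plays the role of one
    character. Non-ASCII chunks (e.g. CJK clinical text) are split into
    individual characters.
    """
    out: list[str] = []
    for chunk in text.split():
        if chunk.isascii():
            out.append(chunk)
        else:
            out.extend(chunk)
    return out


@dataclass(frozen=True)
class EMRRecord:
    """One clinical case: symptom fields, chief complaint, syndrome, labels."""

    record_id: str
    symptom_fields: tuple[tuple[str, str], ...]
    chief_complaint: str
    syndrome: str = ""
    gold_natures: frozenset[str] = frozenset()
    gold_locations: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.symptom_fields and not self.chief_complaint:
            raise DataError(
                f"record {self.record_id!r}: symptom fields and chief "
                "complaint cannot both be empty")

    @property
    def gold_labels(self) -> frozenset[str]:
        return self.gold_natures | self.gold_locations


def record_to_json(rec: EMRRecord) -> str:
    obj = {
        "record_id": rec.record_id,
        "symptom_fields": [[n, t] for n, t in rec.symptom_fields],
        "chief_complaint": rec.chief_complaint,
        "syndrome": rec.syndrome,
        "gold_natures": sorted(rec.gold_natures),
        "gold_locations": sorted(rec.gold_locations),
    }
    return json.dumps(obj, sort_keys=True, ensure_ascii=False)


def record_from_json(line: str) -> EMRRecord:
    obj = json.loads(line)
    return EMRRecord(
        record_id=obj["record_id"],
        symptom_fields=tuple((n, t) for n, t in obj["symptom_fields"]),
        chief_complaint=obj["chief_complaint"],
        syndrome=obj.get("syndrome", ""),
        gold_natures=frozenset(obj.get("gold_natures", ())),
        gold_locations=frozenset(obj.get("gold_locations", ())),
    )


def write_records(recs: list[EMRRecord], path) -> None:
    """Write records as line-delimited JSON (one record per line)."""
    ids = [r.record_id for r in recs]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate record_id in dataset")
    with open(path, "w", encoding="utf-8") as fh:
        for r in recs:
            fh.write(record_to_json(r) + "\n")


def read_records(path) -> list[EMRRecord]:
    with open(path, encoding="utf-8") as fh:
        recs = [record_from_json(line) for line in fh if line.strip()]
    ids = [r.record_id for r in recs]
    if len(set(ids)) != len(ids):
        raise DataError(f"duplicate record_id in {path}")
    return recs


def write_lexicon(lexicon: dict[str, str], path) -> None:
    """Two-column tab-separated (surface, entity_id)."""
    with open(path, "w", encoding="utf-8") as fh:
        for surface in sorted(lexicon):
            fh.write(f"{surface}\t{lexicon[surface]}\n")


def read_lexicon(path) -> dict[str, str]:
    lex: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            surface, entity_id = line.split("\t")
            lex[surface] = entity_id
    return lex


# ---------------------------------------------------------------------------
# segmentation


def segment_fields(raw_text: str, delimiters: set[str]) -> list[str]:
    """Split raw field text on punctuation delimiters; drop empty segments.

    The concatenation of the returned segments equals the input with every
    delimiter character removed.
    """
    if not delimiters:
        raise ConfigError("delimiter set must be non-empty")
    segments: list[str] = []
    cur: list[str] = []
    for ch in raw_text:
        if ch in delimiters:
            if cur:
                segments.append("".join(cur))
                cur = []
        else:
            cur.append(ch)
    if cur:
        segments.append("".join(cur))
    return segments


def parse_four_diagnoses(raw_text: str, delimiters: set[str]
                         ) -> list[tuple[str, str]]:
    """Assign punctuation-segmented chunks to the five named symptom fields.

    Segments beyond the fifth are folded into physical_exam.
    """
    segs = segment_fields(raw_text, delimiters)
    pairs: list[tuple[str, str]] = []
    for name, seg in zip(SYMPTOM_FIELDS, segs):
        pairs.append((name, seg))
    if len(segs) > len(SYMPTOM_FIELDS):
        extra = " ".join(segs[len(SYMPTOM_FIELDS):])
        name, last = pairs[-1]
        pairs[-1] = (name, last + " " + extra)
    return pairs


# ---------------------------------------------------------------------------
# dictionary entity extraction


@dataclass(frozen=True)
class ExtractedEntity:
    surface: tuple[str, ...]
    entity_id: str
    confidence: float


@dataclass(frozen=True)
class ExtractionResult:
    entities: tuple[ExtractedEntity, ...]

    def __post_init__(self):
        for e in self.entities:
            if not 0.0 <= e.confidence <= 1.0:
                raise DataError(f"confidence {e.confidence} outside [0,1]")


def _tokenized_lexicon(lexicon: dict[str, str]) -> dict[tuple[str, ...], str]:
    return {tuple(tokenize(surface)): eid for surface, eid in lexicon.items()}


def _longest_matches(tokens: list[str],
                     surface_map: dict[tuple[str, ...], str]
                     ) -> list[tuple[int, int, str]]:
    """Greedy left-to-right longest-match; returns (start, length, entity)."""
    if not surface_map:
        return []
    max_len = max(len(s) for s in surface_map)
    matches: list[tuple[int, int, str]] = []
    i = 0
    n = len(tokens)
    while i < n:
        hit = None
        for length in range(min(max_len, n - i), 0, -1):
            cand = tuple(tokens[i:i + length])
            if cand in surface_map:
                hit = (i, length, surface_map[cand])
                break
        if hit is not None:
            matches.append(hit)
            i += hit[1]
        else:
            i += 1
    return matches


def extract_chief_entities(chief: str | list[str],
                           lexicon: dict[str, str],
                           threshold: float = 0.5,
                           scorer=None) -> ExtractionResult:
    """Extract symptom entities from the chief complaint by dictionary match.

    Longest-match, left-to-right, non-overlapping. ``scorer(surface_tokens,
    entity_id) -> confidence`` emulates a learned extractor's probability;
    exact lexicon hits default to confidence 1.0. Entities scoring below
    ``threshold`` are deleted.
    """
    if not lexicon:
        raise ConfigError("lexicon must be non-empty")
    if not 0.0 <= threshold <= 1.0:
        raise ConfigError(f"threshold {threshold} outside [0,1]")
    tokens = tokenize(chief) if isinstance(chief, str) else list(chief)
    surface_map = _tokenized_lexicon(lexicon)
    out: list[ExtractedEntity] = []
    for start, length, eid in _longest_matches(tokens, surface_map):
        surface = tuple(tokens[start:start + length])
        conf = 1.0 if scorer is None else float(scorer(surface, eid))
        if conf >= threshold:
            out.append(ExtractedEntity(surface, eid, conf))
    return ExtractionResult(tuple(out))


# ---------------------------------------------------------------------------
# input sequence


@dataclass(frozen=True)
class Span:
    """A token run [start, start+length) linked to a KG entity.

    ``entity_id is None`` marks an unlinked (sentinel) mention: text the
    linker recognized as an entity-shaped run but which is absent from the
    knowledge graph.
    """
    entity_id: str | None
    start: int
    length: int


@dataclass(frozen=True)
class InputSequence:
    tokens: tuple[str, ...]
    spans: tuple[Span, ...]
    max_length: int

    def __post_init__(self):
        t = self.tokens
        if not t or t[0] != CLS or t[-1] != SEP:
            raise DataError("sequence must start with [CLS] and end with [SEP]")
        if len(t) > self.max_length:
            raise DataError(
                f"sequence length {len(t)} exceeds max_length {self.max_length}")
        special = {i for i, tok in enumerate(t) if tok in (CLS, UNK, SEP)}
        covered: set[int] = set()
        for sp in self.spans:
            idx = set(range(sp.start, sp.start + sp.length))
            if sp.length < 1 or sp.start < 0 or sp.start + sp.length > len(t):
                raise DataError(f"span {sp} out of range")
            if idx & special:
                raise DataError(f"span {sp} crosses a separator/marker")
            if idx & covered:
                raise DataError(f"span {sp} overlaps another span")
            covered |= idx


def _segment_spans(tokens: list[str], offset: int,
                   surface_map: dict[tuple[str, ...], str]) -> list[Span]:
    """Spans for one separator-free segment: matched runs carry the entity
    id, each maximal unmatched run carries the sentinel id."""
    spans: list[Span] = []
    matches = _longest_matches(tokens, surface_map)
    cursor = 0
    for start, length, eid in matches:
        if start > cursor:
            spans.append(Span(None, offset + cursor, start - cursor))
        spans.append(Span(eid, offset + start, length))
        cursor = start + length
    if cursor < len(tokens):
        spans.append(Span(None, offset + cursor, len(tokens) - cursor))
    return spans


def build_input_sequence(record: EMRRecord, kg, max_length: int = 256,
                         separator_per_field: bool = True,
                         chief_lexicon: dict[str, str] | None = None,
                         extraction_threshold: float = 0.5,
                         scorer=None) -> InputSequence:
    """Assemble ``[CLS] symptoms [UNK] chief entities [UNK] [SEP]`` with
    entity-span annotations against the knowledge graph ``kg``.

    Chief-complaint text is first reduced to its extracted entities (the
    dictionary extractor stands where a learned extractor would); symptom
    fields enter verbatim. Every maximal token run matching a KG entity
    surface is annotated with that entity; unmatched runs get the sentinel
    id. Overlong sequences are right-truncated before [SEP], dropping spans
    that no longer fit.
    """
    if max_length < 4:
        raise ConfigError(f"max_length {max_length} < 4 leaves no room for "
                          "markers")
    surface_map = {tuple(tokenize(e)): e for e in kg.entity_ids()}
    if chief_lexicon is None:
        chief_lexicon = {e: e for e in kg.entities_of("chief_complaint")}

    tokens: list[str] = [CLS]
    spans: list[Span] = []

    sym_segments = [tokenize(text) for _, text in record.symptom_fields]
    sym_segments = [s for s in sym_segments if s]
    for i, seg in enumerate(sym_segments):
        spans.extend(_segment_spans(seg, len(tokens), surface_map))
        tokens.extend(seg)
        if separator_per_field or i == len(sym_segments) - 1:
            tokens.append(UNK)

    if chief_lexicon and record.chief_complaint:
        extraction = extract_chief_entities(
            record.chief_complaint, chief_lexicon,
            threshold=extraction_threshold, scorer=scorer)
    else:
        extraction = ExtractionResult(())
    for ent in extraction.entities:
        seg = list(ent.surface)
        spans.extend(_segment_spans(seg, len(tokens), surface_map))
        tokens.extend(seg)
        tokens.append(UNK)
    tokens.append(SEP)

    if len(tokens) > max_length:
        tokens = tokens[:max_length - 1] + [SEP]
        spans = [sp for sp in spans if sp.start + sp.length <= max_length - 1]
    return InputSequence(tuple(tokens), tuple(spans), max_length)
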