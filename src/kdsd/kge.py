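"""Knowledge-graph embeddings and link-prediction evaluation.

Entities and relations are embedded in R^d so that a scoring function
separates true triples from corruptions. The translational scorer (TransE)
models a true triple as h + r ≈ t and scores by negated distance,

    score(h, r, t) = -||h + r - t||_{L1 or L2},

so a perfect translation scores 0, the global maximum. DistMult scores by
the trilinear product sum(h*r*t); ComplEx by its complex-valued analogue
Re(<h, r, conj(t)>). Training minimizes margin ranking loss
max(0, margin - score(pos) + score(neg)) with category-respecting uniform
negative sampling, the original translational-embedding recipe.

Evaluation ranks the true completion of (h, r, ?) / (?, r, t) queries among
candidates (category-restricted by default, reflecting the schema's typed
relations) and reports MRR, MR and Hits@N, raw or filtered. A KG-only
baseline scores each diagnosis label by two-hop link plausibility through
the syndrome layer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from kdsd.errors import ConfigError, DataError
from kdsd.kg import (LABEL_RELATION, REL_CHIEF, REL_SIGNATURE, REL_SYMPTOM,
                     KGraph, Triple)

log = logging.getLogger(__name__)

SCORERS = ("transe_l1", "transe_l2", "distmult", "complex")


@dataclass(frozen=True)
class KGETrainConfig:
    dim: int = 100
    scorer: str = "transe_l2"
    margin: float = 1.0
    negatives_per_positive: int = 1
    epochs: int = 200
    batch_size: int = 128
    learning_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.scorer not in SCORERS:
            raise ConfigError(f"unknown scorer {self.scorer!r}")
        if self.dim < 1:
            raise ConfigError("dim must be positive")
        if self.scorer == "complex" and self.dim % 2:
            raise ConfigError("complex scorer needs an even dim "
                              "(real/imaginary halves)")
        for name in ("margin", "learning_rate"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("negatives_per_positive", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")


@dataclass
class EmbeddingSet:
    entity_ids: list[str]
    relation_ids: list[str]
    E: np.ndarray  # (n_entities, d_e)
    R: np.ndarray  # (n_relations, d_r)
    scorer: str
    rng_seed: int = 0
    loss_history: list[float] = field(default_factory=list)

    def __post_init__(self):
        if self.E.shape[0] != len(self.entity_ids):
            raise DataError("entity vector count mismatch")
        if self.R.shape[0] != len(self.relation_ids):
            raise DataError("relation vector count mismatch")
        if self.scorer.startswith("transe") and self.E.shape[1] != self.R.shape[1]:
            raise DataError("translational scorer requires d_e == d_r")
        self._eidx = {e: i for i, e in enumerate(self.entity_ids)}
        self._ridx = {r: i for i, r in enumerate(self.relation_ids)}

    @property
    def dim(self) -> int:
        return self.E.shape[1]

    def entity_vector(self, entity_id: str) -> np.ndarray:
        return self.E[self._eidx[entity_id]]

    def relation_vector(self, relation_id: str) -> np.ndarray:
        return self.R[self._ridx[relation_id]]

    def has_entity(self, entity_id: str) -> bool:
        return entity_id in self._eidx

    def save(self, array_path, manifest_path) -> None:
        np.savez(array_path, E=self.E, R=self.R)
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump({"entity_ids": self.entity_ids,
                       "relation_ids": self.relation_ids,
                       "scorer": self.scorer,
                       "rng_seed": self.rng_seed}, fh, indent=2)

    @classmethod
    def load(cls, array_path, manifest_path) -> "EmbeddingSet":
        arrays = np.load(array_path)
        with open(manifest_path, encoding="utf-8") as fh:
            man = json.load(fh)
        return cls(entity_ids=man["entity_ids"],
                   relation_ids=man["relation_ids"],
                   E=arrays["E"], R=arrays["R"], scorer=man["scorer"],
                   rng_seed=man["rng_seed"])


# ---------------------------------------------------------------------------
# scoring


def _score_rows(H: np.ndarray, R: np.ndarray, T: np.ndarray,
                scorer: str) -> np.ndarray:
    """Row-wise triple scores; higher = more plausible."""
    if scorer == "transe_l2":
        return -np.linalg.norm(H + R - T, axis=-1)
    if scorer == "transe_l1":
        return -np.abs(H + R - T).sum(axis=-1)
    if scorer == "distmult":
        return (H * R * T).sum(axis=-1)
    if scorer == "complex":
        d2 = H.shape[-1] // 2
        hr, hi = H[..., :d2], H[..., d2:]
        rr, ri = R[..., :d2], R[..., d2:]
        tr, ti = T[..., :d2], T[..., d2:]
        return (rr * (hr * tr + hi * ti) + ri * (hr * ti - hi * tr)).sum(axis=-1)
    raise ConfigError(f"unknown scorer {scorer!r}")


def score_triple(h: np.ndarray, r: np.ndarray, t: np.ndarray,
                 scorer: str) -> float:
    """Score a single triple from raw vectors."""
    h, r, t = (np.asarray(v, dtype=float) for v in (h, r, t))
    if h.shape != t.shape:
        raise DataError(f"head/tail dimension mismatch: {h.shape} vs {t.shape}")
    if scorer.startswith("transe") and r.shape != h.shape:
        raise DataError(
            f"translational scorer needs d_r == d_e, got r{r.shape} h{h.shape}")
    if r.shape != h.shape:
        raise DataError(f"relation dimension mismatch: {r.shape} vs {h.shape}")
    return float(_score_rows(h[None], r[None], t[None], scorer)[0])


def score_kg_triple(triple: Triple, emb: EmbeddingSet) -> float:
    return score_triple(emb.entity_vector(triple.head),
                        emb.relation_vector(triple.relation),
                        emb.entity_vector(triple.tail), emb.scorer)


# ---------------------------------------------------------------------------
# negative sampling


def negative_sample(triple: Triple, kg: KGraph, rng: np.random.Generator,
                    max_retries: int = 1000) -> Triple:
    """Corrupt head or tail (fair coin) with a same-category entity such
    that the corrupted triple is absent from the graph."""
    hc, tc = REL_SIGNATURE[triple.relation]
    for _ in range(max_retries):
        corrupt_head = rng.random() < 0.5
        cat = hc if corrupt_head else tc
        candidates = kg.entities_of(cat)
        if len(candidates) < 2:
            raise DataError(f"cannot corrupt: category {cat!r} has "
                            f"{len(candidates)} entities")
        repl = candidates[int(rng.integers(len(candidates)))]
        cand = (Triple(repl, triple.relation, triple.tail) if corrupt_head
                else Triple(triple.head, triple.relation, repl))
        if cand != triple and cand not in kg.triples:
            return cand
    raise DataError(f"no valid corruption found for {triple} after "
                    f"{max_retries} retries")


# ---------------------------------------------------------------------------
# training


def train_kge(kg: KGraph, config: KGETrainConfig,
              triples: list[Triple] | None = None) -> EmbeddingSet:
    """Train embeddings by margin ranking SGD over ``triples`` (default:
    all graph triples). Entity vectors are renormalized to unit L2 norm at
    the start of each epoch for translational scorers."""
    config.validate()
    if not kg.triples:
        raise DataError("cannot train on an empty knowledge graph")
    train_triples = sorted(kg.triples) if triples is None else sorted(triples)
    entity_ids = kg.entity_ids()
    relation_ids = sorted({t.relation for t in kg.triples})
    eidx = {e: i for i, e in enumerate(entity_ids)}
    ridx = {r: i for i, r in enumerate(relation_ids)}
    d = config.dim
    rng = np.random.default_rng(config.seed)
    bound = 6.0 / np.sqrt(d)
    E = rng.uniform(-bound, bound, size=(len(entity_ids), d))
    R = rng.uniform(-bound, bound, size=(len(relation_ids), d))
    translational = config.scorer.startswith("transe")
    if translational:
        R /= np.linalg.norm(R, axis=1, keepdims=True)

    H = np.array([eidx[t.head] for t in train_triples])
    Rel = np.array([ridx[t.relation] for t in train_triples])
    T = np.array([eidx[t.tail] for t in train_triples])
    # category-restricted corruption pools per relation
    pools = {}
    for r in relation_ids:
        hc, tc = REL_SIGNATURE[r]
        pools[r] = (np.array([eidx[e] for e in kg.entities_of(hc)]),
                    np.array([eidx[e] for e in kg.entities_of(tc)]))
    known = {(eidx[t.head], ridx[t.relation], eidx[t.tail])
             for t in kg.triples}

    n = len(train_triples)
    history: list[float] = []
    for _epoch in range(config.epochs):
        if translational:
            E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12)
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            sel = perm[start:start + config.batch_size]
            for _neg in range(config.negatives_per_positive):
                h, rel, t = H[sel].copy(), Rel[sel], T[sel].copy()
                hn, tn = h.copy(), t.copy()
                corrupt_head = rng.random(len(sel)) < 0.5
                for i, (ch, ri) in enumerate(zip(corrupt_head, rel)):
                    pool = pools[relation_ids[ri]][0 if ch else 1]
                    for _try in range(20):
                        repl = int(pool[rng.integers(len(pool))])
                        cand = ((repl, ri, t[i]) if ch else (h[i], ri, repl))
                        if cand not in known:
                            break
                    if ch:
                        hn[i] = repl
                    else:
                        tn[i] = repl
                loss = _margin_step(E, R, h, rel, t, hn, tn, config)
                epoch_loss += loss * len(sel)
        history.append(epoch_loss / (n * config.negatives_per_positive))
    if translational:
        E /= np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-12)
    return EmbeddingSet(entity_ids, relation_ids, E, R, config.scorer,
                        rng_seed=config.seed, loss_history=history)


def _margin_step(E, R, h, rel, t, hn, tn, config: KGETrainConfig) -> float:
    """One SGD step of margin ranking loss; returns the batch mean loss."""
    s_pos = _score_rows(E[h], R[rel], E[t], config.scorer)
    s_neg = _score_rows(E[hn], R[rel], E[tn], config.scorer)
    viol = config.margin - s_pos + s_neg
    active = viol > 0
    if not active.any():
        return 0.0
    lr = config.learning_rate
    # d(loss)/d(score_pos) = -1, d(loss)/d(score_neg) = +1 on active rows
    for sign, hh, tt in ((-1.0, h, t), (1.0, hn, tn)):
        gh, gr, gt = _score_grads(E[hh], R[rel], E[tt], config.scorer)
        w = (sign * active)[:, None]
        np.add.at(E, hh, -lr * w * gh)
        np.add.at(R, rel, -lr * w * gr)
        np.add.at(E, tt, -lr * w * gt)
    return float(np.maximum(viol, 0.0).mean())


def _score_grads(Hv, Rv, Tv, scorer):
    """Gradients of the score wrt head/relation/tail vectors, row-wise."""
    if scorer == "transe_l2":
        diff = Hv + Rv - Tv
        norm = np.maximum(np.linalg.norm(diff, axis=1, keepdims=True), 1e-12)
        g = -diff / norm
        return g, g, -g
    if scorer == "transe_l1":
        g = -np.sign(Hv + Rv - Tv)
        return g, g, -g
    if scorer == "distmult":
        return Rv * Tv, Hv * Tv, Hv * Rv
    if scorer == "complex":
        d2 = Hv.shape[1] // 2
        hr, hi = Hv[:, :d2], Hv[:, d2:]
        rr, ri = Rv[:, :d2], Rv[:, d2:]
        tr, ti = Tv[:, :d2], Tv[:, d2:]
        gh = np.concatenate([rr * tr + ri * ti, rr * ti - ri * tr], axis=1)
        gr = np.concatenate([hr * tr + hi * ti, hr * ti - hi * tr], axis=1)
        gt = np.concatenate([rr * hr - ri * hi, rr * hi + ri * hr], axis=1)
        return gh, gr, gt
    raise ConfigError(f"unknown scorer {scorer!r}")


# ---------------------------------------------------------------------------
# link-prediction evaluation


@dataclass(frozen=True)
class LinkPredReport:
    mrr: float
    mr: float
    hits: dict[int, float]
    mode: str

    def __post_init__(self):
        if not 0.0 <= self.mrr <= 1.0:
            raise DataError(f"mrr {self.mrr} outside [0,1]")
        if self.mr < 1.0:
            raise DataError(f"mr {self.mr} < 1")
        ns = sorted(self.hits)
        vals = [self.hits[n] for n in ns]
        if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
            raise DataError("hits@n must be non-decreasing in n")

    def to_dict(self) -> dict:
        return {"mrr": self.mrr, "mr": self.mr, "mode": self.mode,
                "hits": {str(n): v for n, v in sorted(self.hits.items())}}


def rank_entity(query: tuple, truth: str, emb: EmbeddingSet, kg: KGraph,
                mode: str = "filtered",
                restrict_category: bool = True) -> float:
    """Mid-rank of the true completion of (h, r, ?) or (?, r, t).

    rank = 1 + #{candidates scoring strictly higher} + half the equal-scoring
    others, which makes the metrics stable under candidate permutation. In
    filtered mode other known-true completions are removed first.
    """
    if mode not in ("raw", "filtered"):
        raise ConfigError(f"mode must be raw or filtered, got {mode!r}")
    h, r, t = query
    if (h is None) == (t is None):
        raise DataError("query must have exactly one open slot")
    tail_query = t is None
    hc, tc = REL_SIGNATURE[r]
    cat = tc if tail_query else hc
    candidates = kg.entities_of(cat) if restrict_category else kg.entity_ids()
    if truth not in candidates:
        raise DataError(f"truth {truth!r} not in candidate set")
    if mode == "filtered":
        if tail_query:
            known = {tr.tail for tr in kg.triples
                     if tr.head == h and tr.relation == r}
        else:
            known = {tr.head for tr in kg.triples
                     if tr.tail == t and tr.relation == r}
        candidates = [c for c in candidates if c == truth or c not in known]
    C = np.stack([emb.entity_vector(c) for c in candidates])
    rv = emb.relation_vector(r)
    if tail_query:
        hv = emb.entity_vector(h)
        scores = _score_rows(np.broadcast_to(hv, C.shape),
                             np.broadcast_to(rv, C.shape), C, emb.scorer)
    else:
        tv = emb.entity_vector(t)
        scores = _score_rows(C, np.broadcast_to(rv, C.shape),
                             np.broadcast_to(tv, C.shape), emb.scorer)
    truth_score = scores[candidates.index(truth)]
    better = int((scores > truth_score).sum())
    equal = int((scores == truth_score).sum()) - 1  # excluding truth itself
    return 1.0 + better + 0.5 * equal


def evaluate_link_prediction(test: list[Triple], emb: EmbeddingSet,
                             kg: KGraph, mode: str = "filtered",
                             hits_at: tuple[int, ...] = (1, 10, 100),
                             restrict_category: bool = True) -> LinkPredReport:
    """MRR / MR / Hits@N pooled over head and tail queries of the test set."""
    if not test:
        raise DataError("empty test set")
    ranks: list[float] = []
    for tr in test:
        ranks.append(rank_entity((tr.head, tr.relation, None), tr.tail,
                                 emb, kg, mode, restrict_category))
        ranks.append(rank_entity((None, tr.relation, tr.tail), tr.head,
                                 emb, kg, mode, restrict_category))
    arr = np.array(ranks)
    return LinkPredReport(
        mrr=float((1.0 / arr).mean()),
        mr=float(arr.mean()),
        hits={n: float((arr <= n).mean()) for n in hits_at},
        mode=mode)


def split_triples(kg: KGraph, test_fraction: float = 0.1, seed: int = 0
                  ) -> tuple[list[Triple], list[Triple]]:
    """Hold out a triple split for link-prediction evaluation.

    A triple enters the test set only if both its entities keep at least one
    other triple in training, so no test entity is untrained.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ConfigError(f"test_fraction {test_fraction} outside (0,1)")
    rng = np.random.default_rng(seed)
    triples = sorted(kg.triples)
    order = rng.permutation(len(triples))
    degree: dict[str, int] = {}
    for t in triples:
        degree[t.head] = degree.get(t.head, 0) + 1
        degree[t.tail] = degree.get(t.tail, 0) + 1
    n_test_target = max(1, int(round(test_fraction * len(triples))))
    test: list[Triple] = []
    test_set: set[Triple] = set()
    for i in order:
        if len(test) >= n_test_target:
            break
        t = triples[i]
        if degree[t.head] > 1 and degree[t.tail] > 1:
            test.append(t)
            test_set.add(t)
            degree[t.head] -= 1
            degree[t.tail] -= 1
    train = [t for t in triples if t not in test_set]
    return train, test


# ---------------------------------------------------------------------------
# KG-only label prediction baseline


def kg_baseline_predict(record_entities: list[str], emb: EmbeddingSet,
                        kg: KGraph, label_space: list[str] | None = None,
                        aggregation: str = "mean") -> np.ndarray:
    """Score every diagnosis label for a record using the graph alone.

    For each label L and record entity e, plausibility is the best two-hop
    path through a syndrome s: max_s min(score(e -> s), score(s -> L)),
    with the relation chosen by each entity's category. Scores aggregate
    across entities by mean (order-free); ``aggregation="max"`` and
    ``"sum"`` are alternatives. Records with no KG-linkable entities get a
    uniform zero vector with a warning.
    """
    if label_space is None:
        label_space = kg.label_space
    if not label_space:
        raise DataError("empty label space")
    if aggregation not in ("mean", "max", "sum"):
        raise ConfigError(f"unknown aggregation {aggregation!r}")
    syndromes = [s for s in kg.entities_of("syndrome") if emb.has_entity(s)]
    linkable: list[tuple[str, str]] = []
    for e in record_entities:
        cat = kg.entities.get(e)
        if cat == "symptom" and emb.has_entity(e):
            linkable.append((e, REL_SYMPTOM))
        elif cat == "chief_complaint" and emb.has_entity(e):
            linkable.append((e, REL_CHIEF))
    if not linkable or not syndromes:
        log.warning("kg_baseline_predict: no linkable entities; returning "
                    "uniform scores")
        return np.zeros(len(label_space))

    S = np.stack([emb.entity_vector(s) for s in syndromes])  # (ns, d)
    # hop 2: syndrome -> label, per label category
    hop2 = np.empty((len(syndromes), len(label_space)))
    for j, lab in enumerate(label_space):
        cat = kg.entities.get(lab)
        rel = LABEL_RELATION.get(cat)
        if rel is None or not emb.has_entity(lab):
            hop2[:, j] = -np.inf
            continue
        lv = emb.entity_vector(lab)
        hop2[:, j] = _score_rows(S, np.broadcast_to(
            emb.relation_vector(rel), S.shape),
            np.broadcast_to(lv, S.shape), emb.scorer)

    per_entity = np.empty((len(linkable), len(label_space)))
    for i, (e, rel) in enumerate(linkable):
        ev = emb.entity_vector(e)
        hop1 = _score_rows(np.broadcast_to(ev, S.shape),
                           np.broadcast_to(emb.relation_vector(rel), S.shape),
                           S, emb.scorer)  # (ns,)
        # max over syndromes of min(hop1, hop2)
        per_entity[i] = np.max(np.minimum(hop1[:, None], hop2), axis=0)
    if aggregation == "mean":
        return per_entity.mean(axis=0)
    if aggregation == "max":
        return per_entity.max(axis=0)
    return per_entity.sum(axis=0)
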