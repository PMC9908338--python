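"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, explicit
loops, no shared code with the package internals — so it can serve as an
independent check of the optimized implementations.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# multilabel ranking metrics, by exhaustive enumeration


def oracle_p_at_k(scores, truth, k):
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    return sum(truth[i] for i in order[:k]) / k


def oracle_hamming(scores_batch, truth_batch, threshold=0.0):
    wrong = total = 0
    for scores, truth in zip(scores_batch, truth_batch):
        for s, y in zip(scores, truth):
            pred = 1 if s >= threshold else 0
            wrong += int(pred != y)
            total += 1
    return wrong / total


def oracle_average_precision(scores, truth):
    """Threshold sweep over descending unique scores."""
    n_pos = sum(truth)
    assert n_pos > 0
    ap, r_prev = 0.0, 0.0
    for thr in sorted(set(scores), reverse=True):
        sel = [i for i, s in enumerate(scores) if s >= thr]
        tp = sum(truth[i] for i in sel)
        p = tp / len(sel)
        r = tp / n_pos
        ap += (r - r_prev) * p
        r_prev = r
    return ap


def oracle_ranking_loss(scores, truth):
    """Exhaustive (positive, negative) pair enumeration; ties violate."""
    pos = [i for i, y in enumerate(truth) if y == 1]
    neg = [i for i, y in enumerate(truth) if y == 0]
    assert pos and neg
    bad = sum(1 for p in pos for n in neg if scores[n] >= scores[p])
    return bad / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# link prediction, by full re-scoring


def _oracle_score(h, r, t, scorer):
    h, r, t = np.asarray(h), np.asarray(r), np.asarray(t)
    if scorer == "transe_l2":
        return -float(np.sqrt(((h + r - t) ** 2).sum()))
    if scorer == "transe_l1":
        return -float(np.abs(h + r - t).sum())
    if scorer == "distmult":
        return float((h * r * t).sum())
    if scorer == "complex":
        d2 = len(h) // 2
        hc = h[:d2] + 1j * h[d2:]
        rc = r[:d2] + 1j * r[d2:]
        tc = t[:d2] + 1j * t[d2:]
        return float(np.real((hc * rc * np.conj(tc)).sum()))
    raise ValueError(scorer)


def oracle_rank(query, truth, emb, kg, mode, restrict_category=True):
    """Mid-rank of the truth by scoring every candidate one at a time."""
    from kdsd.kg import REL_SIGNATURE

    h, r, t = query
    tail_query = t is None
    hc, tc = REL_SIGNATURE[r]
    cat = tc if tail_query else hc
    cands = (kg.entities_of(cat) if restrict_category else kg.entity_ids())
    if mode == "filtered":
        keep = []
        for c in cands:
            if c == truth:
                keep.append(c)
                continue
            trip = ((h, r, c) if tail_query else (c, r, t))
            known = any(x.head == trip[0] and x.relation == trip[1]
                        and x.tail == trip[2] for x in kg.triples)
            if not known:
                keep.append(c)
        cands = keep
    scores = {}
    rv = emb.relation_vector(r)
    for c in cands:
        if tail_query:
            scores[c] = _oracle_score(emb.entity_vector(h), rv,
                                      emb.entity_vector(c), emb.scorer)
        else:
            scores[c] = _oracle_score(emb.entity_vector(c), rv,
                                      emb.entity_vector(t), emb.scorer)
    ts = scores[truth]
    better = sum(1 for c in cands if scores[c] > ts)
    equal = sum(1 for c in cands if scores[c] == ts) - 1
    return 1.0 + better + 0.5 * equal


def oracle_link_prediction(test, emb, kg, mode, hits_at=(1, 10, 100)):
    ranks = []
    for tr in test:
        ranks.append(oracle_rank((tr.head, tr.relation, None), tr.tail,
                                 emb, kg, mode))
        ranks.append(oracle_rank((None, tr.relation, tr.tail), tr.head,
                                 emb, kg, mode))
    ranks = np.array(ranks)
    return {
        "mrr": float((1.0 / ranks).mean()),
        "mr": float(ranks.mean()),
        "hits": {n: float((ranks <= n).mean()) for n in hits_at},
    }
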