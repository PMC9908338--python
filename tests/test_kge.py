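"""Scoring functions, negative sampling, margin-ranking training, ranking
protocol and the KG-only baseline."""

import numpy as np
import pytest

from kdsd.errors import DataError
from kdsd.kg import (REL_CHIEF, REL_LOCATION, REL_NATURE, REL_SYMPTOM,
                     KGraph, Triple)
from kdsd.kge import (EmbeddingSet, KGETrainConfig, evaluate_link_prediction,
                      kg_baseline_predict, negative_sample, rank_entity,
                      score_triple, split_triples, train_kge)
from oracles import oracle_link_prediction


class TestScoreTriple:
    def test_exact_translation_scores_zero_the_maximum(self, rng):
        h = rng.normal(size=8)
        r = rng.normal(size=8)
        assert score_triple(h, r, h + r, "transe_l2") == pytest.approx(0.0)
        t_off = h + r + 0.1 * rng.normal(size=8)
        assert score_triple(h, r, t_off, "transe_l2") < 0.0

    def test_l1_hand_evaluation(self):
        assert score_triple([1.0, 0.0], [0.0, 0.0], [0.0, 1.0],
                            "transe_l1") == pytest.approx(-2.0)

    def test_distmult_symmetric_in_head_and_tail(self, rng):
        h, r, t = rng.normal(size=(3, 6))
        assert score_triple(h, r, t, "distmult") == pytest.approx(
            score_triple(t, r, h, "distmult"))

    def test_complex_breaks_head_tail_symmetry(self, rng):
        h, r, t = rng.normal(size=(3, 8))
        assert score_triple(h, r, t, "complex") != pytest.approx(
            score_triple(t, r, h, "complex"))

    def test_dimension_mismatch_reported(self):
        with pytest.raises(DataError, match="d_r == d_e"):
            score_triple([1.0, 2.0], [1.0], [0.0, 1.0], "transe_l2")
        with pytest.raises(DataError, match="mismatch"):
            score_triple([1.0, 2.0], [1.0, 1.0], [0.0], "transe_l2")


def _tiny_kg() -> KGraph:
    kg = KGraph()
    for s, syn in (("s1", "A"), ("s2", "A"), ("s3", "B"), ("s4", "B")):
        kg.add_triple(s, REL_SYMPTOM, syn)
    kg.add_triple("c1", REL_CHIEF, "A")
    kg.add_triple("c2", REL_CHIEF, "B")
    kg.add_triple("A", REL_NATURE, "n1")
    kg.add_triple("A", REL_LOCATION, "l1")
    kg.add_triple("B", REL_NATURE, "n2")
    kg.add_triple("B", REL_LOCATION, "l2")
    return kg


class TestNegativeSample:
    def test_never_returns_a_known_triple(self, rng):
        kg = _tiny_kg()
        true = Triple("s1", REL_SYMPTOM, "A")
        for _ in range(200):
            neg = negative_sample(true, kg, rng)
            assert neg not in kg.triples

    def test_corruption_respects_slot_category(self, rng):
        kg = _tiny_kg()
        true = Triple("A", REL_NATURE, "n1")
        for _ in range(100):
            neg = negative_sample(true, kg, rng)
            assert kg.entities[neg.head] == "syndrome"
            assert kg.entities[neg.tail] == "nature"

    def test_head_tail_corruption_is_a_fair_coin(self, rng):
        kg = _tiny_kg()
        true = Triple("s1", REL_SYMPTOM, "A")
        n = 10000
        heads = sum(negative_sample(true, kg, rng).head != "s1"
                    for _ in range(n))
        se = np.sqrt(0.25 / n)
        assert abs(heads / n - 0.5) < 4 * se


class TestTrainKGE:
    def test_true_triples_outscore_corruptions(self, small_kg, rng):
        cfg = KGETrainConfig(dim=32, epochs=150, batch_size=64, seed=0)
        emb = train_kge(small_kg, cfg)
        pos, neg = [], []
        for t in sorted(small_kg.triples):
            pos.append(score_triple(emb.entity_vector(t.head),
                                    emb.relation_vector(t.relation),
                                    emb.entity_vector(t.tail), emb.scorer))
            c = negative_sample(t, small_kg, rng)
            neg.append(score_triple(emb.entity_vector(c.head),
                                    emb.relation_vector(c.relation),
                                    emb.entity_vector(c.tail), emb.scorer))
        assert np.mean(pos) > np.mean(neg)

    def test_deterministic_for_fixed_seed(self, small_kg):
        cfg = KGETrainConfig(dim=16, epochs=30, seed=9)
        a = train_kge(small_kg, cfg)
        b = train_kge(small_kg, cfg)
        assert np.array_equal(a.E, b.E) and np.array_equal(a.R, b.R)

    def test_loss_trace_decreases_overall(self, small_kg):
        cfg = KGETrainConfig(dim=32, epochs=100, batch_size=64, seed=1)
        emb = train_kge(small_kg, cfg)
        hist = emb.loss_history
        assert hist[-1] < hist[0]
        # monotone up to batch noise: the tail sits well under the head
        assert np.mean(hist[-10:]) < 0.5 * np.mean(hist[:10])

    def test_empty_graph_rejected(self):
        with pytest.raises(DataError):
            train_kge(KGraph(), KGETrainConfig())

    def test_entity_vectors_unit_norm_for_translational(self, small_kg):
        emb = train_kge(small_kg, KGETrainConfig(dim=16, epochs=5, seed=0))
        norms = np.linalg.norm(emb.E, axis=1)
        assert np.allclose(norms, 1.0)


def _embedding_from(kg: KGraph, vectors: dict[str, np.ndarray],
                    rel_vectors: dict[str, np.ndarray],
                    scorer="transe_l2") -> EmbeddingSet:
    ents = kg.entity_ids()
    rels = sorted({t.relation for t in kg.triples})
    E = np.stack([vectors[e] for e in ents])
    R = np.stack([rel_vectors[r] for r in rels])
    return EmbeddingSet(ents, rels, E, R, scorer)


class TestRankEntity:
    def test_exact_translation_ranks_first(self, rng):
        kg = _tiny_kg()
        d = 4
        vecs = {e: rng.normal(size=d) for e in kg.entity_ids()}
        rels = {r: rng.normal(size=d)
                for r in {t.relation for t in kg.triples}}
        vecs["A"] = vecs["s1"] + rels[REL_SYMPTOM]  # truth = exact translation
        emb = _embedding_from(kg, vecs, rels)
        rank = rank_entity(("s1", REL_SYMPTOM, None), "A", emb, kg,
                           mode="raw")
        assert rank == 1.0

    def test_random_embeddings_rank_uniformly(self):
        kg = KGraph()
        for i in range(10):
            kg.add_triple("s0", REL_SYMPTOM, f"syn{i}")
        ranks = []
        for seed in range(300):
            r = np.random.default_rng(seed)
            vecs = {e: r.normal(size=6) for e in kg.entity_ids()}
            rels = {REL_SYMPTOM: r.normal(size=6)}
            emb = _embedding_from(kg, vecs, rels)
            ranks.append(rank_entity(("s0", REL_SYMPTOM, None), "syn3",
                                     emb, kg, mode="raw"))
        assert np.mean(ranks) == pytest.approx(5.5, abs=0.5)

    def test_filtered_rank_never_worse_than_raw(self, rng):
        kg = _tiny_kg()
        for seed in range(30):
            r = np.random.default_rng(seed)
            vecs = {e: r.normal(size=5) for e in kg.entity_ids()}
            rels = {rel: r.normal(size=5)
                    for rel in {t.relation for t in kg.triples}}
            emb = _embedding_from(kg, vecs, rels)
            for t in sorted(kg.triples):
                raw = rank_entity((t.head, t.relation, None), t.tail,
                                  emb, kg, mode="raw")
                filt = rank_entity((t.head, t.relation, None), t.tail,
                                   emb, kg, mode="filtered")
                assert filt <= raw

    def test_truth_outside_candidates_rejected(self, rng):
        kg = _tiny_kg()
        vecs = {e: rng.normal(size=4) for e in kg.entity_ids()}
        rels = {rel: rng.normal(size=4)
                for rel in {t.relation for t in kg.triples}}
        emb = _embedding_from(kg, vecs, rels)
        with pytest.raises(DataError):
            rank_entity(("s1", REL_SYMPTOM, None), "n1", emb, kg)


class TestEvaluateLinkPrediction:
    def test_perfect_model_scores_one_everywhere(self, rng):
        kg = _tiny_kg()
        d = 6
        rels = {rel: rng.normal(size=d)
                for rel in {t.relation for t in kg.triples}}
        # place every entity so each true triple is an exact translation:
        # possible here because the tiny graph is a tree from symptoms up
        vecs = {}
        vecs["A"], vecs["B"] = rng.normal(size=d), rng.normal(size=d)
        for s, syn in (("s1", "A"), ("s2", "A"), ("s3", "B"), ("s4", "B")):
            vecs[s] = vecs[syn] - rels[REL_SYMPTOM] + 1e-3 * rng.normal(size=d)
        for c, syn in (("c1", "A"), ("c2", "B")):
            vecs[c] = vecs[syn] - rels[REL_CHIEF] + 1e-3 * rng.normal(size=d)
        for lab, syn, rel in (("n1", "A", REL_NATURE), ("n2", "B", REL_NATURE),
                              ("l1", "A", REL_LOCATION),
                              ("l2", "B", REL_LOCATION)):
            vecs[lab] = vecs[syn] + rels[rel] + 1e-3 * rng.normal(size=d)
        emb = _embedding_from(kg, vecs, rels)
        rep = evaluate_link_prediction(sorted(kg.triples), emb, kg,
                                       mode="filtered")
        assert rep.mrr == pytest.approx(1.0)
        assert rep.mr == pytest.approx(1.0)
        assert rep.hits[1] == 1.0

    def test_closed_form_from_known_ranks(self, rng):
        kg = _tiny_kg()
        vecs = {e: rng.normal(size=5) for e in kg.entity_ids()}
        rels = {rel: rng.normal(size=5)
                for rel in {t.relation for t in kg.triples}}
        emb = _embedding_from(kg, vecs, rels)
        test = sorted(kg.triples)[:4]
        ranks = []
        for t in test:
            ranks.append(rank_entity((t.head, t.relation, None), t.tail,
                                     emb, kg, "raw"))
            ranks.append(rank_entity((None, t.relation, t.tail), t.head,
                                     emb, kg, "raw"))
        rep = evaluate_link_prediction(test, emb, kg, mode="raw")
        assert rep.mrr == pytest.approx(np.mean([1 / r for r in ranks]))
        assert rep.mr == pytest.approx(np.mean(ranks))
        for n in (1, 10, 100):
            assert rep.hits[n] == pytest.approx(
                np.mean([r <= n for r in ranks]))

    def test_hits_monotone_in_n(self, small_kg):
        emb = train_kge(small_kg, KGETrainConfig(dim=16, epochs=20, seed=2))
        rep = evaluate_link_prediction(sorted(small_kg.triples)[:10], emb,
                                       small_kg, mode="raw")
        assert rep.hits[1] <= rep.hits[10] <= rep.hits[100]

    def test_matches_full_rescoring_oracle(self):
        """Naive re-scoring oracle equivalence on graphs <= 20 entities."""
        for seed in range(10):
            r = np.random.default_rng(seed)
            kg = _tiny_kg()
            vecs = {e: r.normal(size=6) for e in kg.entity_ids()}
            rels = {rel: r.normal(size=6)
                    for rel in {t.relation for t in kg.triples}}
            emb = _embedding_from(kg, vecs, rels)
            test = sorted(kg.triples)[::2]
            for mode in ("raw", "filtered"):
                rep = evaluate_link_prediction(test, emb, kg, mode=mode)
                exp = oracle_link_prediction(test, emb, kg, mode)
                assert rep.mrr == pytest.approx(exp["mrr"], abs=1e-12)
                assert rep.mr == pytest.approx(exp["mr"], abs=1e-12)
                for n, v in exp["hits"].items():
                    assert rep.hits[n] == pytest.approx(v, abs=1e-12)

    def test_empty_test_set_rejected(self, small_kg):
        emb = train_kge(small_kg, KGETrainConfig(dim=8, epochs=2, seed=0))
        with pytest.raises(DataError):
            evaluate_link_prediction([], emb, small_kg)


class TestSplitTriples:
    def test_test_entities_keep_training_support(self, small_kg):
        train, test = split_triples(small_kg, 0.2, seed=5)
        train_ents = {e for t in train for e in (t.head, t.tail)}
        for t in test:
            assert t.head in train_ents and t.tail in train_ents
        assert len(train) + len(test) == len(small_kg.triples)


class TestKGBaseline:
    def _trained(self, small_kg):
        return train_kge(small_kg, KGETrainConfig(dim=32, epochs=150,
                                                  batch_size=64, seed=0))

    def test_single_syndrome_world_puts_its_labels_on_top(self):
        kg = KGraph()
        for s in ("s1", "s2", "s3"):
            kg.add_triple(s, REL_SYMPTOM, "A")
        kg.add_triple("A", REL_NATURE, "n1")
        kg.add_triple("A", REL_LOCATION, "l1")
        # distractor labels attached to an unrelated syndrome
        kg.add_triple("z1", REL_SYMPTOM, "B")
        kg.add_triple("B", REL_NATURE, "n2")
        kg.add_triple("B", REL_LOCATION, "l2")
        emb = train_kge(kg, KGETrainConfig(dim=24, epochs=300, seed=3))
        labels = kg.label_space
        scores = kg_baseline_predict(["s1", "s2", "s3"], emb, kg, labels)
        top2 = {labels[i] for i in np.argsort(-scores)[:2]}
        assert top2 == {"n1", "l1"}

    def test_unlinkable_record_gets_uniform_scores(self, small_kg, caplog):
        emb = self._trained(small_kg)
        with caplog.at_level("WARNING"):
            scores = kg_baseline_predict(["nothere"], emb, small_kg)
        assert np.all(scores == scores[0])

    def test_entity_order_does_not_matter(self, small_kg, rng):
        emb = self._trained(small_kg)
        ents = small_kg.entities_of("symptom")[:4]
        a = kg_baseline_predict(ents, emb, small_kg)
        b = kg_baseline_predict(ents[::-1], emb, small_kg)
        assert np.allclose(a, b)
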