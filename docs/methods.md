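# Methods

## Problem setting

Syndrome differentiation assigns a TCM case its syndrome (证候). Because
syndromes rarely repeat across cases, the task is recast as multilabel
ranking over the syndrome's constituents: disease-nature labels (病性) and
disease-location labels (病位). A record contributes five symptom text
fields (pulse-taking, tongue examination, listening/smelling, inspection,
physical examination), a chief complaint, and — at training time — a
syndrome string from which the gold label sets are derived.

## Knowledge graph

**Schema.** Five entity categories (symptom, chief complaint, syndrome,
nature, location) and four typed relations: chief→syndrome,
symptom→syndrome, syndrome→nature, syndrome→location. The schema layer is
carried implicitly as each entity's category; triples are validated
against the relation signature on insertion. Edges are stored in the
stated direction only; an `add_inverse` flag can mirror them.

**Syndrome decomposition** is lexicon-driven greedy longest-match over the
character (or symbolic-token) sequence, scanning left to right over the
union of the nature and location lexicons so that a longer surface
("damp-heat") absorbs its substrings ("heat"). Syndromes with no lexicon
hit decompose to empty sets and are logged. No fuzzy matching or synonym
merging is attempted: entity identity is the whitespace-normalized surface
form.

**Chief-complaint extraction** replaces a learned sequence extractor with
dictionary longest-match (left-to-right, non-overlapping). The extractor's
confidence is an injectable scorer (exact hits default to 1.0) and
entities scoring below the threshold — default 0.5 — are deleted, so the
confidence-filtering behaviour of a probabilistic extractor remains
exercised end to end.

## Knowledge-graph embedding

Scorers: `transe_l1` / `transe_l2` with score = −‖h + r − t‖ (a perfect
translation scores 0, the global maximum), `distmult` (trilinear product,
symmetric in head/tail by construction), `complex` (real part of the
Hermitian trilinear product; vectors store real/imaginary halves in one
array, so `dim` must be even).

Training minimizes margin ranking loss max(0, γ − s(pos) + s(neg)) by
minibatch SGD with uniform category-respecting corruption of head or tail
(fair coin), resampled against the known-triple set. Entity vectors are
renormalized to unit L2 norm at each epoch for translational scorers;
relation vectors are normalized once at initialization
(uniform ±6/√d). Defaults: dim 100, margin 1.0, L2, one negative per
positive, lr 0.05. The graphs this package targets are small (10²–10³
triples), so a few hundred epochs run in seconds on one CPU; the
configuration file scales all of this.

**Ranking protocol.** Queries (h, r, ?) and (?, r, t) are ranked over
category-restricted candidate sets by default — justified by the typed
schema; a flag ranks over all entities. Ties take the mid-rank (1 +
strictly-better + half of equal-scoring others) so reports are stable
under candidate permutation. Filtered mode removes other known-true
completions before ranking; filtered and raw are both reported, filtered
by default. Held-out splits only admit a triple if both of its entities
retain at least one training edge, the usual protocol for small graphs.

**KG-only baseline.** For a record's linkable entities, each label L is
scored by the best two-hop path through a syndrome s:
max_s min(score(e → s), score(s → L)), averaged over entities (order-free;
`max` and `sum` aggregations are available behind the same interface). The
full score vector is returned so the ranking metrics apply, not just the
argmax. Records with no linkable entities get a uniform vector and a
warning.

## Fusion classifier

The pretrained-LM slot is filled by a small configurable transformer
encoder with the same contract (per-character hidden states, [CLS]
pooling): learned token + position embeddings, then `n_layers` blocks of
residual multi-head self-attention and a residual ReLU feed-forward.
Layer normalization is omitted deliberately — at the scale this package
trains (hidden 16–64, 1–2 layers) Adam is stable without it and the
forward/backward pass stays small. Any encoder with the same interface can
be dropped in.

The input sequence is `[CLS] symptoms [UNK] chief entities [UNK] [SEP]`
with a separator after every symptom field (a switch collapses this to a
single block separator) so that entity spans never cross fields. Chief
complaints are first reduced to their extracted entities. Every maximal
token run matching a KG entity surface is annotated with the entity id;
unmatched runs carry a sentinel id. Sequences are right-truncated before
[SEP] at `max_length` (default 256), dropping spans that no longer fit.

**Fusion** adds each span's entity vector — projected into the hidden
space by a learned linear map, initialized to identity when dimensions
match — to the hidden state of every character the mention covers.
Positions outside spans are untouched (asserted bit-level in tests).
Sentinel mentions draw a deterministic pseudo-random vector keyed by their
surface, reflecting that unseen entities must still receive *some*
embedding at predict time.

**Attention integration** runs one multi-head self-attention block over
Q = K = V = Wˢ·Concat(C; pooled span vectors): the [CLS] hidden state
joined with the mean-pooled vectors of every entity span (symptom and
chief mentions alike — the attention is over their union, so the
symptom/chief distinction does not change the computation). The output at
the C position, C′, is the sequence representation. Span vectors are
mean-pooled rather than taken per-token; fusion is applied before the
integration block. Both choices were genuinely open; the pooled + fuse-first
ordering keeps the integration block's input size independent of mention
length.

A linear head with bias maps C′ to one raw score per label. Sigmoid is
applied only inside the loss; all ranking metrics consume raw scores. The
loss is per-label binary cross-entropy with logits — the standard
multilabel choice, compatible with every metric in the suite. Training is
Adam with defaults lr 1e-2, batch 8, a scale appropriate for a
from-scratch tiny encoder (fine-tuning-scale rates like 2e-5 presuppose
pretrained weights and are configurable). All arithmetic runs through a
minimal reverse-mode autodiff core (`autodiff.py`), so analytic gradients
exist for every block and are validated against central finite differences
to 1e-4 relative error.

**Vocabulary.** The encoder vocabulary is built from the training
sequences with a minimum-frequency cutoff (default 1); out-of-vocabulary
tokens map to [UNK]. This is the mechanism by which a domain mention can
be invisible to the encoder while remaining resolvable by the entity
linker — the regime in which entity fusion has the most to add.

## Synthetic worlds

A world is a set of latent syndromes, each owning a without-replacement
draw of symptoms and chief entities and a distinct (natures, locations)
label combination; the syndrome's surface string is the concatenation of
its label tokens, making decomposition exact by construction. Records
sample a syndrome (uniform by default; a skew exponent is available), emit
its symptoms round-robin across the five fields and its chief entities
amid neutral filler words, and attach the syndrome's labels as gold truth.
Noise replaces one symptom token per record with a uniformly random
vocabulary symptom with probability `noise_rate` (default 0); it perturbs
symptoms only — gold labels always remain the owning syndrome's. An
optional `group_size` arranges syndromes into families drawing from shared
symptom/chief pools, producing the correlated structure under which
held-out graph edges are statistically recoverable.

Symbolic tokens (`sym_0042`) stand in for clinical surface strings; all
matching is token-level, so the pipeline is script-agnostic (CJK text is
tokenized per character, symbolic ASCII tokens stay whole).

What the generator does **not** emulate: realistic clinical prose,
inter-annotator disagreement in syndrome naming, demographic/date fields,
extraction errors with graded confidences, and long-tail label imbalance.
Passing tests on these worlds therefore demonstrate correctness of the
machinery and the direction of the fusion effect, not clinical
performance.

**Train/test split.** A random split is post-processed so that every gold
label occurring in the test set also occurs in training; violating records
are moved to the training side and counted in the log and manifest.

## Metrics

P@k (ties broken by stable label index), Hamming loss (scores binarized at
sigmoid ≥ 0.5, i.e. raw score ≥ 0), average precision (threshold-sweep
summary of the precision–recall curve), and label ranking loss (fraction
of (positive, negative) pairs with the negative scored ≥ the positive,
ties counted as violations, normalized by |y|·(n_labels − |y|) — the
standard normalization by the number of ordered pairs). Rows with no
positive labels carry no ranking information: they are excluded (and
counted) from AP and ranking loss but retained in Hamming loss and P@k.
All four agree with exhaustive brute-force oracles to 1e-12 and, on
tie-free data, with scikit-learn's implementations.

## Reproducibility and problem sizes

Every stochastic component takes a seed; the pipeline derives per-stage
child seeds from one global seed via a seed sequence, and identical runs
reproduce all metric reports byte-identically. The bundled experiments run
at desk scale — worlds of 4–12 syndromes, 50–400 records, graphs of
50–150 triples, encoders of hidden size 16–32 — chosen so the full suite
and the acceptance script each complete in well under a minute on one CPU
while still exercising every contract; all sizes are configuration, not
code.

## Known limitations

* Dictionary extraction cannot produce graded confidences by itself; the
  threshold path is exercised through the injectable scorer.
* TransE cannot model symmetric or one-to-many relations exactly; on the
  four-relation schema this matters little, but MRR saturates below 1 on
  graphs where a symptom supports several syndromes.
* The KG-only baseline's two-hop max–min composition is one resolution of
  "link prediction on the record's triples"; alternatives (sum/max
  aggregation) sit behind the same strategy interface.
* No GPU path and no sharded training; the implementation targets graphs
  and corpora that fit comfortably in memory.
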