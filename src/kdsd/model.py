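"""Character-level classifier with knowledge-entity fusion.

The model mirrors a knowledge-enhanced fine-tuning stack at desk scale:

1. a small transformer *encoder* turns the input sequence into per-token
   hidden states (the pretrained-LM slot — any encoder with the same
   per-character contract can be dropped in);
2. *entity fusion* adds each linked entity's KG vector (projected into the
   hidden space) to the hidden states of exactly the characters spanning
   that entity's mention; unlinked mentions draw a seeded random vector;
3. *attention integration* runs one multi-head self-attention block over
   the [CLS] state together with the mean-pooled span vectors,
   Q = K = V = W_s · Concat(C; S_1..M; C_1..N), and reads the output at the
   [CLS] position as the sequence representation C';
4. a linear head maps C' to one raw score per diagnosis label. Sigmoid is
   applied only inside the binary cross-entropy loss; ranking metrics use
   the raw scores.

All arithmetic runs through the package's reverse-mode autodiff core, so
analytic gradients are available for every trainable block.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass

import numpy as np

from kdsd import autodiff as ad
from kdsd.autodiff import Tensor
from kdsd.errors import ConfigError, DataError
from kdsd.metrics import precision_at_k
from kdsd.records import CLS, SEP, UNK, InputSequence, Span

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EncoderConfig:
    hidden_dim: int = 32
    n_layers: int = 1
    n_heads: int = 2
    ffn_dim: int = 64
    max_len: int = 256
    min_token_freq: int = 1
    seed: int = 0

    def validate(self) -> None:
        for name in ("hidden_dim", "n_layers", "n_heads", "ffn_dim",
                     "max_len", "min_token_freq"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if self.hidden_dim % self.n_heads:
            raise ConfigError(
                f"hidden_dim {self.hidden_dim} not divisible by n_heads "
                f"{self.n_heads}")


@dataclass(frozen=True)
class ClassifierTrainConfig:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-2
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")


class Vocab:
    """Token -> id map with a minimum-frequency cutoff.

    Tokens rarer than ``min_freq`` in the training corpus fall back to the
    [UNK] id — the standard treatment for out-of-vocabulary characters, and
    the reason rare domain mentions can be invisible to the encoder while
    still being resolvable by the entity linker.
    """

    SPECIALS = (CLS, UNK, SEP)

    def __init__(self, tokens: list[str]):
        self._ids: dict[str, int] = {t: i for i, t in enumerate(self.SPECIALS)}
        for t in tokens:
            if t not in self._ids:
                self._ids[t] = len(self._ids)

    @classmethod
    def build(cls, sequences: list[InputSequence],
              min_freq: int = 1) -> "Vocab":
        counts: dict[str, int] = {}
        for seq in sequences:
            for tok in seq.tokens:
                if tok not in cls.SPECIALS:
                    counts[tok] = counts.get(tok, 0) + 1
        kept = sorted(t for t, c in counts.items() if c >= min_freq)
        return cls(kept)

    def __len__(self) -> int:
        return len(self._ids)

    def encode(self, tokens) -> np.ndarray:
        unk = self._ids[UNK]
        return np.array([self._ids.get(t, unk) for t in tokens],
                        dtype=np.intp)


def _mha(X: Tensor, Wq: Tensor, Wk: Tensor, Wv: Tensor, Wo: Tensor,
         n_heads: int) -> Tensor:
    """Multi-head self-attention; per-head projections are column blocks."""
    H = X.shape[1]
    dk = H // n_heads
    Q, K, V = ad.matmul(X, Wq), ad.matmul(X, Wk), ad.matmul(X, Wv)
    heads = []
    for h in range(n_heads):
        lo, hi = h * dk, (h + 1) * dk
        Qh, Kh, Vh = ad.cols(Q, lo, hi), ad.cols(K, lo, hi), ad.cols(V, lo, hi)
        A = ad.softmax_rows(ad.scale(ad.matmul(Qh, ad.transpose(Kh)),
                                     1.0 / np.sqrt(dk)))
        heads.append(ad.matmul(A, Vh))
    return ad.matmul(ad.concat_cols(heads), Wo)


def _sentinel_vector(surface: tuple[str, ...], dim: int, seed: int
                     ) -> np.ndarray:
    """Deterministic pseudo-random entity vector for an unlinked mention."""
    key = zlib.crc32(("\x1f".join(surface)).encode("utf-8"))
    rng = np.random.default_rng((seed, key))
    return rng.normal(scale=0.1, size=dim)


def fuse_entities(hidden: np.ndarray, spans: tuple[Span, ...],
                  entity_lookup, entity_dim: int,
                  projector: np.ndarray | None = None,
                  sentinel_seed: int = 0,
                  surface_of=None) -> np.ndarray:
    """Add each span's (projected) entity vector to its covered positions.

    ``entity_lookup(entity_id)`` returns the KG vector or None; sentinel
    spans (``entity_id is None``) and unknown entities draw a seeded random
    vector keyed by the mention surface. Positions outside any span are
    returned bit-identical.
    """
    T, H = hidden.shape
    if projector is None:
        if entity_dim != H:
            raise DataError(f"need a projector to map d_e={entity_dim} into "
                            f"hidden_dim={H}")
        projector = np.eye(H)
    out = hidden.copy()
    for sp in spans:
        if sp.start + sp.length > T:
            raise DataError(f"span {sp} out of range for {T} tokens")
        vec = None if sp.entity_id is None else entity_lookup(sp.entity_id)
        if vec is None:
            surface = (surface_of(sp) if surface_of is not None
                       else (str(sp.entity_id), str(sp.start)))
            vec = _sentinel_vector(tuple(surface), entity_dim, sentinel_seed)
        out[sp.start:sp.start + sp.length] += np.asarray(vec) @ projector
    return out


def attention_integrate(C: np.ndarray, S: list[np.ndarray],
                        Cc: list[np.ndarray], params: dict,
                        n_heads: int = 1) -> np.ndarray:
    """One self-attention block over Concat(C; S_1..M; C_1..N); returns C'.

    ``params`` holds Ws, Wq, Wk, Wv, Wo (all hidden_dim x hidden_dim numpy
    arrays). Standalone numpy-facing wrapper around the model's internal
    block, for inspection and testing.
    """
    if len(S) == 0 and len(Cc) == 0:
        rows = np.asarray(C)[None]
    else:
        rows = np.vstack([np.asarray(C)[None]] +
                         [np.asarray(v)[None] for v in list(S) + list(Cc)])
    Z = ad.matmul(Tensor(rows), Tensor(params["Ws"]))
    out = _mha(Z, Tensor(params["Wq"]), Tensor(params["Wk"]),
               Tensor(params["Wv"]), Tensor(params["Wo"]), n_heads)
    return out.value[0]


class KDSDClassifier:
    """Encoder + entity fusion + attention integration + linear label head."""

    def __init__(self, label_space: list[str], vocab: Vocab,
                 encoder: EncoderConfig = EncoderConfig(),
                 entity_emb=None, fusion_enabled: bool = True,
                 seed: int | None = None):
        encoder.validate()
        if fusion_enabled and entity_emb is None:
            raise ConfigError("fusion requires an entity EmbeddingSet")
        self.label_space = list(label_space)
        self.vocab = vocab
        self.cfg = encoder
        self.entity_emb = entity_emb
        self.fusion_enabled = fusion_enabled
        self.seed = encoder.seed if seed is None else seed
        self.entity_dim = entity_emb.dim if entity_emb is not None else None
        self._init_params()

    # -- parameters --------------------------------------------------------

    def _init_params(self) -> None:
        rng = np.random.default_rng(self.seed)
        H, F = self.cfg.hidden_dim, self.cfg.ffn_dim
        L = len(self.label_space)

        def w(*shape, s=None):
            s = s if s is not None else 1.0 / np.sqrt(shape[0])
            return Tensor(rng.normal(scale=s, size=shape), requires_grad=True)

        p: dict[str, Tensor] = {
            "tok_emb": w(len(self.vocab), H, s=0.1),
            "pos_emb": w(self.cfg.max_len, H, s=0.1),
        }
        for l in range(self.cfg.n_layers):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[f"enc{l}_{name}"] = w(H, H)
            p[f"enc{l}_W1"] = w(H, F)
            p[f"enc{l}_b1"] = Tensor(np.zeros(F), requires_grad=True)
            p[f"enc{l}_W2"] = w(F, H)
            p[f"enc{l}_b2"] = Tensor(np.zeros(H), requires_grad=True)
        for name in ("Ws", "Wq", "Wk", "Wv", "Wo"):
            p[f"int_{name}"] = w(H, H)
        if self.fusion_enabled:
            d_e = self.entity_dim
            if d_e == H:
                proj = np.eye(H)
            else:
                proj = rng.normal(scale=1.0 / np.sqrt(d_e), size=(d_e, H))
            p["proj"] = Tensor(proj, requires_grad=True)
        p["head_W"] = w(H, L)
        p["head_b"] = Tensor(np.zeros(L), requires_grad=True)
        self.params = p

    def parameters(self) -> list[Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    # -- forward -----------------------------------------------------------

    def _encode(self, seq: InputSequence) -> Tensor:
        ids = self.vocab.encode(seq.tokens)
        T = len(ids)
        if T > self.cfg.max_len:
            raise DataError(f"sequence length {T} exceeds encoder max_len "
                            f"{self.cfg.max_len}")
        X = ad.add(ad.take_rows(self.params["tok_emb"], ids),
                   ad.take_rows(self.params["pos_emb"], np.arange(T)))
        for l in range(self.cfg.n_layers):
            att = _mha(X, self.params[f"enc{l}_Wq"], self.params[f"enc{l}_Wk"],
                       self.params[f"enc{l}_Wv"], self.params[f"enc{l}_Wo"],
                       self.cfg.n_heads)
            X = ad.add(X, att)
            ff = ad.add(ad.matmul(ad.relu(ad.add(
                ad.matmul(X, self.params[f"enc{l}_W1"]),
                self.params[f"enc{l}_b1"])),
                self.params[f"enc{l}_W2"]), self.params[f"enc{l}_b2"])
            X = ad.add(X, ff)
        return X

    def encode(self, seq: InputSequence) -> np.ndarray:
        """Per-token hidden states (deterministic for fixed parameters)."""
        return self._encode(seq).value

    def _entity_matrix(self, spans, tokens) -> np.ndarray:
        """(n_spans, d_e) matrix of KG / sentinel vectors, in span order."""
        rows = []
        for sp in spans:
            vec = None
            if sp.entity_id is not None and self.entity_emb.has_entity(
                    sp.entity_id):
                vec = self.entity_emb.entity_vector(sp.entity_id)
            if vec is None:
                surface = tuple(tokens[sp.start:sp.start + sp.length])
                vec = _sentinel_vector(surface, self.entity_dim, self.seed)
            rows.append(np.asarray(vec, dtype=float))
        return np.stack(rows)

    def _forward(self, seq: InputSequence) -> Tensor:
        X = self._encode(seq)
        T = X.shape[0]
        spans = seq.spans
        if self.fusion_enabled and spans:
            Ent = Tensor(self._entity_matrix(spans, seq.tokens))
            M = np.zeros((T, len(spans)))
            for k, sp in enumerate(spans):
                M[sp.start:sp.start + sp.length, k] = 1.0
            X = ad.add(X, ad.matmul(Tensor(M),
                                    ad.matmul(Ent, self.params["proj"])))
        # pooled rows: [CLS] state first, then mean-pooled span vectors
        P = np.zeros((1 + len(spans), T))
        P[0, 0] = 1.0
        for k, sp in enumerate(spans):
            P[1 + k, sp.start:sp.start + sp.length] = 1.0 / sp.length
        Z = ad.matmul(ad.matmul(Tensor(P), X), self.params["int_Ws"])
        out = _mha(Z, self.params["int_Wq"], self.params["int_Wk"],
                   self.params["int_Wv"], self.params["int_Wo"],
                   self.cfg.n_heads)
        c_prime = ad.take_rows(out, np.array([0]))
        return ad.add(ad.matmul(c_prime, self.params["head_W"]),
                      self.params["head_b"])

    def predict(self, seq: InputSequence) -> np.ndarray:
        """Raw label scores (length = |label space|); rank to get labels."""
        return self._forward(seq).value[0]

    def loss(self, seq: InputSequence, y: np.ndarray) -> Tensor:
        """Mean per-label binary cross-entropy with logits."""
        y = np.asarray(y, dtype=float)
        if y.shape != (len(self.label_space),):
            raise DataError(f"target shape {y.shape} != label space "
                            f"({len(self.label_space)},)")
        return ad.bce_with_logits(self._forward(seq), y[None])

    # -- training ----------------------------------------------------------

    def labels_to_vector(self, labels) -> np.ndarray:
        idx = {lab: i for i, lab in enumerate(self.label_space)}
        y = np.zeros(len(self.label_space))
        for lab in labels:
            if lab not in idx:
                raise DataError(f"label {lab!r} outside the label space")
            y[idx[lab]] = 1.0
        return y

    def fit(self, sequences: list[InputSequence], targets: list,
            train_cfg: ClassifierTrainConfig = ClassifierTrainConfig(),
            val_sequences=None, val_targets=None) -> dict:
        """Minimize BCE by Adam; returns a history of per-epoch loss (and
        validation P@1 when a validation split is given)."""
        train_cfg.validate()
        Y = [self.labels_to_vector(t) if not isinstance(t, np.ndarray) else t
             for t in targets]
        val_Y = None
        if val_sequences is not None:
            val_Y = [self.labels_to_vector(t) if not isinstance(t, np.ndarray)
                     else t for t in val_targets]
        opt = ad.Adam(self.parameters(), lr=train_cfg.learning_rate)
        rng = np.random.default_rng(train_cfg.seed)
        n = len(sequences)
        history: dict[str, list[float]] = {"loss": [], "val_p_at_1": []}
        for epoch in range(train_cfg.epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, train_cfg.batch_size):
                batch = order[start:start + train_cfg.batch_size]
                opt.zero_grad()
                for i in batch:
                    loss = self.loss(sequences[i], Y[i])
                    loss.backward()
                    total += float(loss.value)
                opt.step()
            history["loss"].append(total / n)
            if val_sequences is not None:
                p1 = float(np.mean([
                    precision_at_k(self.predict(s), y, 1)
                    for s, y in zip(val_sequences, val_Y)]))
                history["val_p_at_1"].append(p1)
                log.info("epoch %d: loss %.4f val P@1 %.3f", epoch,
                         history["loss"][-1], p1)
            else:
                log.info("epoch %d: loss %.4f", epoch, history["loss"][-1])
        return history

    # -- persistence -------------------------------------------------------

    def save(self, array_path, manifest_path) -> None:
        np.savez(array_path, **{k: v.value for k, v in self.params.items()})
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump({
                "label_space": self.label_space,
                "vocab_tokens": [t for t in self.vocab._ids
                                 if t not in Vocab.SPECIALS],
                "encoder": self.cfg.__dict__,
                "fusion_enabled": self.fusion_enabled,
                "seed": self.seed,
            }, fh, indent=2)

    @classmethod
    def load(cls, array_path, manifest_path, entity_emb=None
             ) -> "KDSDClassifier":
        with open(manifest_path, encoding="utf-8") as fh:
            man = json.load(fh)
        model = cls(label_space=man["label_space"],
                    vocab=Vocab(man["vocab_tokens"]),
                    encoder=EncoderConfig(**man["encoder"]),
                    entity_emb=entity_emb,
                    fusion_enabled=man["fusion_enabled"],
                    seed=man["seed"])
        arrays = np.load(array_path)
        for k in model.params:
            model.params[k].value = arrays[k]
        return model
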