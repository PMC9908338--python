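"""Multilabel ranking metrics: P@k, Hamming loss, average precision, label
ranking loss.

Conventions (fixed so every metric is deterministic):

* P@k breaks score ties by stable label index.
* Hamming loss binarizes scores at sigmoid(score) >= 0.5, i.e. score >= 0,
  unless raw 0/1 predictions are supplied.
* Average precision is the threshold-sweep summary of the precision-recall
  curve, AP = sum_n (R_n - R_{n-1}) P_n over descending unique scores.
* Label ranking loss counts a (positive, negative) label pair as violated
  when the negative scores >= the positive (ties are violations), normalized
  by |y| * (n_labels - |y|) per sample.
* Rows with no positive labels carry no ranking information: they are
  excluded from average precision and ranking loss (with a logged count)
  but kept, as all-negative rows, in Hamming loss and P@k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from kdsd.errors import DataError

log = logging.getLogger(__name__)


def _check_batch(scores, truths) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    truths = np.asarray(truths)
    if scores.ndim == 1:
        scores = scores[None]
        truths = truths[None]
    if scores.shape != truths.shape:
        raise DataError(f"scores {scores.shape} vs truths {truths.shape}")
    uniq = set(np.unique(truths).tolist())
    if not uniq <= {0, 1, 0.0, 1.0, False, True}:
        raise DataError("truths must be strictly binary")
    return scores, truths.astype(int)


def _rank_order(row: np.ndarray) -> np.ndarray:
    """Descending-score label order with stable index tie-break."""
    return np.argsort(-row, kind="stable")


def precision_at_k(scores, truth, k: int) -> float:
    """Fraction of the k top-scored labels that are true: (1/k) Σ y_rank(l)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    if not 1 <= k <= scores.shape[-1]:
        raise DataError(f"k={k} outside [1, n_labels={scores.shape[-1]}]")
    order = _rank_order(scores)
    return float(truth[order[:k]].sum() / k)


def hamming_loss(scores, truths, threshold: float = 0.0,
                 binary: bool = False) -> float:
    """Mean rate of wrongly predicted labels after thresholding.

    ``threshold`` applies to raw scores (0.0 corresponds to probability 0.5
    under a sigmoid); pass ``binary=True`` if scores are already 0/1.
    """
    scores, truths = _check_batch(scores, truths)
    preds = scores.astype(int) if binary else (scores >= threshold).astype(int)
    return float((preds != truths).mean())


def average_precision(scores, truth) -> float:
    """Per-sample AP = Σ_n (R_n − R_{n−1}) P_n over descending thresholds."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    n_pos = truth.sum()
    if n_pos == 0:
        raise DataError("average precision undefined for a row with no "
                        "positive labels")
    ap = 0.0
    r_prev = 0.0
    for thr in np.sort(np.unique(scores))[::-1]:
        mask = scores >= thr
        tp = int(truth[mask].sum())
        p_n = tp / int(mask.sum())
        r_n = tp / n_pos
        ap += (r_n - r_prev) * p_n
        r_prev = r_n
    return float(ap)


def label_ranking_loss(scores, truth) -> float:
    """Fraction of (positive, negative) label pairs ranked incorrectly,
    normalized by |y| * (n_labels - |y|). Ties count as violations."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("ranking loss undefined without both positive and "
                        "negative labels")
    violations = int((neg[None, :] >= pos[:, None]).sum())
    return float(violations / (len(pos) * len(neg)))


@dataclass(frozen=True)
class MetricsReport:
    p_at_k: dict[int, float]
    hamming_loss: float
    average_precision: float
    label_ranking_loss: float
    n_samples: int
    n_excluded_ap: int = 0
    n_excluded_rl: int = 0

    def __post_init__(self):
        for name in ("hamming_loss", "average_precision",
                     "label_ranking_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name}={v} outside [0,1]")
        for k, v in self.p_at_k.items():
            if not 0.0 <= v <= 1.0:
                raise DataError(f"P@{k}={v} outside [0,1]")

    def to_dict(self) -> dict:
        return {
            "p_at_k": {str(k): v for k, v in sorted(self.p_at_k.items())},
            "hamming_loss": self.hamming_loss,
            "average_precision": self.average_precision,
            "label_ranking_loss": self.label_ranking_loss,
            "n_samples": self.n_samples,
            "n_excluded_ap": self.n_excluded_ap,
            "n_excluded_rl": self.n_excluded_rl,
        }


def evaluate_batch(scores, truths, ks: tuple[int, ...] = (1, 3, 5),
                   threshold: float = 0.0) -> MetricsReport:
    """The full evaluation suite over an (n_samples, n_labels) batch."""
    scores, truths = _check_batch(scores, truths)
    n, n_labels = scores.shape
    ks = tuple(k for k in ks if k <= n_labels)
    p_at_k = {k: float(np.mean([precision_at_k(scores[i], truths[i], k)
                                for i in range(n)])) for k in ks}
    ham = hamming_loss(scores, truths, threshold=threshold)

    ap_vals, rl_vals = [], []
    excluded_ap = excluded_rl = 0
    for i in range(n):
        n_pos = truths[i].sum()
        if n_pos == 0:
            excluded_ap += 1
        else:
            ap_vals.append(average_precision(scores[i], truths[i]))
        if n_pos == 0 or n_pos == n_labels:
            excluded_rl += 1
        else:
            rl_vals.append(label_ranking_loss(scores[i], truths[i]))
    if excluded_ap:
        log.info("evaluate_batch: %d rows without positives excluded from "
                 "average precision", excluded_ap)
    if excluded_rl:
        log.info("evaluate_batch: %d degenerate rows excluded from ranking "
                 "loss", excluded_rl)
    if not ap_vals or not rl_vals:
        raise DataError("no rows usable for ranking metrics")
    return MetricsReport(
        p_at_k=p_at_k,
        hamming_loss=ham,
        average_precision=float(np.mean(ap_vals)),
        label_ranking_loss=float(np.mean(rl_vals)),
        n_samples=n,
        n_excluded_ap=excluded_ap,
        n_excluded_rl=excluded_rl,
    )
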