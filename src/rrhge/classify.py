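"""Signature-based sample scoring, 3-nearest-neighbour classification and
confusion-matrix metrics.

Each sample is mapped to a point ``(S+, S-)`` — its mean normalised
expression over the ER+ and ER- signature genes — and classified by the
majority label of its three nearest labelled training samples under the L1
(Manhattan) distance. Performance is summarised by sensitivity,
specificity, accuracy and the Matthews correlation coefficient, with the
convention that a zero marginal sum sets the MCC denominator to 1 (so the
MCC itself is 0).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .signature import GeneSignature

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "pos"
NEGATIVE_LABEL = "neg"


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round with ties away from zero, matching conventional report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def score_samples(values: pd.DataFrame, signature: GeneSignature) -> pd.DataFrame:
    """Project samples onto the (S+, S-) plane.

    ``S+`` is the mean expression over the ER+ signature genes measured on
    the sample's platform (the divisor adapts to the measured subset;
    missing genes are logged), ``S-`` likewise for the ER- side.

    Parameters
    ----------
    values
        Normalised genes x samples matrix.
    signature
        The disjoint ER+/ER- gene sets.

    Raises
    ------
    ValueError
        If no gene of either side is measured.
    """
    out = {}
    for name, genes in (("s_plus", signature.er_pos_genes),
                        ("s_minus", signature.er_neg_genes)):
        measured = sorted(set(genes) & set(values.index))
        missing = sorted(set(genes) - set(values.index))
        if not measured:
            raise ValueError(
                f"no measured signature genes for {name}; missing: {missing}"
            )
        if missing:
            logger.info("%s: %d signature gene(s) unmeasured: %s",
                        name, len(missing), ",".join(missing))
        out[name] = values.loc[measured].mean(axis=0)
    return pd.DataFrame(out)


def knn_classify(
    test_points: np.ndarray,
    reference_points: np.ndarray,
    reference_labels: np.ndarray,
    k: int = 3,
) -> np.ndarray:
    """Majority-vote k-nearest-neighbour prediction under L1 distance.

    Distance ties at the k-th neighbour are broken deterministically by
    reference index (stable sort on (distance, index)). With binary labels
    and odd k the vote itself cannot tie.
    """
    reference_points = np.asarray(reference_points, dtype=float)
    test_points = np.asarray(test_points, dtype=float)
    reference_labels = np.asarray(reference_labels)
    if reference_points.shape[0] < k:
        raise ValueError(f"need at least k={k} reference points, "
                         f"got {reference_points.shape[0]}")
    distances = cdist(test_points, reference_points, metric="cityblock")
    predictions = []
    indices = np.arange(reference_points.shape[0])
    for row in distances:
        order = np.lexsort((indices, row))[:k]
        votes = Counter(reference_labels[order])
        top = max(votes.values())
        winners = sorted(label for label, c in votes.items() if c == top)
        predictions.append(winners[0])
    return np.asarray(predictions)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion(
    predictions, truths, positive: str = POSITIVE_LABEL
) -> ConfusionCounts:
    """2x2 tabulation with the ER+ class as positive."""
    predictions = list(predictions)
    truths = list(truths)
    if len(predictions) != len(truths):
        raise ValueError("prediction/truth length mismatch")
    tp = fn = tn = fp = 0
    for pred, truth in zip(predictions, truths):
        if truth == positive:
            if pred == positive:
                tp += 1
            else:
                fn += 1
        else:
            if pred == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


@dataclass(frozen=True)
class ClassificationMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    degenerate: bool = False  # a marginal sum was zero

    def rounded(self, ndigits: int = 3) -> "ClassificationMetrics":
        return ClassificationMetrics(
            sensitivity=round_half_up(self.sensitivity, ndigits),
            specificity=round_half_up(self.specificity, ndigits),
            accuracy=round_half_up(self.accuracy, ndigits),
            mcc=round_half_up(self.mcc, ndigits),
            degenerate=self.degenerate,
        )


def metrics(counts: ConfusionCounts) -> ClassificationMetrics:
    """Sensitivity, specificity, accuracy and MCC from a 2x2 table.

    ``MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``; if any
    of the four marginal sums is zero the denominator is set to 1, which
    makes the MCC 0. An undefined sensitivity or specificity (empty truth
    class) is likewise reported as 0 with the ``degenerate`` flag set.
    """
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    if counts.n < 1:
        raise ValueError("empty confusion table")
    degenerate = False
    if tp + fn > 0:
        sn = tp / (tp + fn)
    else:
        sn, degenerate = 0.0, True
    if tn + fp > 0:
        sp = tn / (tn + fp)
    else:
        sp, degenerate = 0.0, True
    acc = (tp + tn) / counts.n
    sums = [tp + fp, tp + fn, tn + fp, tn + fn]
    if any(s == 0 for s in sums):
        mcc = 0.0
        degenerate = True
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(math.prod(sums))
    return ClassificationMetrics(sn, sp, acc, mcc, degenerate)
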