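"""Base-pair level evaluation: confusion counts, PPV/Recall/F1/MCC, and
core-stem matching with a ±1 displacement tolerance.

Confusion counts compare predicted and reference base-pair sets
irrespective of bracket layer.  True negatives at base-pair level are
not uniquely defined; the convention here is the number of sequence
positions unpaired in both structures.

Core-stem matching scores how many of the two pseudoknot core pairs a
prediction recovers, accepting a pair displaced by one position in
exactly one coordinate: (k, l) matches (k, l), (k ± 1, l) or (k, l ± 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_stems import CoreStemCandidate
from .sequence_io import SecondaryStructure

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "compute_metrics", "core_stem_matches"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricReport:
    """PPV (precision), recall, F1 and MCC; an all-False flag set means
    every metric was computable (no zero denominator)."""

    ppv: float
    recall: float
    f1: float
    mcc: float
    ppv_defined: bool = True
    recall_defined: bool = True
    f1_defined: bool = True
    mcc_defined: bool = True


def confusion(pred: SecondaryStructure, truth: SecondaryStructure) -> ConfusionCounts:
    """Base-pair confusion counts of a prediction against a reference."""
    if pred.length != truth.length:
        raise ValueError(
            f"length mismatch: prediction {pred.length} vs reference {truth.length}"
        )
    p, t = pred.pair_set, truth.pair_set
    unpaired_both = (
        set(range(1, pred.length + 1)) - pred.paired_positions() - truth.paired_positions()
    )
    return ConfusionCounts(
        tp=len(p & t), tn=len(unpaired_both), fp=len(p - t), fn=len(t - p)
    )


def compute_metrics(c: ConfusionCounts) -> MetricReport:
    """PPV = tp/(tp+fp); Recall = tp/(tp+fn); F1 their harmonic mean;
    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)).

    A metric with zero denominator is reported as 0.0 and flagged undefined.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    ppv_ok = (tp + fp) > 0
    rec_ok = (tp + fn) > 0
    ppv = tp / (tp + fp) if ppv_ok else 0.0
    rec = tp / (tp + fn) if rec_ok else 0.0
    f1_ok = ppv_ok and rec_ok and (ppv + rec) > 0
    f1 = 2 * ppv * rec / (ppv + rec) if f1_ok else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc_ok = denom > 0
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if mcc_ok else 0.0
    return MetricReport(
        ppv=ppv, recall=rec, f1=f1, mcc=mcc,
        ppv_defined=ppv_ok, recall_defined=rec_ok, f1_defined=f1_ok, mcc_defined=mcc_ok,
    )


def _matches_one(pred_pairs, k: int, l: int) -> bool:
    """True if some predicted pair is (k,l) displaced by <=1 in at most one coordinate."""
    targets = {(k, l), (k - 1, l), (k + 1, l), (k, l - 1), (k, l + 1)}
    return any(p in targets for p in pred_pairs)


def core_stem_matches(pred: SecondaryStructure, truth_core: CoreStemCandidate) -> int:
    """How many of the two reference core pairs (0, 1 or 2) the prediction
    recovers under the ±1 single-coordinate displacement tolerance."""
    pairs = pred.pair_set
    n = 0
    for k, l in (truth_core.pair1, truth_core.pair2):
        if _matches_one(pairs, k, l):
            n += 1
    return n
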