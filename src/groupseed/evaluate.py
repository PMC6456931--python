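"""Scoring of overlap calls against ground truth.

Matching is on pair identity only: a reported pair counts as correct when
it appears in the truth set, regardless of the reported coordinates or
strand (downstream alignment refines coordinates anyway).  Sensitivity is
tp / (tp + fn), precision is tp / (tp + fp), and F1 is their harmonic
mean; per-bin sensitivity partitions the truth pairs by overlap length
into fixed-width bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

__all__ = ["EvaluationReport", "BinRow", "score_calls", "binned_sensitivity"]


@dataclass(frozen=True)
class BinRow:
    bin_index: int  # overlaps in [bin_index * width, (bin_index + 1) * width)
    truth_count: int
    detected_count: int
    sensitivity: float


@dataclass(frozen=True)
class EvaluationReport:
    tp: int
    fp: int
    fn: int
    sensitivity: float
    precision: float
    f1: float

    def as_text(self) -> str:
        return (
            f"tp\t{self.tp}\nfp\t{self.fp}\nfn\t{self.fn}\n"
            f"sensitivity\t{self.sensitivity:.4f}\n"
            f"precision\t{self.precision:.4f}\nf1\t{self.f1:.4f}\n"
        )


def _canonical_pairs(calls: Iterable) -> set:
    pairs = set()
    for item in calls:
        if isinstance(item, tuple):
            a, b = item[0], item[1]
        else:  # OverlapCall-like
            a, b = item.id_a, item.id_b
        pairs.add((a, b) if a <= b else (b, a))
    return pairs


def f1_score(sensitivity: float, precision: float) -> float:
    if sensitivity + precision == 0:
        return 0.0
    return 2.0 * sensitivity * precision / (sensitivity + precision)


def score_calls(calls: Iterable, truth: Iterable) -> EvaluationReport:
    """Score calls against truth pairs (duplicates collapsed; strand and
    coordinates ignored).  With zero calls precision is defined as 0."""
    called = _canonical_pairs(calls)
    truth_pairs = _canonical_pairs(truth)
    tp = len(called & truth_pairs)
    fp = len(called - truth_pairs)
    fn = len(truth_pairs - called)
    sens = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    return EvaluationReport(
        tp=tp, fp=fp, fn=fn,
        sensitivity=sens, precision=prec,
        f1=round(f1_score(sens, prec), 4),
    )


def binned_sensitivity(
    calls: Iterable,
    truth: Dict[Tuple[str, str], int],
    bin_width: int = 500,
) -> List[BinRow]:
    """Per-bin sensitivity over truth pairs binned by overlap length;
    a pair with overlap L lands in bin floor(L / bin_width)."""
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    called = _canonical_pairs(calls)
    totals: Dict[int, int] = {}
    hits: Dict[int, int] = {}
    for pair, length in truth.items():
        pair = pair if pair[0] <= pair[1] else (pair[1], pair[0])
        b = length // bin_width
        totals[b] = totals.get(b, 0) + 1
        if pair in called:
            hits[b] = hits.get(b, 0) + 1
    return [
        BinRow(
            bin_index=b,
            truth_count=totals[b],
            detected_count=hits.get(b, 0),
            sensitivity=hits.get(b, 0) / totals[b],
        )
        for b in sorted(totals)
    ]
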