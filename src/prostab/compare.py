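"""Comparative engine: percentage change between structure pairs and
prediction evaluation.

For a thermophile/mesophile pair the percentage change of a parameter is

    (TS_norm - MS_norm) / MS_norm

on the normalized values.  A parameter absent (zero or undefined) in both
members is rendered '#'; absent only in the mesophilic member, '~'; absent
only in the thermophilic member the formula itself yields -1.0 and the
cell stays numeric.  Counting 'positive' outcomes per parameter — numeric
values > 0 plus '~' cells — summarizes, across a family panel, how often
the thermophilic member shows more of the parameter.
"""

from __future__ import annotations

import dataclasses
import math

import pandas as pd

from .model import Structure
from .profiles import FEATURE_NAMES, FeatureVector, feature_vector

__all__ = [
    "ComparisonRecord",
    "ComparisonTable",
    "PredictionEvaluation",
    "percent_change",
    "compare_feature_vectors",
    "compare_pairs",
    "evaluate_predictions",
    "positive_count",
]

ABSENT_BOTH = "#"
ABSENT_MS = "~"


@dataclasses.dataclass
class ComparisonRecord:
    parameter: str
    ts_norm: float | None
    ms_norm: float | None
    value: float | None  # numeric percentage change; None when coded
    code: str  # "numeric", "#", or "~"

    def display(self, decimals: int = 2) -> str:
        if self.code != "numeric":
            return self.code
        return f"{self.value:.{decimals}f}"


def _absent(x: float | None) -> bool:
    return x is None or x == 0


def percent_change(
    ts_norm: float | None, ms_norm: float | None, parameter: str = ""
) -> ComparisonRecord:
    """One comparison cell; see the module docstring for the coding rules."""
    for v in (ts_norm, ms_norm):
        if v is not None and v < 0:
            raise ValueError("normalized feature values must be non-negative")
    if _absent(ms_norm):
        if _absent(ts_norm):
            return ComparisonRecord(parameter, ts_norm, ms_norm, None, ABSENT_BOTH)
        return ComparisonRecord(parameter, ts_norm, ms_norm, None, ABSENT_MS)
    ts = 0.0 if ts_norm is None else ts_norm
    value = (ts - ms_norm) / ms_norm
    return ComparisonRecord(parameter, ts_norm, ms_norm, value, "numeric")


def positive_count(records: list[ComparisonRecord]) -> int:
    """Numeric values > 0 plus '~' cells (mesophile-only absence counts as
    a thermophile preference)."""
    return sum(
        1
        for r in records
        if (r.code == "numeric" and r.value > 0) or r.code == ABSENT_MS
    )


@dataclasses.dataclass
class ComparisonTable:
    """Rows = parameters, columns = pairs, plus the positive-count column."""

    pair_labels: list[str]
    cells: dict[str, list[ComparisonRecord]]  # parameter -> one per pair

    def positive_counts(self) -> dict[str, int]:
        return {p: positive_count(rows) for p, rows in self.cells.items()}

    def to_frame(self, decimals: int = 2) -> pd.DataFrame:
        data = {}
        for parameter, rows in self.cells.items():
            data[parameter] = [r.display(decimals) for r in rows] + [
                positive_count(rows)
            ]
        frame = pd.DataFrame(
            data, index=self.pair_labels + ["positive_count"]
        ).T
        frame.index.name = "parameter"
        return frame


def compare_feature_vectors(
    pairs: list[tuple[FeatureVector, FeatureVector]],
    labels: list[str] | None = None,
) -> ComparisonTable:
    """Comparison table from precomputed (thermophile, mesophile) vectors."""
    if not pairs:
        raise ValueError("need at least one pair")
    if labels is None:
        labels = [f"{ts.structure_id}/{ms.structure_id}" for ts, ms in pairs]
    cells: dict[str, list[ComparisonRecord]] = {p: [] for p in FEATURE_NAMES}
    for ts, ms in pairs:
        for parameter in FEATURE_NAMES:
            cells[parameter].append(
                percent_change(
                    ts.normalized.get(parameter),
                    ms.normalized.get(parameter),
                    parameter,
                )
            )
    return ComparisonTable(labels, cells)


def compare_pairs(
    pairs: list[tuple[Structure, Structure]],
    params: dict | None = None,
    on_error: str = "drop",
) -> ComparisonTable:
    """Comparison table from (thermophile, mesophile) structure pairs.

    A pair whose feature extraction fails is dropped with a logged reason
    (``on_error='raise'`` re-raises instead).
    """
    import logging

    log = logging.getLogger(__name__)
    vectors = []
    labels = []
    for ts, ms in pairs:
        try:
            vectors.append((feature_vector(ts, params), feature_vector(ms, params)))
            labels.append(f"{ts.id}/{ms.id}")
        except Exception:
            if on_error == "raise":
                raise
            log.exception("dropping pair %s/%s", ts.id, ms.id)
    return compare_feature_vectors(vectors, labels)


@dataclasses.dataclass
class PredictionEvaluation:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        """TP/(TP+FP) — the ratio reported as the headline true-positive
        rate in the original validation write-up."""
        return self.tp / (self.tp + self.fp)

    @property
    def sensitivity(self) -> float:
        """TP/(TP+FN), the conventional true-positive rate."""
        return self.tp / (self.tp + self.fn)

    @property
    def false_positive_rate(self) -> float:
        return self.fp / (self.fp + self.tn)


def _classify(experimental: str, predicted: str) -> str:
    """Confusion cell with increase = positive.

    A neutral experimental outcome counts against the prediction: calling
    'I' on a no-change mutant is a false positive, calling 'D' on one a
    false negative.
    """
    if predicted == "I":
        return "tp" if experimental == "I" else "fp"
    if predicted == "D":
        return "tn" if experimental == "D" else "fn"
    raise ValueError(f"predicted label must be I or D, got {predicted!r}")


def evaluate_predictions(
    records: list[tuple[str, str]],
    scores: list[float] | None = None,
) -> PredictionEvaluation | tuple[PredictionEvaluation, list[tuple[float, float, float]]]:
    """Confusion counts and rates from (experimental, predicted) labels.

    Labels are 'I' (stability increase), 'D' (decrease) or, for the
    experimental side, 'N' (no change).  With ``scores`` supplied (same
    order, higher = more stabilizing) ROC points are generated by sweeping
    a symmetric neutral band of half-width c on the score: predictions
    inside the band are treated as neutral and dropped, and (FPR, TPR) is
    recomputed at each c.
    """
    if not records:
        raise ValueError("no prediction records supplied")
    counts = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for experimental, predicted in records:
        if experimental not in ("I", "D", "N"):
            raise ValueError(f"experimental label must be I/D/N, got {experimental!r}")
        counts[_classify(experimental, predicted)] += 1
    evaluation = PredictionEvaluation(**counts)
    if scores is None:
        return evaluation
    if len(scores) != len(records):
        raise ValueError("scores and records length mismatch")
    roc = []
    for c in sorted({0.0} | {abs(s) for s in scores}):
        kept = [
            (exp, "I" if s > 0 else "D")
            for (exp, _), s in zip(records, scores)
            if abs(s) > c or c == 0.0
        ]
        sub = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
        for experimental, predicted in kept:
            sub[_classify(experimental, predicted)] += 1
        tpr = sub["tp"] / (sub["tp"] + sub["fn"]) if sub["tp"] + sub["fn"] else 0.0
        fpr = sub["fp"] / (sub["fp"] + sub["tn"]) if sub["fp"] + sub["tn"] else 0.0
        roc.append((c, fpr, tpr))
    return evaluation, roc
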