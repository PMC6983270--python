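"""Scoring doublet calls against known truth, and multi-caller consensus.

Sensitivity is the fraction of known doublets called as doublets;
specificity the fraction of known singlets called as singlets; both are
reported as percentages. F1 = 2TP / (2TP + FP + FN) summarizes overall
performance under the uneven class balance typical of these benchmarks.
Call sets from several tools (or several runs of one stochastic tool) can
be combined by union (favors sensitivity), intersection (favors
specificity), or all-runs consensus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import pandas as pd

__all__ = [
    "PerformanceTable",
    "confusion",
    "combine_calls",
    "consensus_runs",
    "percent",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (display convention of the tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """A percentage rounded half-up for display (e.g., a doublet rate)."""
    return round_half_up(100.0 * numerator / denominator, decimals)


@dataclass
class PerformanceTable:
    """Confusion counts and the derived sensitivity/specificity/F1."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        """Percentage of known doublets called; NaN when none are known."""
        denom = self.tp + self.fn
        return math.nan if denom == 0 else 100.0 * self.tp / denom

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return math.nan if denom == 0 else 100.0 * self.tn / denom

    @property
    def f1(self) -> float:
        denom = 2 * self.tp + self.fp + self.fn
        return math.nan if denom == 0 else 2.0 * self.tp / denom

    def display(self) -> dict:
        """Counts plus metrics rounded half-up to 2 decimals."""
        return {
            "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
            "sensitivity": round_half_up(self.sensitivity)
            if not math.isnan(self.sensitivity) else math.nan,
            "specificity": round_half_up(self.specificity)
            if not math.isnan(self.specificity) else math.nan,
            "f1": round_half_up(self.f1)
            if not math.isnan(self.f1) else math.nan,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.display()])


def confusion(
    called_doublets: Iterable,
    truth_doublets: Iterable,
    universe: Iterable,
    exclude: Iterable = (),
) -> PerformanceTable:
    """Confusion counts of a call set against truth over a cell universe.

    ``exclude`` (e.g., ambiguous barcodes) is removed from all three sets
    before counting.
    """
    excl = set(exclude)
    uni = set(universe) - excl
    called = set(called_doublets) & uni
    truth = set(truth_doublets) & uni
    tp = len(called & truth)
    fp = len(called - truth)
    fn = len(truth - called)
    tn = len(uni) - tp - fp - fn
    return PerformanceTable(tp=tp, fp=fp, tn=tn, fn=fn)


def combine_calls(call_sets: list, mode: str = "union") -> set:
    """Union or intersection of >= 2 call sets."""
    if len(call_sets) < 2:
        raise ValueError("need at least 2 call sets to combine")
    sets = [set(s) for s in call_sets]
    if mode == "union":
        return set().union(*sets)
    if mode == "intersection":
        return set.intersection(*sets)
    raise ValueError(f"mode must be 'union' or 'intersection', got {mode!r}")


def consensus_runs(run_call_sets: list) -> set:
    """Cells called as doublets in every one of the supplied runs."""
    if len(run_call_sets) == 0:
        raise ValueError("need at least one run")
    sets = [set(s) for s in run_call_sets]
    return set.intersection(*sets)
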