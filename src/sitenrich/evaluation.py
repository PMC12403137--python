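"""Scoring of predictions against ground truth.

Protein-level predictions are compared as (protein, EC number) pairs with
matching at a configurable depth of the four-level EC hierarchy;
residue-level predictions are compared as sets against the true active site
(catalytic residues plus 3.5 A neighbors) and against the catalytic residues
alone. Proportions carry Wilson score confidence intervals, and per-class
performance can be stratified into frequency bins by how often an enzyme
class occurs in the annotation source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .reference import EC_PATTERN
from .structure_io import ResidueKey

__all__ = [
    "GroundTruth",
    "MetricReport",
    "ec_match_level",
    "protein_metrics",
    "residue_metrics",
    "frequency_bins",
    "wilson_interval",
    "DEFAULT_BIN_EDGES",
]


@dataclass
class GroundTruth:
    """True annotations: per-protein EC numbers and active-site residues."""

    protein_ecs: dict[str, set[str]]
    active_site: dict[str, set[ResidueKey]] = field(default_factory=dict)
    catalytic: dict[str, set[ResidueKey]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, cat in self.catalytic.items():
            site = self.active_site.get(pid, set())
            if not cat <= site:
                raise ValueError(f"protein {pid!r}: catalytic residues not a subset of the site")


@dataclass
class MetricReport:
    precision: float
    recall: float
    f1: float
    precision_ci: tuple[float, float]
    recall_ci: tuple[float, float]
    n_predicted: int
    n_truth: int


def ec_match_level(predicted_ec: str, true_ec: str) -> int:
    """Depth of agreement (0-4) between two EC numbers.

    Counts leading fields that agree before the first mismatch; a dash on
    either side ends the comparison without counting (partial numbers can
    match only as deep as they are specified).
    """
    for ec in (predicted_ec, true_ec):
        if not EC_PATTERN.match(ec):
            raise ValueError(f"malformed EC number {ec!r}")
    level = 0
    for a, b in zip(predicted_ec.split("."), true_ec.split(".")):
        if a == "-" or b == "-" or a != b:
            break
        level += 1
    return level


def wilson_interval(
    successes: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("Wilson interval requires n >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must be in [0, {n}], got {successes}")
    z = stats.norm.ppf(0.5 + confidence / 2)
    phat = successes / n
    denom = 1 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    # bounds are exactly 0/1 at the boundary counts; guard the float error
    low = 0.0 if successes == 0 else max(0.0, center - half)
    high = 1.0 if successes == n else min(1.0, center + half)
    return (low, high)


def _f1(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if p + r > 0 else 0.0


def protein_metrics(
    predictions: Iterable[tuple[str, str]],
    truth: GroundTruth,
    level: int = 4,
    confidence: float = 0.95,
) -> MetricReport:
    """Micro-averaged precision/recall/F1 over (protein, EC) pairs.

    A predicted pair is a true positive if the protein has a true EC number
    matching it to at least ``level``; a truth pair is recovered if some
    prediction for its protein matches it at that depth. With zero
    predictions precision is reported as 1 with ``n_predicted = 0``
    (declining to predict harms recall only).
    """
    if not truth.protein_ecs:
        raise ValueError("empty ground truth")
    predictions = set(predictions)
    for pid, _ in predictions:
        if pid not in truth.protein_ecs:
            raise KeyError(f"predicted protein {pid!r} absent from the truth universe")

    tp_pred = sum(
        1
        for pid, ec in predictions
        if any(ec_match_level(ec, true_ec) >= level for true_ec in truth.protein_ecs[pid])
    )
    truth_pairs = [(pid, ec) for pid, ecs in truth.protein_ecs.items() for ec in ecs]
    tp_truth = sum(
        1
        for pid, true_ec in truth_pairs
        if any(
            ec_match_level(pred_ec, true_ec) >= level
            for p, pred_ec in predictions
            if p == pid
        )
    )
    n_pred, n_truth = len(predictions), len(truth_pairs)
    precision = tp_pred / n_pred if n_pred else 1.0
    recall = tp_truth / n_truth
    return MetricReport(
        precision=precision,
        recall=recall,
        f1=_f1(precision, recall),
        precision_ci=wilson_interval(tp_pred, n_pred, confidence) if n_pred else (0.0, 1.0),
        recall_ci=wilson_interval(tp_truth, n_truth, confidence),
        n_predicted=n_pred,
        n_truth=n_truth,
    )


def residue_metrics(
    predicted_residues: set[ResidueKey],
    truth_active_site: set[ResidueKey],
    truth_catalytic: set[ResidueKey] | None = None,
    confidence: float = 0.95,
) -> tuple[MetricReport, float]:
    """Residue-level precision/recall vs the active site, plus catalytic recall.

    The active site comprises catalytic residues and their 3.5 A neighbors;
    catalytic recall is reported separately since neighbors are less
    functionally critical and dominate the site denominator.
    """
    if not truth_active_site:
        raise ValueError("empty truth active site")
    truth_catalytic = truth_catalytic or set()
    tp = len(predicted_residues & truth_active_site)
    n_pred = len(predicted_residues)
    precision = tp / n_pred if n_pred else 1.0
    recall = tp / len(truth_active_site)
    report = MetricReport(
        precision=precision,
        recall=recall,
        f1=_f1(precision, recall),
        precision_ci=wilson_interval(tp, n_pred, confidence) if n_pred else (0.0, 1.0),
        recall_ci=wilson_interval(tp, len(truth_active_site), confidence),
        n_predicted=n_pred,
        n_truth=len(truth_active_site),
    )
    cat_recall = (
        len(predicted_residues & truth_catalytic) / len(truth_catalytic)
        if truth_catalytic
        else float("nan")
    )
    return report, cat_recall


#: Default five-bin edges on class frequency: [1,5), [5,20), [20,50), [50,100), [100, inf).
#: Only the rare boundary (<5) and the top boundary (>=100) are fixed by the
#: analysis design; the middle edges are configurable.
DEFAULT_BIN_EDGES = (1, 5, 20, 50, 100)


def frequency_bins(
    class_counts: Mapping[str, int], bin_edges: Sequence[int] = DEFAULT_BIN_EDGES
) -> dict[str, int]:
    """Assign each class to a frequency bin (1 = rarest).

    ``bin_edges`` are left edges; a count falls in bin ``i`` when
    ``edges[i-1] <= count < edges[i]``, and counts at or above the last edge
    fall in the top bin.
    """
    edges = np.asarray(bin_edges)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    out: dict[str, int] = {}
    for ec, count in class_counts.items():
        if count < 1:
            raise ValueError(f"class {ec!r} has count {count}; counts must be >= 1")
        out[ec] = int(np.searchsorted(edges, count, side="right"))
    return out
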