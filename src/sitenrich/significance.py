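"""Function-specific empirical nulls, empirical P-values and BH-FDR.

Raw enrichment scores are not comparable across classes: class size and the
internal correlation of its embeddings shape each class's null. Label
permutation (the classical gene-set approach) over-reports significance for
internally correlated sets, so significance is instead assessed against a
**function-specific empirical background**: for each class, the ES computed
on every background protein *not* annotated with that class. The empirical
P-value of a new score ``s`` is then a tail fraction of that background.

P-value conventions
-------------------
``right-tail`` (default)
    ``p = #{d_i >= s} / n`` — larger scores give smaller p; ties count
    toward the tail (conservative).
``pseudocount``
    ``p = (1 + #{d_i >= s}) / (1 + n)`` — never exactly zero; exactly
    calibrated under exchangeability.
``literal``
    ``p = #{s > d_i} / n`` — the opposite-direction variant retained as a
    compatibility/audit mode; anti-monotone in evidence, do not use for
    calling.

Multiple testing across the classes tested for one protein is controlled
with the Benjamini–Hochberg step-up procedure; a class is called significant
when its q-value is at most the threshold (default 0.001, where
precision/recall plateaus in validation-scale experiments) *and* its score
is positive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .embeddings import EmbeddingRecord
from .enrichment import RankedList, enrichment_score, rank_database, similarity_matrix
from .reference import ReferenceDatabase
from .structure_io import ResidueKey

__all__ = [
    "PVALUE_MODES",
    "BackgroundDistribution",
    "BackgroundProtein",
    "SignificanceResult",
    "ks_es_statistic",
    "build_background",
    "empirical_pvalue",
    "bh_fdr",
    "call_significant",
    "save_backgrounds",
    "load_backgrounds",
]

PVALUE_MODES = ("right-tail", "pseudocount", "literal")

#: Background sizes below this are usable but flagged low-power.
DEFAULT_MIN_BACKGROUND = 50

#: A per-class score of a ranked list: (ranked, db, class_id) -> float.
ClassScoreFn = Callable[[RankedList, ReferenceDatabase, str], float]


def ks_es_statistic(weight_exponent: float = 1.0) -> ClassScoreFn:
    """The default class statistic: the weighted K-S enrichment score."""

    def score(ranked: RankedList, db: ReferenceDatabase, class_id: str) -> float:
        return enrichment_score(ranked, db, class_id, weight_exponent=weight_exponent).es

    return score


@dataclass
class BackgroundDistribution:
    """Empirical null scores of one class over eligible background proteins."""

    class_id: str
    scores: np.ndarray  # sorted ascending
    min_n: int = DEFAULT_MIN_BACKGROUND

    def __post_init__(self) -> None:
        self.scores = np.sort(np.asarray(self.scores, dtype=np.float64))

    @property
    def n(self) -> int:
        return len(self.scores)

    @property
    def low_power(self) -> bool:
        return self.n < self.min_n


@dataclass
class BackgroundProtein:
    """A background query: its embeddings and its known class annotations."""

    protein_id: str
    records: Sequence[EmbeddingRecord]
    annotations: frozenset[str] = frozenset()


@dataclass
class SignificanceResult:
    class_id: str
    es: float
    p_value: float
    q_value: float = float("nan")
    significant: bool = False
    low_power: bool = False


def build_background(
    proteins: Iterable[BackgroundProtein],
    db: ReferenceDatabase,
    score_fn: ClassScoreFn | None = None,
    min_n: int = DEFAULT_MIN_BACKGROUND,
) -> dict[str, BackgroundDistribution]:
    """Per-class empirical null distributions.

    For each class the statistic is computed on every protein **not**
    annotated with that class; annotated proteins are excluded so the null
    reflects proteins lacking the function. Classes with zero eligible
    proteins get no distribution and are reported untestable via a warning.
    """
    score_fn = score_fn or ks_es_statistic()
    scores: dict[str, list[float]] = {cid: [] for cid in db.class_ids}
    for protein in proteins:
        ranked = rank_database(
            similarity_matrix(protein.records, db), [r.key for r in protein.records]
        )
        for cid in db.class_ids:
            if cid in protein.annotations:
                continue
            scores[cid].append(score_fn(ranked, db, cid))
    out: dict[str, BackgroundDistribution] = {}
    for cid, vals in scores.items():
        if not vals:
            warnings.warn(
                f"class {cid!r} has no eligible background proteins; marked untestable",
                stacklevel=2,
            )
            continue
        out[cid] = BackgroundDistribution(class_id=cid, scores=np.array(vals), min_n=min_n)
    return out


def empirical_pvalue(
    s: float, background: BackgroundDistribution, mode: str = "right-tail"
) -> float:
    """Empirical P-value of score ``s`` against one class background."""
    if background.n == 0:
        raise ValueError(f"class {background.class_id!r} has an empty background")
    if mode not in PVALUE_MODES:
        raise ValueError(f"unknown p-value mode {mode!r}; choose from {PVALUE_MODES}")
    d = background.scores
    if mode == "right-tail":
        return float(np.count_nonzero(d >= s)) / background.n
    if mode == "pseudocount":
        return (1.0 + np.count_nonzero(d >= s)) / (1.0 + background.n)
    return float(np.count_nonzero(s > d)) / background.n  # literal


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the ascending-sorted
    p-values, clipped to 1.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_significant(
    results: list[SignificanceResult], threshold: float = 0.001
) -> list[SignificanceResult]:
    """Mark and sort significant calls.

    A class is significant iff ``q <= threshold`` (inclusive) and its score
    is positive — depletion never supports a call. Results are returned
    sorted by ascending q, then descending score, then class id.
    """
    for r in results:
        r.significant = bool(r.q_value <= threshold and r.es > 0)
    return sorted(results, key=lambda r: (r.q_value, -r.es, r.class_id))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_BG_VERSION = 1


def save_backgrounds(
    backgrounds: dict[str, BackgroundDistribution], path, db_checksum: str | None = None
) -> None:
    """Write backgrounds as a JSON bundle, versioned against the database."""
    payload = {
        "version": _BG_VERSION,
        "db_checksum": db_checksum,
        "classes": {
            cid: {"scores": bg.scores.tolist(), "min_n": bg.min_n}
            for cid, bg in backgrounds.items()
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_backgrounds(
    path, expected_checksum: str | None = None
) -> dict[str, BackgroundDistribution]:
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != _BG_VERSION:
        raise ValueError(f"background bundle {path!s}: unsupported version")
    stored = payload.get("db_checksum")
    if expected_checksum is not None and stored is not None and stored != expected_checksum:
        raise ValueError(
            f"background bundle {path!s} was built against a different reference database"
        )
    return {
        cid: BackgroundDistribution(
            class_id=cid, scores=np.array(entry["scores"]), min_n=entry["min_n"]
        )
        for cid, entry in payload["classes"].items()
    }
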