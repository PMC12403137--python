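"""Ranking of reference residues and weighted K-S enrichment scoring.

The annotation statistic works like preranked gene-set enrichment analysis,
with reference-database residues playing the role of genes and function
classes playing the role of gene sets:

1. every reference residue is scored by its **maximum cosine similarity** to
   any query residue (recording which query residue attained it);
2. the database is sorted by that score, descending;
3. for each class, a running sum ``S`` walks down the ranked list, increasing
   by ``|r_j|^p / N_R`` at class members (``r_j`` the member's similarity,
   ``N_R`` the sum of ``|r_j|^p`` over all members) and decreasing by
   ``1/(N - N_class)`` at non-members. The enrichment score (ES) is the value
   of ``S`` at its maximum absolute deviation from zero, signed.

The *leading edge* — class members ranked at or before the ES peak — maps
back through the max-similarity correspondence to the query residues that
explain the call.

The weight exponent ``p`` defaults to 1 (the classical weighted statistic);
``p = 0`` recovers the unweighted Kolmogorov–Smirnov form, for which the
running sum terminates exactly at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .embeddings import EmbeddingRecord
from .reference import ReferenceDatabase
from .structure_io import ResidueKey

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "similarity_matrix",
    "rank_database",
    "enrichment_score",
]


@dataclass
class RankedList:
    """Reference residues ordered by max similarity to the query.

    ``ref_indices[i]`` is the database index of the residue at rank ``i``
    (0-based internally; reported peak positions are 1-based ranks),
    ``similarities[i]`` its max similarity (non-increasing), and
    ``best_query[i]`` the query residue attaining that max.
    """

    ref_indices: np.ndarray
    similarities: np.ndarray
    best_query: list[ResidueKey]

    def __post_init__(self) -> None:
        self.ref_indices = np.asarray(self.ref_indices, dtype=np.intp)
        self.similarities = np.asarray(self.similarities, dtype=np.float64)
        if not (len(self.ref_indices) == len(self.similarities) == len(self.best_query)):
            raise ValueError("ranked list arrays must have equal length")
        if np.any(np.diff(self.similarities) > 1e-12):
            raise ValueError("similarities must be non-increasing")
        # rank position (0-based) of each database index
        self._rank_of = np.empty(len(self.ref_indices), dtype=np.intp)
        self._rank_of[self.ref_indices] = np.arange(len(self.ref_indices))

    def rank_of(self, ref_index: int) -> int:
        """0-based rank of a database residue."""
        return int(self._rank_of[ref_index])

    def __len__(self) -> int:
        return len(self.ref_indices)


@dataclass
class EnrichmentResult:
    """Per-class enrichment score with its explanatory residues."""

    class_id: str
    es: float
    peak_position: int  # 1-based rank where |S| is maximal
    leading_edge_refs: list[int]  # database indices, empty unless es > 0
    mapped_query_residues: set[ResidueKey]
    running_sum: np.ndarray | None = field(default=None, repr=False)


def similarity_matrix(
    query_records: Sequence[EmbeddingRecord], db: ReferenceDatabase
) -> np.ndarray:
    """Pairwise cosine similarities, shape ``(n_query, n_db)``.

    Entry (i, j) is ``dot(q_i, d_j) / (||q_i|| ||d_j||)``, clipped to
    [-1, 1] only against floating-point overshoot.
    """
    if not query_records:
        raise ValueError("no query records to compare")
    if len(db) == 0:
        raise ValueError("reference database is empty")
    Q = np.array([r.vector for r in query_records])
    if Q.shape[1] != db.dimension:
        raise ValueError(
            f"query embedding dimension {Q.shape[1]} != database dimension {db.dimension}"
        )
    D = db.embedding_matrix()
    qn = np.linalg.norm(Q, axis=1)
    dn = np.linalg.norm(D, axis=1)
    for norms, records, side in ((qn, query_records, "query"), (dn, db.residues, "database")):
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            raise ValueError(f"zero-norm {side} embedding for residue {records[bad[0]].key}")
    sim = (Q / qn[:, None]) @ (D / dn[:, None]).T
    return np.clip(sim, -1.0, 1.0)


def rank_database(
    sim: np.ndarray, query_keys: Sequence[ResidueKey] | None = None
) -> RankedList:
    """Sort reference residues by max similarity to any query residue.

    Ties between reference residues are broken by ascending database index;
    when several query residues tie as the argmax for one reference residue,
    the one with the lowest residue number (then earliest input position)
    wins. Both rules make the ranking fully deterministic.
    """
    sim = np.asarray(sim, dtype=np.float64)
    if sim.ndim != 2 or sim.shape[0] == 0 or sim.shape[1] == 0:
        raise ValueError("no rankable residues: similarity matrix is empty")
    n_query, n_db = sim.shape
    if query_keys is None:
        query_keys = [ResidueKey("query", "A", i + 1) for i in range(n_query)]
    if len(query_keys) != n_query:
        raise ValueError("query_keys length must match similarity matrix rows")

    scores = sim.max(axis=0)
    argmax = sim.argmax(axis=0)
    # resolve argmax ties toward the lowest residue number, then input order
    tie_cols = np.flatnonzero((sim == scores[None, :]).sum(axis=0) > 1)
    for j in tie_cols:
        rows = np.flatnonzero(sim[:, j] == scores[j])
        argmax[j] = min(rows, key=lambda i: (query_keys[i].residue_number, i))
    order = np.lexsort((np.arange(n_db), -scores))
    return RankedList(
        ref_indices=order,
        similarities=scores[order],
        best_query=[query_keys[argmax[j]] for j in order],
    )


def enrichment_score(
    ranked: RankedList,
    db: ReferenceDatabase,
    class_id: str,
    weight_exponent: float = 1.0,
    keep_trace: bool = False,
) -> EnrichmentResult:
    """Weighted K-S enrichment score of one class against the ranked list.

    See the module docstring for the running-sum definition. The ES is the
    signed value of ``S`` at the first position where ``|S|`` is maximal.
    The leading edge (class members at ranks <= peak) is populated only for
    positive scores: only enrichment, not depletion, can support a call.
    """
    member_idx = db.member_indices(class_id)
    N = len(ranked)
    n_class = len(member_idx)
    if n_class == 0:
        raise ValueError(f"class {class_id!r} has no residues in the ranked list")
    if n_class >= N:
        raise ValueError(
            f"class {class_id!r} covers the entire ranked list; enrichment is undefined"
        )

    member_mask = np.zeros(N, dtype=bool)
    member_mask[[ranked.rank_of(i) for i in member_idx]] = True
    r = ranked.similarities
    weights = np.abs(r[member_mask]) ** weight_exponent
    n_r = weights.sum()
    if n_r == 0:
        raise ValueError(
            f"class {class_id!r}: all member similarities are zero; running sum is undefined"
        )
    steps = np.full(N, -1.0 / (N - n_class))
    steps[member_mask] = weights / n_r
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))  # first occurrence: deterministic
    es = float(running[peak])

    leading_edge: list[int] = []
    mapped: set[ResidueKey] = set()
    if es > 0:
        hit_ranks = np.flatnonzero(member_mask[: peak + 1])
        leading_edge = [int(ranked.ref_indices[i]) for i in hit_ranks]
        mapped = {ranked.best_query[i] for i in hit_ranks}
    return EnrichmentResult(
        class_id=class_id,
        es=es,
        peak_position=peak + 1,
        leading_edge_refs=leading_edge,
        mapped_query_residues=mapped,
        running_sum=running if keep_trace else None,
    )
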