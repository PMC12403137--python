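"""Simpler similarity-based classifiers used as head-to-head baselines.

Four alternatives that consume the *same* ranked list as the enrichment
workflow but aggregate the residue similarities more directly:

* ``max_similarity`` — predict the class of the single most similar
  reference residue;
* ``topk_mean`` — predict the class with the highest mean over its top k%
  most similar members;
* ``direct_mwu`` — binarize the ranked list per class and run a one-sided
  Mann–Whitney U test that members rank nearer the top; predict the
  lowest-p class;
* ``mwu_background`` — the full significance workflow (function-specific
  empirical null + BH-FDR) with the K-S statistic replaced by the
  Mann–Whitney U statistic (scored as ``-log10 p`` so larger means more
  enriched).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .enrichment import RankedList
from .reference import ReferenceDatabase
from .significance import (
    BackgroundDistribution,
    ClassScoreFn,
    SignificanceResult,
    bh_fdr,
    call_significant,
    empirical_pvalue,
)

__all__ = [
    "BaselineResult",
    "max_similarity_baseline",
    "topk_mean_baseline",
    "mann_whitney_u",
    "mwu_neglogp_statistic",
    "direct_mwu_baseline",
    "mwu_background_baseline",
]

#: k values (percent) evaluated for the top-k% baseline.
DEFAULT_K_GRID = (10, 15, 20, 25, 30, 35, 40)

#: Exact Mann-Whitney enumeration is used up to this combined sample size.
_EXACT_MWU_LIMIT = 12


@dataclass
class BaselineResult:
    method: str
    class_scores: dict[str, float]
    predicted_class: str
    k_percent: int | None = None


def _member_similarities(ranked: RankedList, db: ReferenceDatabase) -> dict[str, np.ndarray]:
    """Per-class member similarities in ranked (descending) order."""
    out: dict[str, list[float]] = {cid: [] for cid in db.class_ids}
    for ref_idx, sim in zip(ranked.ref_indices, ranked.similarities):
        out[db.residues[ref_idx].class_id].append(float(sim))
    return {cid: np.array(v) for cid, v in out.items()}


def max_similarity_baseline(ranked: RankedList, db: ReferenceDatabase) -> BaselineResult:
    """Predict the class of the top-ranked reference residue.

    The ranked list's deterministic tie-break (ascending database index)
    resolves ties at the top.
    """
    if len(ranked) == 0:
        raise ValueError("empty ranked list")
    sims = _member_similarities(ranked, db)
    scores = {cid: float(v[0]) if v.size else -np.inf for cid, v in sims.items()}
    predicted = db.residues[int(ranked.ref_indices[0])].class_id
    return BaselineResult("max_similarity", scores, predicted)


def topk_mean_baseline(
    ranked: RankedList, db: ReferenceDatabase, k_percent: int
) -> BaselineResult:
    """Predict the class with the highest mean over its top k% members.

    The member count is ``ceil(k% of class size)``, never below one, so
    small classes always contribute at least their best residue.
    """
    if not 0 < k_percent <= 100:
        raise ValueError(f"k_percent must be in (0, 100], got {k_percent}")
    sims = _member_similarities(ranked, db)
    scores: dict[str, float] = {}
    for cid, v in sims.items():
        if v.size == 0:
            scores[cid] = -np.inf
            continue
        k = max(1, math.ceil(k_percent / 100 * v.size))
        scores[cid] = float(v[:k].mean())  # v already sorted descending
    predicted = max(db.class_ids, key=lambda cid: (scores[cid], -db.class_ids.index(cid)))
    return BaselineResult("topk_mean", scores, predicted, k_percent=k_percent)


def mann_whitney_u(
    in_class_ranks: Sequence[float], out_class_ranks: Sequence[float]
) -> tuple[float, float]:
    """One-sided Mann–Whitney U test that the in-class group ranks higher.

    Ranks are positions in the ranked list (1 = best), so "ranked higher"
    means *smaller* values. U counts pairs where the in-class member beats
    the out-class member. The p-value is exact (enumeration over all
    assignments) when the combined sample is small, otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    x = np.asarray(in_class_ranks, dtype=np.float64)
    y = np.asarray(out_class_ranks, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    u = float(np.sum(x[:, None] < y[None, :]) + 0.5 * np.sum(x[:, None] == y[None, :]))

    n1, n2 = x.size, y.size
    if n1 + n2 <= _EXACT_MWU_LIMIT:
        pooled = np.concatenate([x, y])
        count = total = 0
        for idx in combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            xx, yy = pooled[mask], pooled[~mask]
            uu = np.sum(xx[:, None] < yy[None, :]) + 0.5 * np.sum(xx[:, None] == yy[None, :])
            total += 1
            if uu >= u:
                count += 1
        return u, count / total

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    sigma = math.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
    if sigma == 0:
        return u, 1.0
    z = (u - 0.5 - mu) / sigma  # continuity correction
    return u, float(stats.norm.sf(z))


def _class_mwu_pvalues(ranked: RankedList, db: ReferenceDatabase) -> dict[str, float]:
    positions = np.arange(1, len(ranked) + 1, dtype=np.float64)
    class_of = np.array([db.residues[i].class_id for i in ranked.ref_indices])
    pvals: dict[str, float] = {}
    for cid in db.class_ids:
        mask = class_of == cid
        if not mask.any() or mask.all():
            raise ValueError(f"class {cid!r} cannot be tested against the rest of the list")
        _, p = mann_whitney_u(positions[mask], positions[~mask])
        pvals[cid] = p
    return pvals


def direct_mwu_baseline(ranked: RankedList, db: ReferenceDatabase) -> BaselineResult:
    """Predict the class whose members are most significantly top-ranked."""
    if len(db.class_ids) < 2:
        raise ValueError("direct MWU baseline needs at least 2 classes")
    pvals = _class_mwu_pvalues(ranked, db)
    predicted = min(db.class_ids, key=lambda cid: (pvals[cid], db.class_ids.index(cid)))
    return BaselineResult("direct_mwu", pvals, predicted)


def mwu_neglogp_statistic() -> ClassScoreFn:
    """Class statistic for the background workflow: ``-log10`` of the MWU p.

    Larger means more enriched, mirroring the direction of the enrichment
    score so the same right-tail empirical P-value applies.
    """

    def score(ranked: RankedList, db: ReferenceDatabase, class_id: str) -> float:
        positions = np.arange(1, len(ranked) + 1, dtype=np.float64)
        member_ranks = [ranked.rank_of(i) + 1 for i in db.member_indices(class_id)]
        mask = np.zeros(len(ranked), dtype=bool)
        mask[np.array(member_ranks) - 1] = True
        _, p = mann_whitney_u(positions[mask], positions[~mask])
        return -math.log10(max(p, 1e-300))

    return score


def mwu_background_baseline(
    ranked: RankedList,
    db: ReferenceDatabase,
    backgrounds: dict[str, BackgroundDistribution],
    score_fn: ClassScoreFn | None = None,
    fdr_threshold: float = 0.001,
    pvalue_mode: str = "right-tail",
) -> tuple[BaselineResult, list[SignificanceResult]]:
    """The full significance workflow with a plug-in class statistic.

    By default the statistic is the MWU ``-log10 p``; passing
    ``score_fn=ks_es_statistic()`` (with backgrounds built the same way)
    reproduces the primary enrichment workflow exactly — the pipeline is
    statistic-agnostic.
    """
    score_fn = score_fn or mwu_neglogp_statistic()
    results: list[SignificanceResult] = []
    for cid in db.class_ids:
        if cid not in backgrounds:
            continue
        s = score_fn(ranked, db, cid)
        results.append(
            SignificanceResult(
                class_id=cid,
                es=s,
                p_value=empirical_pvalue(s, backgrounds[cid], mode=pvalue_mode),
                low_power=backgrounds[cid].low_power,
            )
        )
    if not results:
        raise ValueError("no class has a background distribution")
    qs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    results = call_significant(results, threshold=fdr_threshold)
    best = results[0]
    baseline = BaselineResult(
        "mwu_background", {r.class_id: r.q_value for r in results}, best.class_id
    )
    return baseline, results
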