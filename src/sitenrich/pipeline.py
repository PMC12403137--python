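"""End-to-end annotation of one query protein.

Pipeline: embed (or load embeddings) -> pLDDT filter -> cosine similarity ->
rank reference residues -> per-class enrichment score -> empirical P-value
against the function-specific background -> BH-FDR -> significance call ->
optional structural post-filters. Deterministic given identical inputs and
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

from .embeddings import EmbeddingRecord
from .enrichment import enrichment_score, rank_database, similarity_matrix
from .filters import (
    apply_proteome_filters,
    kabsch_superpose,
    match_catalytic,
    paired_atom_coordinates,
)
from .reference import ReferenceDatabase, class_to_ec
from .significance import (
    BackgroundDistribution,
    SignificanceResult,
    bh_fdr,
    call_significant,
    empirical_pvalue,
)
from .structure_io import ResidueKey, StructureModel

__all__ = ["AnnotateConfig", "Prediction", "AnnotationResult", "annotate_protein"]


@dataclass(frozen=True)
class AnnotateConfig:
    """Tunable parameters of the annotation pipeline.

    ``fdr``: BH-corrected significance threshold (inclusive).
    ``min_plddt``: confidence cutoff for predicted structures (inclusive).
    ``weight_exponent``: K-S weighting; 1 = classical weighted, 0 = unweighted.
    ``pvalue_mode``: empirical-tail convention (see :mod:`sitenrich.significance`).
    ``apply_filters``: run the catalytic-coverage/RMSD post-filters when
    structures are available.
    """

    fdr: float = 0.001
    min_plddt: float = 70.0
    weight_exponent: float = 1.0
    pvalue_mode: str = "right-tail"
    apply_filters: bool = False
    report_all: bool = False
    min_coverage: float = 0.75
    max_rmsd: float = 5.0
    min_matches: int = 2

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Prediction:
    """One (protein, function class) call with its explanatory residues."""

    protein_id: str
    class_id: str
    ec_number: str
    es: float
    p_value: float
    q_value: float
    significant: bool
    leading_edge: list[tuple[ResidueKey, float]]  # query residue, similarity
    low_power: bool = False
    filter_passed: bool | None = None
    filter_reasons: list[str] = field(default_factory=list)
    coverage: float | None = None
    rmsd: float | None = None

    @property
    def residues(self) -> set[ResidueKey]:
        return {key for key, _ in self.leading_edge}


@dataclass
class AnnotationResult:
    protein_id: str
    predictions: list[Prediction]
    untestable_classes: list[str]
    n_residues_used: int
    unannotatable: bool = False

    @property
    def significant(self) -> list[Prediction]:
        return [p for p in self.predictions if p.significant]


def annotate_protein(
    query_records: Sequence[EmbeddingRecord],
    db: ReferenceDatabase,
    backgrounds: dict[str, BackgroundDistribution],
    config: AnnotateConfig = AnnotateConfig(),
    protein_id: str | None = None,
    query_model: StructureModel | None = None,
    reference_models: dict[str, StructureModel] | None = None,
) -> AnnotationResult:
    """Annotate one query protein against the reference database.

    ``query_records`` are the (already pLDDT-filtered) residue embeddings.
    With ``config.apply_filters`` and both ``query_model`` and per-class
    ``reference_models`` supplied, each significant call additionally gets
    catalytic coverage, all-atom RMSD and a pass/fail verdict.

    An empty ``query_records`` (e.g. every residue below the confidence
    cutoff) yields a structured unannotatable result rather than an error.
    Classes without a background distribution are reported untestable.
    """
    pid = protein_id or (query_records[0].key.structure_id if query_records else "query")
    if not query_records:
        return AnnotationResult(pid, [], list(db.class_ids), 0, unannotatable=True)

    sim = similarity_matrix(query_records, db)
    ranked = rank_database(sim, [r.key for r in query_records])

    untestable = [cid for cid in db.class_ids if cid not in backgrounds]
    testable = [cid for cid in db.class_ids if cid in backgrounds]
    if not testable:
        return AnnotationResult(pid, [], untestable, len(query_records))

    enrichments = {
        cid: enrichment_score(ranked, db, cid, weight_exponent=config.weight_exponent)
        for cid in testable
    }
    results = [
        SignificanceResult(
            class_id=cid,
            es=enrichments[cid].es,
            p_value=empirical_pvalue(enrichments[cid].es, backgrounds[cid], config.pvalue_mode),
            low_power=backgrounds[cid].low_power,
        )
        for cid in testable
    ]
    for r, q in zip(results, bh_fdr([r.p_value for r in results])):
        r.q_value = float(q)
    results = call_significant(results, threshold=config.fdr)

    predictions: list[Prediction] = []
    for res in results:
        if not (res.significant or config.report_all):
            continue
        enr = enrichments[res.class_id]
        leading = sorted(
            (
                (ranked.best_query[ranked.rank_of(i)], float(ranked.similarities[ranked.rank_of(i)]))
                for i in enr.leading_edge_refs
            ),
            key=lambda t: -t[1],
        )
        # one entry per query residue, keeping its best similarity
        seen: dict[ResidueKey, float] = {}
        for key, s in leading:
            if key not in seen:
                seen[key] = s
        pred = Prediction(
            protein_id=pid,
            class_id=res.class_id,
            ec_number=class_to_ec(db, res.class_id),
            es=res.es,
            p_value=res.p_value,
            q_value=res.q_value,
            significant=res.significant,
            leading_edge=sorted(seen.items(), key=lambda t: (-t[1], t[0])),
            low_power=res.low_power,
        )
        if config.apply_filters and query_model is not None and reference_models is not None:
            _apply_filters(pred, enrichments[res.class_id], db, query_model,
                           reference_models, ranked, config)
        predictions.append(pred)
    return AnnotationResult(pid, predictions, untestable, len(query_records))


def _apply_filters(pred, enr, db, query_model, reference_models, ranked, config) -> None:
    correspondences = {
        db.residues[i].key: ranked.best_query[ranked.rank_of(i)] for i in enr.leading_edge_refs
    }
    catalytic = db.catalytic_residues(pred.class_id)
    match = match_catalytic(correspondences, catalytic)
    pred.coverage = match.coverage
    superposition = None
    ref_model = reference_models.get(db.classes[pred.class_id].reference_structure_id)
    if ref_model is not None and match.n_pairs >= config.min_matches:
        ref_xyz, query_xyz = paired_atom_coordinates(ref_model, query_model, match.pairs)
        if len(ref_xyz) >= 3:
            superposition = kabsch_superpose(ref_xyz, query_xyz)
            pred.rmsd = superposition.rmsd
    passed, reasons = apply_proteome_filters(
        match,
        superposition,
        min_coverage=config.min_coverage,
        max_rmsd=config.max_rmsd,
        min_matches=config.min_matches,
    )
    pred.filter_passed = passed
    pred.filter_reasons = reasons
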