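"""High-specificity structural post-filters for proteome-scale scans.

Proteome-wide scans hit low-complexity structures whose residues match many
reference sites; such spurious calls are removed by demanding that the
predicted site structurally reproduces the reference catalytic machinery:

1. **exact catalytic matching** — each reference catalytic residue counts as
   identified only if it sits in the leading edge and its mapped query
   residue has the identical amino acid;
2. **coverage** — at least 75% of the reference catalytic residues must be
   identified (boundary inclusive);
3. **geometry** — after Kabsch superposition of the matched catalytic
   residues (all atoms, backbone and side chain), the RMSD must be below
   5 angstroms (boundary exclusive), and at least two catalytic residues
   must match for the superposition to be meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .reference import ReferenceResidue
from .structure_io import ResidueKey, StructureModel

__all__ = [
    "CatalyticMatch",
    "SuperpositionResult",
    "match_catalytic",
    "kabsch_superpose",
    "paired_atom_coordinates",
    "apply_proteome_filters",
]


@dataclass
class CatalyticMatch:
    """Reference-to-query catalytic residue pairs with identical amino acids."""

    pairs: list[tuple[ResidueKey, ResidueKey]]
    coverage: float  # matched / total reference catalytic residues

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class SuperpositionResult:
    """Optimal rigid superposition of corresponded coordinate sets."""

    rotation: np.ndarray  # 3x3, proper (det = +1)
    translation: np.ndarray  # applied after rotation, angstroms
    rmsd: float
    n_atoms: int


def match_catalytic(
    correspondences: Mapping[ResidueKey, ResidueKey],
    reference_catalytic: Sequence[ReferenceResidue],
) -> CatalyticMatch:
    """Pair reference catalytic residues with their mapped query residues.

    ``correspondences`` maps leading-edge reference residue keys to the query
    residues that attained their max similarity. A pair is kept only when the
    amino acids are identical (an active-site substitution such as a
    threonine replacing a catalytic histidine disqualifies the residue).
    Pairs are distinct on both sides; coverage is the matched fraction of
    **all** catalytic residues of the class.
    """
    if not reference_catalytic:
        raise ValueError("reference catalytic set is empty")
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    used_query: set[ResidueKey] = set()
    for ref in reference_catalytic:
        query = correspondences.get(ref.key)
        if query is None or query in used_query:
            continue
        if query.amino_acid == ref.key.amino_acid:
            pairs.append((ref.key, query))
            used_query.add(query)
    return CatalyticMatch(pairs=pairs, coverage=len(pairs) / len(reference_catalytic))


def kabsch_superpose(
    coords_ref: np.ndarray, coords_query: np.ndarray
) -> SuperpositionResult:
    """Least-squares rigid superposition of the query onto the reference.

    Closed-form SVD solution with reflection correction, so the returned
    rotation is always proper (det = +1) even for mirrored inputs. Points
    correspond by position; both sets need at least 3 atoms. Degenerate
    (rank-deficient, e.g. collinear) sets still return a result but emit a
    warning, since the in-plane/axial component of the rotation is then
    arbitrary.
    """
    P = np.asarray(coords_query, dtype=np.float64)
    R = np.asarray(coords_ref, dtype=np.float64)
    if P.shape != R.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"coordinate sets must both be (n, 3); got {R.shape} and {P.shape}")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs at least 3 atoms, got {n}")

    pc, rc = P.mean(axis=0), R.mean(axis=0)
    P0, R0 = P - pc, R - rc
    if min(np.linalg.matrix_rank(P0), np.linalg.matrix_rank(R0)) < 2:
        warnings.warn("degenerate (collinear) coordinate set; superposition is not unique",
                      stacklevel=2)
    H = P0.T @ R0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    rot = Vt.T @ D @ U.T
    transformed = P0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((transformed - R0) ** 2, axis=1))))
    translation = rc - rot @ pc
    return SuperpositionResult(rotation=rot, translation=translation, rmsd=rmsd, n_atoms=n)


def paired_atom_coordinates(
    ref_model: StructureModel,
    query_model: StructureModel,
    pairs: Sequence[tuple[ResidueKey, ResidueKey]],
) -> tuple[np.ndarray, np.ndarray]:
    """Corresponded all-atom coordinates of matched residue pairs.

    Atoms correspond by name within each pair (backbone and side chain);
    atoms present on only one side are skipped.
    """
    ref_coords: list = []
    query_coords: list = []
    for ref_key, query_key in pairs:
        ref_atoms = {a.atom_name: a.position for a in ref_model.residue_atoms(ref_key)}
        query_atoms = {a.atom_name: a.position for a in query_model.residue_atoms(query_key)}
        for name, pos in ref_atoms.items():
            if name in query_atoms:
                ref_coords.append(pos)
                query_coords.append(query_atoms[name])
    return np.array(ref_coords), np.array(query_coords)


def apply_proteome_filters(
    match: CatalyticMatch,
    superposition: SuperpositionResult | None,
    min_coverage: float = 0.75,
    max_rmsd: float = 5.0,
    min_matches: int = 2,
) -> tuple[bool, list[str]]:
    """Evaluate the high-specificity filters on one prediction.

    Pass requires coverage >= ``min_coverage`` (inclusive), at least
    ``min_matches`` matched catalytic residues (inclusive), and superposition
    RMSD strictly below ``max_rmsd``. Returns the verdict and the list of
    failure reasons (empty on pass).
    """
    reasons: list[str] = []
    if match.coverage < min_coverage:
        reasons.append(
            f"catalytic coverage {match.coverage:.3f} below required {min_coverage:.2f}"
        )
    if match.n_pairs < min_matches:
        reasons.append(f"only {match.n_pairs} matched catalytic residues; need >= {min_matches}")
    if superposition is None:
        if match.n_pairs >= min_matches:
            reasons.append("no superposition available")
    elif not superposition.rmsd < max_rmsd:
        reasons.append(f"RMSD {superposition.rmsd:.3f} A not below {max_rmsd:.1f} A")
    return (not reasons), reasons
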