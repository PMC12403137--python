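"""Synthetic data: class-structured embeddings, planted queries, toy structures.

The generators emulate the statistical structure the annotator relies on —
residues of one functional site are close in embedding space, unrelated
residues are near-orthogonal in high dimension — without any trained
embedder or downloaded structure:

* reference databases whose class centroids are uniform on the unit sphere
  and whose members are centroid-plus-Gaussian-noise, renormalized;
* query proteins with a *planted* functional site (noisy copies of one
  class's members) buried among isotropic background residues;
* pure-null proteins and cohorts of them, for empirical backgrounds and
  calibration experiments;
* deterministic toy coordinate structures for neighbor-expansion and
  superposition tests.

All generators take explicit integer seeds and never touch global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embeddings import EmbeddingRecord
from .reference import FunctionClass, ReferenceDatabase, ReferenceResidue
from .significance import BackgroundProtein
from .structure_io import STANDARD_AMINO_ACIDS, AtomRecord, ResidueKey, StructureModel

__all__ = [
    "SyntheticSpec",
    "generate_reference",
    "generate_query",
    "generate_null_protein",
    "generate_null_cohort",
    "generate_toy_structure",
    "TOY_LAYOUTS",
]

_AA_CYCLE = sorted(STANDARD_AMINO_ACIDS)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a synthetic reference database.

    ``within_class_noise`` is the std-dev of the isotropic Gaussian added to
    a class centroid before renormalization; it controls how tightly a
    class clusters in cosine similarity (0 = identical members).
    """

    n_classes: int = 20
    residues_per_class: int = 10
    catalytic_per_class: int = 3
    dimension: int = 64
    within_class_noise: float = 0.1
    n_background_residues: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.catalytic_per_class > self.residues_per_class:
            raise ValueError("catalytic_per_class cannot exceed residues_per_class")
        if self.dimension < 2:
            raise ValueError("dimension must be >= 2")
        if self.within_class_noise < 0:
            raise ValueError("within_class_noise must be >= 0")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def generate_reference(spec: SyntheticSpec) -> ReferenceDatabase:
    """Synthetic reference database with class-structured unit embeddings.

    Class centroids are drawn uniformly on the unit sphere; each member is
    the centroid plus isotropic Gaussian noise, renormalized. The first
    ``catalytic_per_class`` members of each class are flagged catalytic.
    EC numbers are synthetic but well-formed, distinct per class.
    """
    rng = np.random.default_rng(spec.seed)
    residues: list[ReferenceResidue] = []
    classes: dict[str, FunctionClass] = {}
    for c in range(spec.n_classes):
        centroid = _unit(rng.standard_normal(spec.dimension))
        class_id = f"class_{c:03d}"
        classes[class_id] = FunctionClass(
            class_id=class_id,
            ec_number=f"{c % 6 + 1}.{c // 6 + 1}.{c + 1}.{c + 1}",
            reference_structure_id=f"SYN{c:03d}",
            reference_chain="A",
        )
        members = centroid + spec.within_class_noise * rng.standard_normal(
            (spec.residues_per_class, spec.dimension)
        )
        members = _unit(members)
        for m in range(spec.residues_per_class):
            key = ResidueKey(
                structure_id=f"SYN{c:03d}",
                chain_id="A",
                residue_number=m + 1,
                amino_acid=_AA_CYCLE[(c + m) % len(_AA_CYCLE)],
            )
            residues.append(
                ReferenceResidue(
                    key=key,
                    class_id=class_id,
                    is_catalytic=m < spec.catalytic_per_class,
                    embedding=members[m],
                )
            )
    return ReferenceDatabase(residues=residues, classes=classes, dimension=spec.dimension)


def generate_query(
    db: ReferenceDatabase,
    planted_class: str | None,
    noise: float,
    n_background: int,
    seed: int,
    protein_id: str = "QUERY",
) -> tuple[list[EmbeddingRecord], set[ResidueKey]]:
    """A query protein with an optionally planted functional site.

    For each member of ``planted_class`` the query receives one residue with
    embedding ``member + noise``-Gaussian, renormalized, **with the member's
    amino acid** (the planted site is an exact-sequence copy of the
    reference site). ``n_background`` extra residues are fresh isotropic
    unit vectors. Returns the records and the set of planted residue keys
    (empty for ``planted_class=None``, a pure-null query).
    """
    rng = np.random.default_rng(seed)
    records: list[EmbeddingRecord] = []
    planted_keys: set[ResidueKey] = set()
    number = 1
    if planted_class is not None:
        members = [db.residues[i] for i in db.member_indices(planted_class)]
        for member in members:
            vec = _unit(member.embedding + noise * rng.standard_normal(db.dimension))
            key = ResidueKey(protein_id, "A", number, amino_acid=member.key.amino_acid)
            records.append(EmbeddingRecord(key=key, vector=vec))
            planted_keys.add(key)
            number += 1
    for _ in range(n_background):
        vec = _unit(rng.standard_normal(db.dimension))
        key = ResidueKey(
            protein_id, "A", number, amino_acid=_AA_CYCLE[int(rng.integers(len(_AA_CYCLE)))]
        )
        records.append(EmbeddingRecord(key=key, vector=vec))
        number += 1
    return records, planted_keys


def generate_null_protein(
    db: ReferenceDatabase, n_residues: int, seed: int, protein_id: str = "NULL"
) -> BackgroundProtein:
    """A protein of isotropic random unit-vector residues, no annotations."""
    records, _ = generate_query(db, None, 0.0, n_residues, seed, protein_id=protein_id)
    return BackgroundProtein(protein_id=protein_id, records=records)


def generate_null_cohort(
    db: ReferenceDatabase, n_proteins: int, n_residues_each: int, seed: int
) -> list[BackgroundProtein]:
    """A cohort of pure-null proteins for background building and calibration."""
    rng = np.random.default_rng(seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_proteins)
    return [
        generate_null_protein(db, n_residues_each, int(child_seeds[i]), protein_id=f"NULL{i:04d}")
        for i in range(n_proteins)
    ]


TOY_LAYOUTS = ("collinear_gaps", "square_planar", "perturbed_copy", "random_cloud")


def generate_toy_structure(
    layout: str, seed: int = 0, displacement: float = 1.0, structure_id: str | None = None
) -> StructureModel:
    """Deterministic toy coordinate sets with documented pairwise distances.

    ``collinear_gaps``
        three single-atom residues on the x axis at 0, 3 and 9 A: the
        nearest-atom gaps are exactly 3.0 A (residues 1-2) and 6.0 A
        (residues 2-3).
    ``square_planar``
        one residue of four atoms on a unit square in the z=0 plane.
    ``perturbed_copy``
        the 8-atom ``random_cloud`` of the same seed with its first atom
        displaced by exactly ``displacement`` A along +x.
    ``random_cloud``
        one residue of 8 atoms at seeded uniform positions in a 10 A box.
    """
    if layout not in TOY_LAYOUTS:
        raise ValueError(f"unknown toy layout {layout!r}; choose from {TOY_LAYOUTS}")
    sid = structure_id or f"toy_{layout}"

    def _model(res_atom_positions: list[list[tuple[float, float, float]]]) -> StructureModel:
        residues, atoms = [], []
        for i, positions in enumerate(res_atom_positions):
            key = ResidueKey(sid, "A", i + 1, amino_acid="GLY")
            residues.append(key)
            for j, pos in enumerate(positions):
                atoms.append(
                    AtomRecord(
                        parent=key,
                        atom_name=f"C{j}" if len(positions) > 1 else "CA",
                        element="C",
                        position=pos,
                        b_factor_or_plddt=0.0,
                    )
                )
        return StructureModel(sid, residues, atoms)

    if layout == "collinear_gaps":
        return _model([[(0.0, 0.0, 0.0)], [(3.0, 0.0, 0.0)], [(9.0, 0.0, 0.0)]])
    if layout == "square_planar":
        return _model([[(0.0, 0.0, 0.0), (1.0, 0.0, 0.0), (1.0, 1.0, 0.0), (0.0, 1.0, 0.0)]])
    rng = np.random.default_rng(seed)
    cloud = rng.uniform(0.0, 10.0, size=(8, 3))
    if layout == "perturbed_copy":
        cloud = cloud.copy()
        cloud[0, 0] += displacement
    return _model([[tuple(p) for p in cloud]])
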