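"""Structure parsing and geometric primitives.

Reads PDB/mmCIF files (via gemmi), strips heteroatoms, exposes residues with
coordinates and per-residue confidence (pLDDT for predicted models, B-factor
otherwise), and performs the distance-based expansion of catalytic sites into
full active sites.

Conventions
-----------
* Author residue numbering and insertion codes are preserved as written in
  the source file.
* Only the first model of multi-model files is used; for alternate locations
  the highest-occupancy conformer of each atom is kept.
* Predicted models (``is_predicted=True``) carry pLDDT in the B-factor
  column; per-residue pLDDT is the value on the residue's first atom, or the
  mean (with a warning) if atoms disagree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "ResidueKey",
    "AtomRecord",
    "StructureModel",
    "StructureParseError",
    "parse_structure",
    "strip_heteroatoms",
    "expand_active_site",
    "filter_by_plddt",
]

#: The 20 standard amino acids, 3-letter codes.
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed or yields no residues."""


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Unique identifier of a residue within one parsed model.

    ``(structure_id, chain_id, residue_number, insertion_code)`` is unique;
    ``amino_acid`` is the 3-letter code (possibly nonstandard, see
    :attr:`is_standard`).
    """

    structure_id: str
    chain_id: str
    residue_number: int
    insertion_code: str = ""
    amino_acid: str = "UNK"

    @property
    def is_standard(self) -> bool:
        return self.amino_acid in STANDARD_AMINO_ACIDS

    def __str__(self) -> str:  # e.g. 1abc/A/123A:HIS
        ic = self.insertion_code or ""
        return f"{self.structure_id}/{self.chain_id}/{self.residue_number}{ic}:{self.amino_acid}"


@dataclass(frozen=True)
class AtomRecord:
    """One atom with coordinates and the B-factor/pLDDT it carries."""

    parent: ResidueKey
    atom_name: str
    element: str
    position: tuple[float, float, float]
    b_factor_or_plddt: float
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.position)):
            raise ValueError(f"non-finite coordinates on atom {self.atom_name} of {self.parent}")
        if self.b_factor_or_plddt < 0:
            raise ValueError(f"negative B-factor/pLDDT on atom {self.atom_name} of {self.parent}")


@dataclass
class StructureModel:
    """A single-model structure: ordered residues plus their atoms.

    ``hetero_residues`` flags residues parsed from HETATM records or with a
    nonstandard residue name (waters, ligands, modified residues).
    """

    structure_id: str
    residues: list[ResidueKey]
    atoms: list[AtomRecord]
    is_predicted: bool = False
    hetero_residues: set[ResidueKey] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._by_residue: dict[ResidueKey, list[AtomRecord]] = {r: [] for r in self.residues}
        for atom in self.atoms:
            if atom.parent not in self._by_residue:
                raise ValueError(f"atom {atom.atom_name} has unknown parent {atom.parent}")
            self._by_residue[atom.parent].append(atom)

    def residue_atoms(self, key: ResidueKey) -> list[AtomRecord]:
        return self._by_residue[key]

    def residue_plddt(self, key: ResidueKey) -> float:
        """Per-residue pLDDT/B-factor: first atom's value; mean if atoms disagree."""
        atoms = self._by_residue[key]
        if not atoms:
            raise ValueError(f"residue {key} has no atoms")
        values = np.array([a.b_factor_or_plddt for a in atoms])
        if np.allclose(values, values[0], atol=1e-6):
            return float(values[0])
        warnings.warn(
            f"atoms of residue {key} carry unequal B-factor/pLDDT values; using the mean",
            stacklevel=2,
        )
        return float(values.mean())

    @property
    def polymer_residues(self) -> list[ResidueKey]:
        return [r for r in self.residues if r not in self.hetero_residues]

    def __len__(self) -> int:
        return len(self.residues)


def parse_structure(
    path,
    chain_filter: str | None = None,
    *,
    structure_id: str | None = None,
    is_predicted: bool = False,
) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path
        Path to a PDB or mmCIF file (format inferred from the extension).
    chain_filter
        If given, restrict the model to this author chain id.
    structure_id
        Identifier attached to every residue; defaults to the file stem.
    is_predicted
        Mark the model as AlphaFold-style, i.e. B-factors are pLDDT values.

    Raises
    ------
    StructureParseError
        On unreadable/garbled files or when the requested chain is empty.
    """
    path = str(path)
    try:
        st = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse structure file {path!r}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"structure file {path!r} contains no models")
    sid = structure_id if structure_id is not None else st.name.lower() or "structure"

    model = st[0]  # first model only
    residues: list[ResidueKey] = []
    atoms: list[AtomRecord] = []
    hetero: set[ResidueKey] = set()
    for chain in model:
        if chain_filter is not None and chain.name != chain_filter:
            continue
        for res in chain:
            icode = res.seqid.icode.strip()
            key = ResidueKey(sid, chain.name, res.seqid.num, icode, res.name)
            is_het = res.het_flag == "H" or res.name not in STANDARD_AMINO_ACIDS
            residues.append(key)
            if is_het:
                hetero.add(key)
            for atom in _highest_occupancy_atoms(res):
                atoms.append(
                    AtomRecord(
                        parent=key,
                        atom_name=atom.name,
                        element=atom.element.name,
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        b_factor_or_plddt=float(atom.b_iso),
                        is_hetero=is_het,
                    )
                )
    if not residues:
        where = f"chain {chain_filter!r} of " if chain_filter else ""
        raise StructureParseError(f"{where}{path!r} yields an empty model")
    return StructureModel(sid, residues, atoms, is_predicted=is_predicted, hetero_residues=hetero)


def _highest_occupancy_atoms(res: gemmi.Residue):
    """Resolve alternate locations: keep the highest-occupancy conformer per atom name."""
    has_alt = any(a.altloc not in ("", "\x00") for a in res)
    if not has_alt:
        yield from res
        return
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for a in res:
        if a.name not in best:
            best[a.name] = a
            order.append(a.name)
        elif a.occ > best[a.name].occ:
            best[a.name] = a
    for name in order:
        yield best[name]


#: Modified residues that a config switch can map back to their parent amino acid.
_MODIFIED_TO_STANDARD = {"MSE": "MET"}


def strip_heteroatoms(model: StructureModel, *, map_modified: bool = False) -> StructureModel:
    """Return a copy containing only standard polymer amino-acid residues.

    Waters, ligands, ions and modified residues are removed. With
    ``map_modified=True`` selenomethionine (MSE) is renamed to MET and kept
    instead of removed. The input model is not modified; the operation is
    idempotent.
    """
    rename: dict[ResidueKey, ResidueKey] = {}
    if map_modified:
        for key in model.residues:
            if key.amino_acid in _MODIFIED_TO_STANDARD:
                rename[key] = replace(key, amino_acid=_MODIFIED_TO_STANDARD[key.amino_acid])

    keep: list[ResidueKey] = []
    for key in model.residues:
        if key in rename:
            keep.append(key)
        elif key not in model.hetero_residues and key.is_standard:
            keep.append(key)
    if not keep:
        raise StructureParseError(
            f"model {model.structure_id!r} has no polymer residues after heteroatom removal"
        )
    kept_keys = set(keep)
    new_residues = [rename.get(k, k) for k in keep]
    new_atoms = [
        replace(a, parent=rename.get(a.parent, a.parent), is_hetero=False)
        for a in model.atoms
        if a.parent in kept_keys
    ]
    return StructureModel(
        model.structure_id,
        new_residues,
        new_atoms,
        is_predicted=model.is_predicted,
        hetero_residues=set(),
    )


def expand_active_site(
    model: StructureModel,
    catalytic: set[ResidueKey],
    cutoff: float = 3.5,
) -> set[ResidueKey]:
    """Expand a catalytic-residue set to the full active site.

    A residue joins the site if **any** of its atoms lies within ``cutoff``
    angstroms of **any** atom of a catalytic residue; the catalytic residues
    themselves are always included. The default 3.5 A captures residues close
    enough for direct interactions such as hydrogen bonds.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    model_residues = set(model.residues)
    for key in catalytic:
        if key not in model_residues:
            raise KeyError(f"catalytic residue {key} not present in model {model.structure_id!r}")

    cat_coords = np.array(
        [a.position for key in sorted(catalytic) for a in model.residue_atoms(key)]
    )
    result = set(catalytic)
    if cat_coords.size == 0:
        return result
    tree = cKDTree(cat_coords)
    for key in model.residues:
        if key in result:
            continue
        atoms = model.residue_atoms(key)
        if not atoms:
            continue
        coords = np.array([a.position for a in atoms])
        dists, _ = tree.query(coords, k=1)
        if np.min(dists) <= cutoff:
            result.add(key)
    return result


def filter_by_plddt(model: StructureModel, min_plddt: float = 70.0) -> list[ResidueKey]:
    """Keep residues with per-residue pLDDT >= ``min_plddt`` (boundary inclusive).

    For experimental structures (``is_predicted=False``) the B-factor column
    is not a confidence score, so all residues are returned. Returns residues
    in model order; an empty result is allowed and flagged downstream.
    """
    if not model.is_predicted:
        return list(model.residues)
    return [r for r in model.residues if model.residue_plddt(r) >= min_plddt]
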