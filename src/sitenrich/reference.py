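"""Reference database of embedded functional-site residues.

A reference database holds, for each function class (one curated catalytic
mechanism, e.g. one Catalytic Site Atlas entry), the catalytic residues of
its reference structure plus all residues within a distance cutoff of them,
each with a fixed-dimension embedding. Classes carry an EC number for
evaluation; several classes may share one EC number (catalytic mechanisms
are more specific than EC, e.g. beta-lactamase subclasses all map to
3.5.2.6).

Serialization: an HDF5 embedding store for the residues plus a JSON sidecar
for class metadata, wrapped in one directory.
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .embeddings import (
    Embedder,
    EmbeddingRecord,
    EnvironmentSpec,
    embed_residues,
    read_store,
    write_store,
)
from .structure_io import (
    ResidueKey,
    StructureParseError,
    expand_active_site,
    parse_structure,
    strip_heteroatoms,
)

__all__ = [
    "EC_PATTERN",
    "FunctionClass",
    "ReferenceResidue",
    "ReferenceDatabase",
    "build_reference_db",
    "save_db",
    "load_db",
    "class_to_ec",
    "db_checksum",
]

_DB_VERSION = 1

#: Four-field EC grammar; trailing fields may be dashes (partial numbers).
EC_PATTERN = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(n?\d+|-)$")


@dataclass(frozen=True)
class FunctionClass:
    """One function class: a catalytic mechanism with its reference structure."""

    class_id: str
    ec_number: str
    reference_structure_id: str
    reference_chain: str

    def __post_init__(self) -> None:
        if not EC_PATTERN.match(self.ec_number):
            raise ValueError(
                f"class {self.class_id!r}: EC number {self.ec_number!r} "
                "does not match the a.b.c.d grammar"
            )


@dataclass
class ReferenceResidue:
    """One embedded residue of a reference functional site."""

    key: ResidueKey
    class_id: str
    is_catalytic: bool
    embedding: np.ndarray

    def __post_init__(self) -> None:
        self.embedding = np.asarray(self.embedding, dtype=np.float64)


@dataclass
class ReferenceDatabase:
    """Ordered reference residues plus class metadata.

    Residue order is significant: it defines the deterministic tie-break used
    when ranking, and is preserved by save/load.
    """

    residues: list[ReferenceResidue]
    classes: dict[str, FunctionClass]
    dimension: int
    _members: dict[str, list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._members = {cid: [] for cid in self.classes}
        seen: dict[str, set[ResidueKey]] = {cid: set() for cid in self.classes}
        for i, res in enumerate(self.residues):
            if res.class_id not in self.classes:
                raise ValueError(f"residue {res.key} references unknown class {res.class_id!r}")
            if res.embedding.shape != (self.dimension,):
                raise ValueError(
                    f"residue {res.key} has dimension {res.embedding.shape[0]}, "
                    f"database dimension is {self.dimension}"
                )
            if res.key in seen[res.class_id]:
                raise ValueError(f"duplicate residue {res.key} within class {res.class_id!r}")
            seen[res.class_id].add(res.key)
            self._members[res.class_id].append(i)
        for cid, idx in self._members.items():
            if not any(self.residues[i].is_catalytic for i in idx):
                raise ValueError(f"class {cid!r} has no catalytic residue")

    def member_indices(self, class_id: str) -> list[int]:
        """Indices (database order) of residues belonging to ``class_id``."""
        if class_id not in self._members:
            raise KeyError(f"unknown class {class_id!r}")
        return list(self._members[class_id])

    def catalytic_residues(self, class_id: str) -> list[ReferenceResidue]:
        return [self.residues[i] for i in self.member_indices(class_id) if self.residues[i].is_catalytic]

    @property
    def class_ids(self) -> list[str]:
        return list(self.classes)

    def embedding_matrix(self) -> np.ndarray:
        return np.array([r.embedding for r in self.residues])

    def __len__(self) -> int:
        return len(self.residues)


ANNOTATION_COLUMNS = [
    "class_id",
    "ec_number",
    "structure_id",
    "chain",
    "residue_number",
    "insertion_code",
    "amino_acid",
    "is_catalytic",
]


def build_reference_db(
    annotation_table: pd.DataFrame | str | Path,
    structure_dir: str | Path,
    embedder: Embedder,
    env: EnvironmentSpec | None = None,
    cutoff: float = 3.5,
) -> ReferenceDatabase:
    """Build a reference database from a catalytic-residue annotation table.

    The table lists the catalytic residues of each class (CSV columns
    ``class_id, ec_number, structure_id, chain, residue_number,
    insertion_code, amino_acid, is_catalytic``). For each class the reference
    chain is parsed, heteroatoms are stripped, the catalytic set is expanded
    to every residue with an atom within ``cutoff`` angstroms, and all site
    residues are embedded. Classes whose catalytic residues cannot be
    resolved in the structure are skipped with a warning.
    """
    env = env or EnvironmentSpec()
    if not isinstance(annotation_table, pd.DataFrame):
        annotation_table = pd.read_csv(annotation_table, dtype=str, keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(annotation_table.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    structure_dir = Path(structure_dir)

    residues: list[ReferenceResidue] = []
    classes: dict[str, FunctionClass] = {}
    for class_id, rows in annotation_table.groupby("class_id", sort=False):
        try:
            fc, class_residues = _build_class(rows, structure_dir, embedder, env, cutoff)
        except (StructureParseError, KeyError, FileNotFoundError, ValueError) as exc:
            warnings.warn(f"skipping class {class_id!r}: {exc}", stacklevel=2)
            continue
        classes[fc.class_id] = fc
        residues.extend(class_residues)
    if not classes:
        raise RuntimeError("no reference classes could be built from the annotation table")
    return ReferenceDatabase(residues=residues, classes=classes, dimension=embedder.dimension)


def _find_structure_file(structure_dir: Path, structure_id: str) -> Path:
    for ext in (".pdb", ".cif", ".ent", ".pdb.gz", ".cif.gz"):
        candidate = structure_dir / f"{structure_id}{ext}"
        if candidate.exists():
            return candidate
    raise FileNotFoundError(f"no structure file for {structure_id!r} in {structure_dir}")


def _build_class(rows: pd.DataFrame, structure_dir: Path, embedder, env, cutoff):
    first = rows.iloc[0]
    fc = FunctionClass(
        class_id=first["class_id"],
        ec_number=first["ec_number"],
        reference_structure_id=first["structure_id"],
        reference_chain=first["chain"],
    )
    path = _find_structure_file(structure_dir, fc.reference_structure_id)
    model = parse_structure(
        path, chain_filter=fc.reference_chain, structure_id=fc.reference_structure_id
    )
    model = strip_heteroatoms(model)
    by_id = {
        (r.chain_id, r.residue_number, r.insertion_code): r for r in model.residues
    }
    catalytic: set[ResidueKey] = set()
    for _, row in rows.iterrows():
        if str(row["is_catalytic"]).strip().lower() not in ("1", "true", "yes"):
            continue
        loc = (row["chain"], int(row["residue_number"]), row["insertion_code"].strip())
        if loc not in by_id:
            raise KeyError(
                f"catalytic residue {row['chain']}/{row['residue_number']} "
                f"not found in {fc.reference_structure_id!r}"
            )
        key = by_id[loc]
        if row["amino_acid"] and key.amino_acid != row["amino_acid"]:
            raise ValueError(
                f"catalytic residue {key} has type {key.amino_acid}, "
                f"annotation says {row['amino_acid']}"
            )
        catalytic.add(key)
    if not catalytic:
        raise ValueError("class has no catalytic rows")
    site = expand_active_site(model, catalytic, cutoff=cutoff)
    ordered = [r for r in model.residues if r in site]  # stable structure order
    records = embed_residues(model, ordered, embedder, env)
    return fc, [
        ReferenceResidue(
            key=rec.key,
            class_id=fc.class_id,
            is_catalytic=rec.key in catalytic,
            embedding=rec.vector,
        )
        for rec in records
    ]


def save_db(db: ReferenceDatabase, path: str | Path) -> None:
    """Serialize a database to ``path`` (a directory) losslessly."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    records = [EmbeddingRecord(key=r.key, vector=r.embedding) for r in db.residues]
    write_store(records, path / "residues.h5")
    meta = {
        "version": _DB_VERSION,
        "dimension": db.dimension,
        "classes": [
            {
                "class_id": c.class_id,
                "ec_number": c.ec_number,
                "reference_structure_id": c.reference_structure_id,
                "reference_chain": c.reference_chain,
            }
            for c in db.classes.values()
        ],
        "residue_class_ids": [r.class_id for r in db.residues],
        "is_catalytic": [bool(r.is_catalytic) for r in db.residues],
    }
    (path / "classes.json").write_text(json.dumps(meta, indent=1))


def load_db(path: str | Path) -> ReferenceDatabase:
    """Load a database saved by :func:`save_db`; order-preserving."""
    path = Path(path)
    meta = json.loads((path / "classes.json").read_text())
    if meta.get("version") != _DB_VERSION:
        raise ValueError(
            f"reference database {path}: version {meta.get('version')} "
            f"not supported (expected {_DB_VERSION})"
        )
    records = read_store(path / "residues.h5")
    class_ids = meta["residue_class_ids"]
    catalytic = meta["is_catalytic"]
    if not (len(records) == len(class_ids) == len(catalytic)):
        raise ValueError(f"reference database {path} is truncated or inconsistent")
    classes = {
        c["class_id"]: FunctionClass(
            class_id=c["class_id"],
            ec_number=c["ec_number"],
            reference_structure_id=c["reference_structure_id"],
            reference_chain=c["reference_chain"],
        )
        for c in meta["classes"]
    }
    residues = [
        ReferenceResidue(key=rec.key, class_id=cid, is_catalytic=cat, embedding=rec.vector)
        for rec, cid, cat in zip(records, class_ids, catalytic)
    ]
    return ReferenceDatabase(residues=residues, classes=classes, dimension=int(meta["dimension"]))


def class_to_ec(db: ReferenceDatabase, class_id: str) -> str:
    """EC number stored for a class (verbatim, including partial dashes)."""
    if class_id not in db.classes:
        raise KeyError(f"unknown class {class_id!r}")
    return db.classes[class_id].ec_number


def db_checksum(db: ReferenceDatabase) -> str:
    """Stable checksum of residue order, class labels and embeddings.

    Used to version background distributions against the database they were
    computed from.
    """
    h = hashlib.sha256()
    for r in db.residues:
        h.update(str(r.key).encode())
        h.update(r.class_id.encode())
        h.update(b"1" if r.is_catalytic else b"0")
        h.update(np.ascontiguousarray(r.embedding).tobytes())
    for c in db.classes.values():
        h.update(f"{c.class_id}|{c.ec_number}".encode())
    return h.hexdigest()
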