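"""Residue embedding contract, deterministic mock embedder, and embedding stores.

The annotator is agnostic to the local-structure embedder: any model that
maps a residue's atomic neighborhood to a fixed-dimension vector can be
plugged in through :class:`Embedder`. Pretrained embedders of local protein
environments (e.g. the 512-dimensional COLLAPSE representation, or per-residue
protein-language-model embeddings) are consumed through this adapter; they
are never re-implemented here. For tests and synthetic pipelines a
deterministic hash-based mock embedder is provided.

Stores
------
Embeddings travel in two formats:

* an HDF5 store (``.h5``) — the primary single-file binary table, with the
  dimension recorded as a root attribute and validated on write;
* a plain TSV interchange format — key columns plus a comma-separated vector
  column, round-tripping float64 values exactly via 17-significant-digit
  decimal representation.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import h5py
import numpy as np
import pandas as pd

from .structure_io import ResidueKey, StructureModel

__all__ = [
    "EnvironmentSpec",
    "EmbeddingRecord",
    "Embedder",
    "MockEmbedder",
    "mock_embed",
    "embed_residues",
    "write_store",
    "read_store",
    "write_tsv",
    "read_tsv",
]

_STORE_VERSION = 1


@dataclass(frozen=True)
class EnvironmentSpec:
    """Definition of the local environment an embedder sees.

    ``radius`` is the sphere (in angstroms) around the residue's functional
    center; ``center_definition`` names the per-amino-acid rule used to place
    that center and is treated as an opaque identifier passed through to the
    embedder.
    """

    radius: float = 10.0
    center_definition: str = "functional_center"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"environment radius must be positive, got {self.radius}")


@dataclass
class EmbeddingRecord:
    """One residue's embedding vector, optionally with its pLDDT."""

    key: ResidueKey
    vector: np.ndarray
    plddt: float | None = None

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if self.vector.ndim != 1:
            raise ValueError("embedding vector must be 1-D")
        if not np.linalg.norm(self.vector) > 0:
            raise ValueError(f"zero-norm embedding rejected for residue {self.key}")


@runtime_checkable
class Embedder(Protocol):
    """Adapter contract for per-residue local-structure embedders."""

    name: str
    dimension: int
    deterministic: bool

    def embed(
        self, model: StructureModel, key: ResidueKey, env: EnvironmentSpec
    ) -> np.ndarray: ...


def mock_embed(key: ResidueKey, coords_digest: bytes, dimension: int, seed: int) -> np.ndarray:
    """Deterministic unit vector derived from (residue key, coordinates, seed).

    The residue identity and a digest of its coordinates are hashed into a
    PRNG seed; the vector is a normalized Gaussian draw. Identical inputs give
    bit-identical output, and distinct residues collide only if SHA-256 does.
    """
    if dimension < 2:
        raise ValueError(f"mock embedding dimension must be >= 2, got {dimension}")
    payload = "|".join(
        [
            key.structure_id,
            key.chain_id,
            str(key.residue_number),
            key.insertion_code,
            key.amino_acid,
            str(seed),
            str(dimension),
        ]
    ).encode() + coords_digest
    digest = hashlib.sha256(payload).digest()
    rng = np.random.Generator(np.random.PCG64(int.from_bytes(digest[:8], "little")))
    vec = rng.standard_normal(dimension)
    return vec / np.linalg.norm(vec)


@dataclass
class MockEmbedder:
    """Hash-based stand-in embedder for tests and synthetic pipelines.

    Produces unit-norm vectors that are deterministic in the residue
    identity, its atom coordinates and the embedder seed. Unrelated residues
    receive near-orthogonal vectors in high dimension, mimicking the low
    background similarity of real local-structure embeddings without any
    trained weights.
    """

    dimension: int = 32
    seed: int = 0
    name: str = "mock"
    deterministic: bool = field(default=True, init=False)

    def embed(self, model: StructureModel, key: ResidueKey, env: EnvironmentSpec) -> np.ndarray:
        coords = np.array([a.position for a in model.residue_atoms(key)], dtype=np.float64)
        digest = hashlib.sha256(np.round(coords, 3).tobytes()).digest()
        return mock_embed(key, digest, self.dimension, self.seed)


def embed_residues(
    model: StructureModel,
    residues: Sequence[ResidueKey],
    embedder: Embedder,
    env: EnvironmentSpec | None = None,
) -> list[EmbeddingRecord]:
    """Embed the requested residues, in input order.

    A residue on which the embedder fails is skipped with a warning (its key
    is reported in the warning message); if every residue fails, an error is
    raised instead.
    """
    env = env or EnvironmentSpec()
    model_residues = set(model.residues)
    records: list[EmbeddingRecord] = []
    failed: list[ResidueKey] = []
    for key in residues:
        if key not in model_residues:
            raise KeyError(f"residue {key} not in model {model.structure_id!r}")
        try:
            vec = np.asarray(embedder.embed(model, key, env), dtype=np.float64)
            if vec.shape != (embedder.dimension,):
                raise ValueError(
                    f"embedder returned shape {vec.shape}, expected ({embedder.dimension},)"
                )
            plddt = model.residue_plddt(key) if model.is_predicted else None
            records.append(EmbeddingRecord(key=key, vector=vec, plddt=plddt))
        except (ValueError, ArithmeticError) as exc:
            failed.append(key)
            warnings.warn(f"embedding failed for residue {key}: {exc}", stacklevel=2)
    if residues and not records:
        raise RuntimeError(f"embedding failed for all {len(failed)} requested residues")
    return records


# ---------------------------------------------------------------------------
# HDF5 store
# ---------------------------------------------------------------------------

def write_store(records: Sequence[EmbeddingRecord], path) -> None:
    """Write records to a single-file HDF5 store (order-preserving)."""
    dims = {r.vector.shape[0] for r in records}
    if len(dims) > 1:
        raise ValueError(f"mixed embedding dimensions in one store: {sorted(dims)}")
    dim = dims.pop() if dims else 0
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as f:
        f.attrs["version"] = _STORE_VERSION
        f.attrs["dimension"] = dim
        n = len(records)
        f.create_dataset("structure_id", data=[r.key.structure_id for r in records], dtype=str_dt)
        f.create_dataset("chain_id", data=[r.key.chain_id for r in records], dtype=str_dt)
        f.create_dataset(
            "residue_number", data=np.array([r.key.residue_number for r in records], dtype=np.int64)
        )
        f.create_dataset(
            "insertion_code", data=[r.key.insertion_code for r in records], dtype=str_dt
        )
        f.create_dataset("amino_acid", data=[r.key.amino_acid for r in records], dtype=str_dt)
        vectors = np.array([r.vector for r in records]) if n else np.empty((0, dim))
        f.create_dataset("vectors", data=vectors, dtype=np.float64)
        plddt = np.array(
            [np.nan if r.plddt is None else r.plddt for r in records], dtype=np.float64
        )
        f.create_dataset("plddt", data=plddt)


def read_store(path) -> list[EmbeddingRecord]:
    """Read an HDF5 embedding store; inverse of :func:`write_store`."""
    try:
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("version", -1))
            if version != _STORE_VERSION:
                raise ValueError(
                    f"embedding store {path!s}: unsupported version {version} "
                    f"(expected {_STORE_VERSION})"
                )
            sid = [s.decode() for s in f["structure_id"][...]]
            chain = [s.decode() for s in f["chain_id"][...]]
            num = f["residue_number"][...]
            icode = [s.decode() for s in f["insertion_code"][...]]
            aa = [s.decode() for s in f["amino_acid"][...]]
            vectors = f["vectors"][...]
            plddt = f["plddt"][...]
    except OSError as exc:
        raise ValueError(f"corrupted or unreadable embedding store {path!s}: {exc}") from exc
    records = []
    for i in range(len(sid)):
        records.append(
            EmbeddingRecord(
                key=ResidueKey(sid[i], chain[i], int(num[i]), icode[i], aa[i]),
                vector=vectors[i],
                plddt=None if np.isnan(plddt[i]) else float(plddt[i]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

_TSV_COLUMNS = [
    "structure_id",
    "chain_id",
    "residue_number",
    "insertion_code",
    "amino_acid",
    "plddt",
    "vector",
]


def write_tsv(records: Sequence[EmbeddingRecord], path) -> None:
    """Write the plain-text interchange format (lossless for float64)."""
    rows = []
    for r in records:
        rows.append(
            {
                "structure_id": r.key.structure_id,
                "chain_id": r.key.chain_id,
                "residue_number": r.key.residue_number,
                "insertion_code": r.key.insertion_code,
                "amino_acid": r.key.amino_acid,
                "plddt": "" if r.plddt is None else repr(float(r.plddt)),
                "vector": ",".join(np.format_float_scientific(x, unique=True) for x in r.vector),
            }
        )
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tsv(path) -> list[EmbeddingRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"embedding TSV {path!s} missing columns: {sorted(missing)}")
    records = []
    dims = set()
    for _, row in df.iterrows():
        vec = np.array([float(x) for x in row["vector"].split(",")])
        dims.add(vec.shape[0])
        if len(dims) > 1:
            raise ValueError(f"mixed embedding dimensions in TSV {path!s}")
        records.append(
            EmbeddingRecord(
                key=ResidueKey(
                    row["structure_id"],
                    row["chain_id"],
                    int(row["residue_number"]),
                    row["insertion_code"],
                    row["amino_acid"],
                ),
                vector=vec,
                plddt=float(row["plddt"]) if row["plddt"] != "" else None,
            )
        )
    return records
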