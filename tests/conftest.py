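"""Shared fixtures: minimal hand-written PDB files and synthetic databases."""

from __future__ import annotations

import numpy as np
import pytest

from sitenrich.embeddings import MockEmbedder
from sitenrich.significance import build_background
from sitenrich.synthetic import SyntheticSpec, generate_null_cohort, generate_reference


def pdb_atom_line(
    serial: int,
    name: str,
    res_name: str,
    chain: str,
    res_num: int,
    x: float,
    y: float,
    z: float,
    b: float = 20.0,
    element: str = "C",
    record: str = "ATOM",
    icode: str = " ",
    occ: float = 1.0,
    altloc: str = " ",
) -> str:
    return (
        f"{record:<6}{serial:>5} {name:<4}{altloc}{res_name:<3} {chain}{res_num:>4}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2}"
    )


def write_pdb(path, lines: list[str]) -> None:
    path.write_text("\n".join(lines + ["END", ""]))


@pytest.fixture
def two_residue_pdb(tmp_path):
    """Two alanines with stated coordinates."""
    path = tmp_path / "two.pdb"
    write_pdb(
        path,
        [
            pdb_atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, element="N"),
            pdb_atom_line(2, "CA", "ALA", "A", 1, 1.458, 0.0, 0.0),
            pdb_atom_line(3, "N", "ALA", "A", 2, 3.0, 1.0, 0.0, element="N"),
            pdb_atom_line(4, "CA", "ALA", "A", 2, 4.4, 1.2, 0.1),
        ],
    )
    return path


@pytest.fixture
def predicted_pdb(tmp_path):
    """AlphaFold-style file: constant per-residue pLDDT in the B-factor column."""
    path = tmp_path / "af.pdb"
    write_pdb(
        path,
        [
            pdb_atom_line(1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, b=91.2, element="N"),
            pdb_atom_line(2, "CA", "GLY", "A", 1, 1.4, 0.0, 0.0, b=91.2),
            pdb_atom_line(3, "N", "SER", "A", 2, 3.0, 0.0, 0.0, b=45.0, element="N"),
            pdb_atom_line(4, "CA", "SER", "A", 2, 4.4, 0.0, 0.0, b=45.0),
        ],
    )
    return path


@pytest.fixture
def hetero_pdb(tmp_path):
    """Ten glycines in a row, three waters, one zinc and one MSE."""
    lines = []
    serial = 1
    for i in range(10):
        lines.append(pdb_atom_line(serial, "CA", "GLY", "A", i + 1, 4.0 * i, 0.0, 0.0))
        serial += 1
    lines.append(
        pdb_atom_line(serial, "CA", "MSE", "A", 11, 44.0, 0.0, 0.0, record="HETATM")
    )
    serial += 1
    for j in range(3):
        lines.append(
            pdb_atom_line(
                serial, "O", "HOH", "A", 101 + j, 50.0 + j, 5.0, 0.0,
                element="O", record="HETATM",
            )
        )
        serial += 1
    lines.append(
        pdb_atom_line(serial, "ZN", "ZN", "A", 201, 60.0, 0.0, 0.0, element="ZN", record="HETATM")
    )
    path = tmp_path / "hetero.pdb"
    write_pdb(path, lines)
    return path


@pytest.fixture(scope="session")
def small_db():
    """Synthetic reference database: 5 classes, d=32, tight clusters."""
    return generate_reference(
        SyntheticSpec(n_classes=5, residues_per_class=6, catalytic_per_class=2,
                      dimension=32, within_class_noise=0.05, seed=42)
    )


@pytest.fixture(scope="session")
def small_backgrounds(small_db):
    cohort = generate_null_cohort(small_db, 60, 20, seed=43)
    return build_background(cohort, small_db)


@pytest.fixture(scope="session")
def std_db():
    """Default study conditions: 20 classes, 10 residues each, d=64.

    Pipeline-level power tests need this scale; with very few, very tight
    classes a null query ranks some class's whole membership on top and the
    null ES saturates near 1 (the known correlation weakness of the K-S
    statistic that the empirical background corrects).
    """
    return generate_reference(SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def std_backgrounds(std_db):
    cohort = generate_null_cohort(std_db, 200, 30, seed=77)
    return build_background(cohort, std_db)


@pytest.fixture
def mock_embedder():
    return MockEmbedder(dimension=16, seed=0)


def brute_force_es(similarities, member_mask, weight_exponent=1.0):
    """Independent running-sum enumeration of the weighted K-S statistic.

    Plain Python loop, no shared code with the implementation under test.
    """
    n = len(similarities)
    n_class = sum(member_mask)
    n_r = sum(abs(similarities[i]) ** weight_exponent for i in range(n) if member_mask[i])
    s = 0.0
    best = 0.0
    best_pos = 0
    trace = []
    for i in range(n):
        if member_mask[i]:
            s += abs(similarities[i]) ** weight_exponent / n_r
        else:
            s -= 1.0 / (n - n_class)
        trace.append(s)
        if abs(s) > abs(best):  # strict: keep the first position of the extremum
            best = s
            best_pos = i + 1
    return best, best_pos, trace


def make_ranked_db(similarities, class_labels, dimension=4):
    """Build a (RankedList, ReferenceDatabase) pair from descending sims + labels."""
    from sitenrich.enrichment import RankedList
    from sitenrich.reference import FunctionClass, ReferenceDatabase, ReferenceResidue
    from sitenrich.structure_io import ResidueKey

    similarities = np.asarray(similarities, dtype=float)
    order = np.argsort(-similarities, kind="stable")
    unique = sorted(set(class_labels))
    classes = {
        cid: FunctionClass(cid, f"{k + 1}.1.1.{k + 1}", f"ref_{cid}", "A")
        for k, cid in enumerate(unique)
    }
    rng = np.random.default_rng(0)
    residues = [
        ReferenceResidue(
            ResidueKey(f"s{i}", "A", i + 1, amino_acid="GLY"),
            class_labels[i],
            True,
            rng.standard_normal(dimension),
        )
        for i in range(len(class_labels))
    ]
    db = ReferenceDatabase(residues, classes, dimension)
    ranked = RankedList(
        ref_indices=order,
        similarities=similarities[order],
        best_query=[ResidueKey("q", "A", i + 1) for i in order],
    )
    return ranked, db
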