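"""Structure parsing, heteroatom stripping, site expansion, pLDDT filtering."""

import numpy as np
import pytest

from sitenrich.structure_io import (
    ResidueKey,
    StructureParseError,
    expand_active_site,
    filter_by_plddt,
    parse_structure,
    strip_heteroatoms,
)
from sitenrich.synthetic import generate_toy_structure

from conftest import pdb_atom_line, write_pdb


class TestParse:
    def test_round_trips_residues_and_coordinates(self, two_residue_pdb):
        model = parse_structure(two_residue_pdb, structure_id="two")
        assert len(model.residues) == 2
        assert [r.residue_number for r in model.residues] == [1, 2]
        assert all(r.amino_acid == "ALA" for r in model.residues)
        ca = [a for a in model.atoms if a.atom_name == "CA"]
        np.testing.assert_allclose(ca[0].position, (1.458, 0.0, 0.0), atol=1e-3)
        np.testing.assert_allclose(ca[1].position, (4.4, 1.2, 0.1), atol=1e-3)

    def test_plddt_column_passes_through(self, predicted_pdb):
        model = parse_structure(predicted_pdb, is_predicted=True)
        values = [model.residue_plddt(r) for r in model.residues]
        assert values == pytest.approx([91.2, 45.0], abs=1e-4)

    def test_hetero_records_flagged(self, hetero_pdb):
        # oracle: independent scan of HETATM records in the fixture text
        n_het_lines = sum(
            1 for line in hetero_pdb.read_text().splitlines() if line.startswith("HETATM")
        )
        model = parse_structure(hetero_pdb)
        assert len(model.hetero_residues) == n_het_lines  # one atom per hetero residue here
        assert len(model.residues) == 10 + n_het_lines

    def test_chain_filter_and_empty_chain_error(self, two_residue_pdb):
        model = parse_structure(two_residue_pdb, chain_filter="A")
        assert len(model) == 2
        with pytest.raises(StructureParseError, match="empty"):
            parse_structure(two_residue_pdb, chain_filter="B")

    def test_garbled_file_raises(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("data_x\n_loop garbage [ ]]\n\x00\x01")
        with pytest.raises(StructureParseError):
            parse_structure(bad)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        write_pdb(
            path,
            [
                pdb_atom_line(1, "CA", "GLY", "A", 1, 0.0, 0.0, 0.0, occ=0.4, altloc="A"),
                pdb_atom_line(2, "CA", "GLY", "A", 1, 9.9, 0.0, 0.0, occ=0.6, altloc="B"),
                pdb_atom_line(3, "N", "GLY", "A", 1, 1.0, 0.0, 0.0, element="N"),
            ],
        )
        model = parse_structure(path)
        ca = [a for a in model.atoms if a.atom_name == "CA"]
        assert len(ca) == 1
        assert ca[0].position[0] == pytest.approx(9.9, abs=1e-3)


class TestStripHeteroatoms:
    def test_removes_waters_ions_and_modified(self, hetero_pdb):
        model = parse_structure(hetero_pdb)
        stripped = strip_heteroatoms(model)
        assert len(stripped.residues) == 10
        assert not stripped.hetero_residues
        assert len(model.residues) == 15  # input unmodified

    def test_identity_on_clean_model_and_idempotent(self, two_residue_pdb):
        model = parse_structure(two_residue_pdb)
        once = strip_heteroatoms(model)
        twice = strip_heteroatoms(once)
        assert once.residues == model.residues == twice.residues
        assert [a.position for a in twice.atoms] == [a.position for a in model.atoms]

    def test_mse_mapped_to_met_when_requested(self, hetero_pdb):
        model = parse_structure(hetero_pdb)
        kept = strip_heteroatoms(model, map_modified=True)
        assert len(kept.residues) == 11
        assert kept.residues[-1].amino_acid == "MET"

    def test_all_hetero_model_raises(self, tmp_path):
        path = tmp_path / "only_water.pdb"
        write_pdb(
            path,
            [pdb_atom_line(1, "O", "HOH", "A", 1, 0, 0, 0, element="O", record="HETATM")],
        )
        with pytest.raises(StructureParseError, match="no polymer"):
            strip_heteroatoms(parse_structure(path))


def brute_force_expand(model, catalytic, cutoff):
    """O(n^2) all-atom-pair distance scan."""
    result = set(catalytic)
    cat_atoms = [a for key in catalytic for a in model.residue_atoms(key)]
    for key in model.residues:
        for a in model.residue_atoms(key):
            for c in cat_atoms:
                d = np.linalg.norm(np.array(a.position) - np.array(c.position))
                if d <= cutoff:
                    result.add(key)
    return result


class TestExpandActiveSite:
    def test_isolated_catalytic_residue(self):
        model = generate_toy_structure("collinear_gaps")
        last = model.residues[2]  # 6 A from its nearest neighbor
        assert expand_active_site(model, {last}, cutoff=3.5) == {last}

    def test_collinear_gaps_include_near_exclude_far(self):
        model = generate_toy_structure("collinear_gaps")
        r1, r2, r3 = model.residues
        site = expand_active_site(model, {r2}, cutoff=3.5)
        assert site == {r1, r2}  # 3.0 A neighbor in, 6.0 A neighbor out

    def test_boundary_cutoff_inclusive(self):
        model = generate_toy_structure("collinear_gaps")
        r1, r2, _ = model.residues
        assert expand_active_site(model, {r2}, cutoff=3.0) == {r1, r2}
        assert expand_active_site(model, {r2}, cutoff=2.999) == {r2}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        from sitenrich.structure_io import AtomRecord, StructureModel

        residues, atoms = [], []
        for i in range(12):
            key = ResidueKey("cloud", "A", i + 1, amino_acid="GLY")
            residues.append(key)
            for j in range(3):
                atoms.append(
                    AtomRecord(key, f"C{j}", "C", tuple(rng.uniform(0, 15, 3)), 0.0)
                )
        model = StructureModel("cloud", residues, atoms)
        catalytic = {residues[0], residues[5]}
        for cutoff in (2.0, 3.5, 6.0):
            assert expand_active_site(model, catalytic, cutoff) == brute_force_expand(
                model, catalytic, cutoff
            )

    def test_monotone_in_cutoff(self):
        model = generate_toy_structure("collinear_gaps")
        mid = {model.residues[1]}
        sites = [expand_active_site(model, mid, c) for c in (1.0, 3.0, 3.5, 6.0, 10.0)]
        for smaller, larger in zip(sites, sites[1:]):
            assert smaller <= larger

    def test_unknown_catalytic_residue_raises(self):
        model = generate_toy_structure("collinear_gaps")
        ghost = ResidueKey("toy_collinear_gaps", "A", 99, amino_acid="GLY")
        with pytest.raises(KeyError, match="99"):
            expand_active_site(model, {ghost})

    def test_nonpositive_cutoff_rejected(self):
        model = generate_toy_structure("collinear_gaps")
        with pytest.raises(ValueError):
            expand_active_site(model, {model.residues[0]}, cutoff=0.0)


class TestPlddtFilter:
    def _model(self, values):
        from sitenrich.structure_io import AtomRecord, StructureModel

        residues, atoms = [], []
        for i, v in enumerate(values):
            key = ResidueKey("m", "A", i + 1, amino_acid="GLY")
            residues.append(key)
            atoms.append(AtomRecord(key, "CA", "C", (float(i), 0.0, 0.0), v))
        return StructureModel("m", residues, atoms, is_predicted=True)

    def test_boundary_inclusive_at_70(self):
        model = self._model([91.0, 70.0, 69.9])
        kept = filter_by_plddt(model, 70.0)
        assert [r.residue_number for r in kept] == [1, 2]

    def test_experimental_structures_pass_through(self, two_residue_pdb):
        model = parse_structure(two_residue_pdb)  # is_predicted=False
        assert filter_by_plddt(model, 70.0) == model.residues

    def test_mixed_confidence_count(self):
        values = [90, 85, 50, 71, 60, 30, 75, 70, 69, 88, 10, 95]
        model = self._model([float(v) for v in values])
        assert len(filter_by_plddt(model, 70.0)) == sum(v >= 70 for v in values) == 7

    def test_zero_cutoff_keeps_everything(self):
        model = self._model([0.0, 10.0, 99.0])
        assert filter_by_plddt(model, 0.0) == model.residues

    def test_disagreeing_atoms_use_mean_with_warning(self):
        from sitenrich.structure_io import AtomRecord, StructureModel

        key = ResidueKey("m", "A", 1, amino_acid="GLY")
        model = StructureModel(
            "m",
            [key],
            [AtomRecord(key, "CA", "C", (0, 0, 0), 60.0), AtomRecord(key, "CB", "C", (1, 0, 0), 80.0)],
            is_predicted=True,
        )
        with pytest.warns(UserWarning, match="unequal"):
            assert model.residue_plddt(key) == pytest.approx(70.0)
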