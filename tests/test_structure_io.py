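"""Parsing of MOL2/PDB documents, the 6 A pocket rule and affinity indexes."""

import math

import numpy as np
import pytest

from seqbind import fixtures, structure_io
from seqbind.structure_io import (EmptyPocketError, StructureParseError,
                                  extract_pocket_sequence, load_affinity_index,
                                  parse_mol2, parse_pocket_pdb)

from conftest import ALA_PDB, BENZENE_MOL2, ETHANE_MOL2, GLY_SER_PDB


class TestParseMol2:
    def test_benzene_ring_topology(self):
        lig = parse_mol2(BENZENE_MOL2)
        assert len(lig.heavy_atoms) == 6
        assert len(lig.heavy_bonds()) == 6
        assert lig.smiles == "c1ccccc1"

    def test_ethane(self):
        lig = parse_mol2(ETHANE_MOL2)
        assert len(lig.heavy_atoms) == 2
        assert len(lig.heavy_bonds()) == 1
        assert lig.smiles == "CC"

    def test_bond_index_out_of_range(self):
        bad = ETHANE_MOL2.replace("1 1 2 1", "1 1 9 1")
        with pytest.raises(StructureParseError, match="beyond ATOM count"):
            parse_mol2(bad)

    def test_missing_bond_block(self):
        truncated = ETHANE_MOL2.split("@<TRIPOS>BOND")[0]
        with pytest.raises(StructureParseError, match="ATOM or .*BOND"):
            parse_mol2(truncated)

    def test_unparsable_coordinates(self):
        bad = ETHANE_MOL2.replace("1.540", "abc")
        with pytest.raises(StructureParseError, match="coordinates"):
            parse_mol2(bad)

    def test_valence_inconsistent_table(self):
        # pentavalent carbon: 5 neighbours on one C
        lines = ["@<TRIPOS>MOLECULE", "bad", "6 5 0 0 0", "SMALL", "NO_CHARGES", "",
                 "@<TRIPOS>ATOM"]
        for i in range(6):
            lines.append(f"{i+1} C{i+1} {float(i)} 0.0 0.0 C.3 1 LIG 0.0")
        lines.append("@<TRIPOS>BOND")
        for i in range(5):
            lines.append(f"{i+1} 1 {i+2} 1")
        with pytest.raises(StructureParseError, match="valence"):
            parse_mol2("\n".join(lines))

    def test_hydrogens_retained_but_flagged(self):
        mol2 = ETHANE_MOL2.replace(
            "@<TRIPOS>BOND",
            "  3 H1   0.500   1.000   0.000 H 1 ETH 0.0\n@<TRIPOS>BOND"
        ).replace(" 2 1 0 0 0", " 3 2 0 0 0") + " 2 1 3 1\n"
        lig = parse_mol2(mol2)
        assert len(lig.atoms) == 3
        assert len(lig.heavy_atoms) == 2
        assert not lig.atoms[2].is_heavy


class TestParsePocketPdb:
    def test_single_residue(self):
        pocket = parse_pocket_pdb(ALA_PDB)
        assert len(pocket.residues) == 1
        res_id, name, atoms = pocket.residues[0]
        assert name == "ALA"
        assert len(atoms) == 3

    def test_file_order_preserved(self):
        pocket = parse_pocket_pdb(GLY_SER_PDB)
        assert [name for _, name, _ in pocket.residues] == ["GLY", "SER"]

    def test_header_only_document_errors(self):
        with pytest.raises(StructureParseError, match="no residues"):
            parse_pocket_pdb("HEADER    TEST\nREMARK    NOTHING\nEND\n")


def _pocket_at(distances, resnames=None):
    """One-atom residues at given x-distances from a single ligand atom at origin."""
    resnames = resnames or ["GLY"] * len(distances)
    residues = []
    for i, (d, name) in enumerate(zip(distances, resnames), start=1):
        atom = structure_io.AtomRecord(element="C", coords=(float(d), 0.0, 0.0),
                                       residue_name=name, residue_id=i)
        residues.append((i, name, (atom,)))
    return structure_io.PocketStructure(residues=tuple(residues))


@pytest.fixture
def point_ligand():
    return parse_mol2(ETHANE_MOL2.replace("1.540", "0.0001"))


class TestExtractPocketSequence:
    def test_inclusive_boundary(self, point_ligand):
        assert extract_pocket_sequence(_pocket_at([5.9]), point_ligand) == "G"

    def test_outside_boundary_raises(self, point_ligand):
        with pytest.raises(EmptyPocketError):
            extract_pocket_sequence(_pocket_at([6.1]), point_ligand)

    def test_mixed_distances(self, point_ligand):
        pocket = _pocket_at([3.0, 10.0], resnames=["ALA", "SER"])
        assert extract_pocket_sequence(pocket, point_ligand) == "A"

    def test_nonstandard_residue_maps_to_unknown(self, point_ligand):
        assert extract_pocket_sequence(_pocket_at([3.0], ["LIG"]), point_ligand) == "X"

    def test_radius_monotonicity(self, point_ligand):
        rng = np.random.default_rng(0)
        distances = rng.uniform(2.0, 14.0, size=20)
        pocket = _pocket_at(distances)
        previous = ""
        for radius in (3.0, 5.0, 6.0, 9.0, 15.0):
            seq = extract_pocket_sequence(pocket, point_ligand, radius=radius)
            assert len(seq) >= len(previous)
            previous = seq


class TestAffinityIndex:
    def test_pdbbind_dialect_units(self):
        text = ("# comment line\n"
                "1abc  2.00  2005  6.00  Kd=1uM  // note\n"
                "2xyz  1.80  2010  8.00  Ki=10nM // other\n")
        records, rejects = load_affinity_index(text)
        assert not rejects
        assert records[0].value_molar == pytest.approx(1e-6)
        assert records[0].pK == pytest.approx(6.0)
        assert records[1].pK == pytest.approx(8.0)
        assert records[1].measurement == "Ki"

    def test_ic50_excluded_by_default(self):
        records, rejects = load_affinity_index("3foo 2.0 2001 5.3 IC50=5nM\n")
        assert records == []
        assert len(rejects) == 1 and "IC50" in rejects[0].reason

    def test_ic50_kept_on_request(self):
        records, _ = load_affinity_index("3foo 2.0 2001 5.3 IC50=5nM\n", keep_ic50=True)
        assert len(records) == 1
        assert records[0].pK == pytest.approx(-math.log10(5e-9))

    def test_csv_dialect(self):
        text = "id,type,value,unit\nc1,Kd,2.5,nM\nc2,Ki,100,uM\n"
        records, rejects = load_affinity_index(text)
        assert not rejects
        assert records[0].value_molar == pytest.approx(2.5e-9)
        assert records[1].pK == pytest.approx(4.0)

    def test_bad_rows_collected_not_raised(self):
        text = "c1,Kd,-3,nM\nc2,Kd,1,XL\nc3,Kq,1,nM\nc4 2.0 2001 5.0 nothing\n"
        records, rejects = load_affinity_index(text)
        assert records == []
        assert [r.complex_id for r in rejects] == ["c1", "c2", "c3", "c4"]

    def test_pk_consistency_invariant(self):
        text = "\n".join(f"c{i},Kd,{v},uM" for i, v in
                         enumerate([0.001, 0.5, 1, 37.2, 900]))
        records, _ = load_affinity_index(text)
        for rec in records:
            assert abs(rec.pK + math.log10(rec.value_molar)) < 1e-9


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(10))
    def test_fixture_complexes_survive_reparse(self, seed):
        """parse(emit(complex)) reproduces atoms, bonds, sequence and pK."""
        ligand, mol2 = fixtures.generate_ligand(seed)
        reparsed = structure_io.parse_mol2(mol2)
        assert len(reparsed.heavy_atoms) == len(ligand.heavy_atoms)
        assert len(reparsed.heavy_bonds()) == len(ligand.heavy_bonds())
        assert reparsed.smiles == ligand.smiles

        pocket, pdb = fixtures.generate_pocket(seed + 100, ligand, 5, 3)
        reparsed_pocket = structure_io.parse_pocket_pdb(pdb)
        seq1 = extract_pocket_sequence(pocket, ligand)
        seq2 = extract_pocket_sequence(reparsed_pocket, ligand)
        assert seq1 == seq2 and len(seq1) == 5

    def test_index_roundtrip_pk(self, small_dataset, tmp_path):
        fixtures.write_dataset(small_dataset, tmp_path)
        records, rejects = load_affinity_index((tmp_path / "index.csv").read_text())
        assert not rejects
        by_id = {r.complex_id: r for r in records}
        for rec in small_dataset.records:
            assert by_id[rec.complex_id].pK == pytest.approx(rec.affinity.pK, abs=1e-9)
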