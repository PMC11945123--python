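"""Graph statistics, descriptor catalogs, protein features and encodings."""

import networkx as nx
import numpy as np
import pytest

from seqbind import featurization as ft
from seqbind.structure_io import parse_mol2

from conftest import (BENZENE_MOL2, ETHANE_MOL2, brute_force_graph_stats,
                      connected_graphs_up_to)


def graph_of(edges, n=None):
    g = nx.Graph()
    nodes = n or (max(max(e) for e in edges) + 1 if edges else 1)
    g.add_nodes_from(range(nodes))
    g.add_edges_from(edges)
    return g


class TestGraphFeatures:
    def test_triangle(self):
        fs = ft.graph_features(graph_of([(0, 1), (1, 2), (0, 2)]))
        assert fs.mean_degree == pytest.approx(2.0)
        assert fs.mean_clustering == pytest.approx(1.0)
        assert fs.mean_betweenness == pytest.approx(0.0)

    def test_path_of_three(self):
        # centre carries the single s-t shortest path: bc = (1, 0, 0) -> mean 1/3
        fs = ft.graph_features(graph_of([(0, 1), (1, 2)]))
        assert fs.mean_clustering == pytest.approx(0.0)
        assert fs.mean_betweenness == pytest.approx(1.0 / 3.0)

    def test_star_of_four(self):
        fs = ft.graph_features(graph_of([(0, 1), (0, 2), (0, 3)]))
        assert fs.mean_degree == pytest.approx(1.5)
        assert fs.mean_betweenness == pytest.approx(0.25)

    def test_lone_atom(self):
        fs = ft.graph_features(graph_of([], n=1))
        assert (fs.n_nodes, fs.n_edges) == (1, 0)
        assert fs.mean_betweenness == 0.0

    def test_disconnected_uses_largest_component(self):
        # 4-cycle plus an isolated counter-ion node
        fs = ft.graph_features(graph_of([(0, 1), (1, 2), (2, 3), (3, 0)], n=5))
        assert fs.n_nodes == 4 and fs.n_edges == 4
        assert fs.mean_degree == pytest.approx(2.0)

    def test_oracle_on_all_small_connected_graphs(self):
        """Exhaustive check against brute-force shortest-path enumeration (<=6 nodes)."""
        checked = 0
        for n, edges in connected_graphs_up_to(5):
            fs = ft.graph_features(graph_of(edges, n=n))
            clus, bet = brute_force_graph_stats(n, edges)
            assert fs.mean_clustering == pytest.approx(clus, abs=1e-9)
            assert fs.mean_betweenness == pytest.approx(bet, abs=1e-9)
            checked += 1
        assert checked > 700

    def test_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(3, 9))
            g = nx.gnp_random_graph(n, rng.uniform(0.3, 0.9), seed=int(rng.integers(1 << 30)))
            if not nx.is_connected(g):
                continue
            fs = ft.graph_features(g.copy())
            clus, bet = brute_force_graph_stats(n, list(g.edges()))
            assert fs.mean_clustering == pytest.approx(clus, abs=1e-9)
            assert fs.mean_betweenness == pytest.approx(bet, abs=1e-9)


class TestLigandGraph:
    def test_build_counts(self):
        lig = parse_mol2(BENZENE_MOL2)
        g = ft.build_ligand_graph(lig)
        assert g.number_of_nodes() == 6 and g.number_of_edges() == 6

    def test_hydrogens_excluded(self):
        mol2 = ETHANE_MOL2.replace(
            "@<TRIPOS>BOND",
            "  3 H1   0.500   1.000   0.000 H 1 ETH 0.0\n@<TRIPOS>BOND"
        ).replace(" 2 1 0 0 0", " 3 2 0 0 0") + " 2 1 3 1\n"
        g = ft.build_ligand_graph(parse_mol2(mol2))
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1


class TestChemicalDescriptors:
    def test_benzene_has_no_polar_surface(self):
        vec = ft.chemical_descriptors("c1ccccc1")
        named = dict(zip(ft.DESCRIPTOR_SCHEMA, vec))
        assert named["TPSA"] == pytest.approx(0.0)
        assert named["NumHDonors"] == 0 and named["NumHAcceptors"] == 0

    def test_ethanol_hydrogen_bonding(self):
        named = dict(zip(ft.DESCRIPTOR_SCHEMA, ft.chemical_descriptors("CCO")))
        assert named["NumHDonors"] == 1 and named["NumHAcceptors"] == 1

    def test_methane_mass_from_atomic_masses(self):
        # oracle: 12.011 + 4 * 1.008
        named = dict(zip(ft.DESCRIPTOR_SCHEMA, ft.chemical_descriptors("C")))
        assert named["MolWt"] == pytest.approx(12.011 + 4 * 1.008, abs=0.01)

    def test_bad_smiles_raises(self):
        with pytest.raises(ValueError, match="SMILES"):
            ft.chemical_descriptors("not-a-molecule(((")


class TestProteinFeatures:
    def named(self, seq):
        return dict(zip(ft.PROTEIN_SCHEMA, ft.protein_sequence_features(seq)))

    def test_frequencies(self):
        named = self.named("AAAG")
        assert named["length"] == 4
        assert named["freq_A"] == pytest.approx(0.75)
        assert named["freq_G"] == pytest.approx(0.25)
        freqs = sum(named[f"freq_{aa}"] for aa in ft.PROTEIN_ALPHABET)
        assert freqs == pytest.approx(1.0, abs=1e-9)

    def test_all_aromatic(self):
        assert self.named("FWY")["aromaticity"] == pytest.approx(1.0)

    def test_gravy_of_polyalanine(self):
        # Kyte-Doolittle value of alanine is 1.8
        named = self.named("AAAA")
        assert named["gravy"] == pytest.approx(1.8)
        assert named["hydrophobicity"] == pytest.approx(1.8)

    def test_unknown_excluded_from_averages_but_counted_in_length(self):
        with_x = self.named("AXAXA")
        plain = self.named("AAA")
        assert with_x["length"] == 5
        assert with_x["gravy"] == pytest.approx(plain["gravy"])
        assert with_x["freq_A"] == pytest.approx(1.0)

    def test_duplication_scale_invariance(self):
        """Per-residue averages are invariant under sequence duplication;
        extensive features (length, extinction) double exactly."""
        seq = "ACDWYFGHIKL"
        one, two = self.named(seq), self.named(seq + seq)
        for name in (["gravy", "aromaticity", "hydrophilicity", "polarity",
                      "polar_fraction", "helix_fraction"]
                     + [f"freq_{aa}" for aa in ft.PROTEIN_ALPHABET]):
            assert two[name] == pytest.approx(one[name], abs=1e-12)
        assert two["length"] == 2 * one["length"]
        assert two["extinction_coefficient"] == 2 * one["extinction_coefficient"]

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            ft.protein_sequence_features("")

    def test_fraction_bounds(self):
        named = self.named("ACDEFGHIKLMNPQRSTVWY")
        for key in ("polar_fraction", "basic_fraction", "acidic_fraction",
                    "helix_fraction", "turn_fraction", "sheet_fraction",
                    "aromaticity"):
            assert 0.0 <= named[key] <= 1.0


class TestOneHotEncodings:
    def test_smiles_rows(self):
        mat = ft.encode_smiles_onehot("CCO")
        assert mat.shape == (325, 80)
        assert mat[:3].sum(axis=1).tolist() == [1, 1, 1]
        assert mat[3:].sum() == 0

    def test_two_character_tokens(self):
        tokens = ft.tokenize_smiles("CCl.C[Br]")
        assert tokens == ["C", "Cl", ".", "C", "[", "Br", "]"]

    def test_unknown_symbol_maps_to_reserved_column(self):
        mat = ft.encode_smiles_onehot("C!")
        unk = ft.SMILES_VOCAB.index(ft.UNKNOWN_TOKEN)
        assert mat[1, unk] == 1

    def test_overlong_smiles_truncated(self):
        mat = ft.encode_smiles_onehot("C" * 400)
        assert mat.sum() == 325

    def test_empty_smiles_raises(self):
        with pytest.raises(ValueError):
            ft.encode_smiles_onehot("")

    def test_protein_rows(self):
        mat = ft.encode_protein_onehot("ACD")
        assert mat.shape == (150, 20)
        assert (mat.sum(axis=1) > 0).sum() == 3

    def test_protein_unknown_row_is_zero(self):
        mat = ft.encode_protein_onehot("XG")
        assert mat[0].sum() == 0 and mat[1].sum() == 1

    def test_overlong_protein_truncated(self):
        mat = ft.encode_protein_onehot("A" * 200)
        assert mat.sum() == 150

    def test_onehot_conservation(self, small_dataset):
        """Sum of the one-hot equals min(token count, 325); protein analogue
        subtracts 'X' positions."""
        for rec in small_dataset.records[:20]:
            tokens = ft.tokenize_smiles(rec.ligand.smiles)
            mat = ft.encode_smiles_onehot(rec.ligand.smiles)
            assert mat.sum() == min(len(tokens), 325)
            seq = rec.pocket_sequence[:150]
            pmat = ft.encode_protein_onehot(rec.pocket_sequence)
            assert pmat.sum() == len(seq) - seq.count("X")


class TestStructuralVectors:
    def test_padding_and_placement(self):
        gf = ft.GraphFeatureSet(3, 2, 4 / 3, 0.0, 1 / 3)
        desc = np.arange(float(len(ft.DESCRIPTOR_SCHEMA)))
        prot = np.arange(float(len(ft.PROTEIN_SCHEMA)))
        lig_vec, prot_vec = ft.assemble_structural_vectors(gf, desc, prot)
        used = len(ft.LIGAND_SCHEMA)
        assert lig_vec.shape == (88,) and prot_vec.shape == (74,)
        assert np.all(lig_vec[used:] == 0)
        assert np.all(prot_vec[len(ft.PROTEIN_SCHEMA):] == 0)
        assert lig_vec[0] == 3 and lig_vec[5] == 0.0  # graph block then descriptors

    def test_overlong_schema_truncated(self):
        gf = ft.GraphFeatureSet(1, 0, 0.0, 0.0, 0.0)
        lig_vec, _ = ft.assemble_structural_vectors(
            gf, np.ones(95), np.ones(10))
        assert lig_vec.shape == (88,)

    def test_standardization_applied_at_transform_time(self):
        gf = ft.GraphFeatureSet(2, 1, 1.0, 0.0, 0.0)
        desc = np.zeros(len(ft.DESCRIPTOR_SCHEMA))
        prot = np.zeros(len(ft.PROTEIN_SCHEMA))
        mean, std = np.full(88, 1.0), np.full(88, 2.0)
        lig_vec, _ = ft.assemble_structural_vectors(gf, desc, prot,
                                                    ligand_stats=(mean, std))
        assert lig_vec[0] == pytest.approx((2 - 1) / 2)

    def test_determinism(self, small_dataset):
        rec = small_dataset.records[0]
        a, b = ft.encode_complex(rec), ft.encode_complex(rec)
        assert np.array_equal(a.ligand_struct_vec, b.ligand_struct_vec)
        assert np.array_equal(a.protein_struct_vec, b.protein_struct_vec)
        assert np.array_equal(a.ligand_onehot, b.ligand_onehot)
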