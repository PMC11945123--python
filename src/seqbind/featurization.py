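"""Ligand and protein feature catalogs and fixed-shape one-hot encodings.

Three ligand feature families are computed: graph statistics of the
heavy-atom bond graph (node/edge counts, mean degree, mean clustering
coefficient, mean betweenness centrality), the classical chemical descriptors
(MW, HBD, HBA, LogP, TPSA) and an extended RDKit descriptor block (ring and
heteroatom counts, FractionCSP3, MolMR, QED, the PEOE/SMR/SlogP VSA
partitions and VSA_EState bins).  The protein side covers the ProtParam-style
physicochemical catalog of the pocket sequence.

Sequence inputs are additionally one-hot encoded to fixed shapes -- SMILES to
325 tokens x 80 symbols, pocket sequence to 150 positions x 20 letters --
with zero-padding past the true length, and the scalar catalogs are packed
into fixed-length "structural" vectors (ligand 88, protein 74).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np

from .structure_io import LigandStructure, UNKNOWN_RESIDUE

logger = logging.getLogger(__name__)

# fixed encoder shapes
SMILES_MAX_TOKENS = 325
SMILES_VOCAB_SIZE = 80
PROTEIN_MAX_LEN = 150
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
LIGAND_STRUCT_LEN = 88
PROTEIN_STRUCT_LEN = 74

GRAPH_FEATURE_NAMES = ["n_nodes", "n_edges", "mean_degree",
                       "mean_clustering", "mean_betweenness"]

CHEMICAL_DESCRIPTOR_NAMES = ["MolWt", "NumHDonors", "NumHAcceptors", "MolLogP", "TPSA"]

ADDITIONAL_DESCRIPTOR_NAMES = (
    ["NumAliphaticCarbocycles", "NumAliphaticHeterocycles", "NumAliphaticRings",
     "NumAromaticCarbocycles", "NumAromaticHeterocycles", "NumAromaticRings",
     "FractionCSP3", "HeavyAtomCount", "NHOHCount", "NOCount", "NumHeteroatoms",
     "NumRadicalElectrons", "NumSaturatedCarbocycles", "NumSaturatedHeterocycles",
     "NumSaturatedRings", "RingCount", "MolMR", "qed"]
    + [f"PEOE_VSA{i}" for i in range(1, 15)]
    + [f"SMR_VSA{i}" for i in range(1, 9)]
    + [f"SlogP_VSA{i}" for i in range(1, 13)]
    + [f"VSA_EState{i}" for i in range(1, 11)]
)

DESCRIPTOR_SCHEMA = CHEMICAL_DESCRIPTOR_NAMES + ADDITIONAL_DESCRIPTOR_NAMES
LIGAND_SCHEMA = GRAPH_FEATURE_NAMES + DESCRIPTOR_SCHEMA

PROTEIN_SCHEMA = (
    ["length"]
    + [f"freq_{aa}" for aa in PROTEIN_ALPHABET]
    + ["hydrophobicity", "hydrophilicity", "polarity", "charge",
       "extinction_coefficient", "isoelectric_point",
       "helix_fraction", "turn_fraction", "sheet_fraction",
       "aromaticity", "instability_index", "flexibility", "aliphatic_index",
       "gravy", "isoelectric_point_2", "molecular_weight", "charge_composition",
       "polar_fraction", "basic_fraction", "acidic_fraction",
       "turn_fraction_2", "sheet_fraction_2", "helix_fraction_2",
       "disulfide_bonds", "transmembrane_helices"]
)

# ---------------------------------------------------------------------------
# amino-acid scales
# ---------------------------------------------------------------------------

#: Kyte-Doolittle hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Hopp-Woods hydrophilicity
HOPP_WOODS = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0, "Q": 0.2, "E": 3.0,
    "G": 0.0, "H": -0.5, "I": -1.8, "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5,
    "P": 0.0, "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}

#: Grantham polarity
GRANTHAM_POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5, "E": 12.3,
    "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2,
    "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9,
}

#: EMBOSS pKa set for Henderson-Hasselbalch net charge
EMBOSS_PKA = {"Nterm": 8.6, "Cterm": 3.6, "C": 8.5, "D": 3.9, "E": 4.1,
              "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1}

POLAR_AA = set("NQSTYC")
BASIC_AA = set("KRH")
ACIDIC_AA = set("DE")
AROMATIC_AA = set("FWY")


# ---------------------------------------------------------------------------
# ligand graph features
# ---------------------------------------------------------------------------

def build_ligand_graph(ligand: LigandStructure) -> nx.Graph:
    """Simple undirected graph over heavy atoms; one edge per heavy-atom bond."""
    heavy = ligand.heavy_atoms
    if not heavy:
        raise ValueError("ligand has no heavy atoms")
    g = nx.Graph()
    g.add_nodes_from(range(len(heavy)))
    g.add_edges_from((i, j) for i, j, _ in ligand.heavy_bonds())
    return g


@dataclass(frozen=True)
class GraphFeatureSet:
    n_nodes: int
    n_edges: int
    mean_degree: float
    mean_clustering: float
    mean_betweenness: float

    def as_array(self) -> np.ndarray:
        return np.array([self.n_nodes, self.n_edges, self.mean_degree,
                         self.mean_clustering, self.mean_betweenness], dtype=float)


def graph_features(g: nx.Graph) -> GraphFeatureSet:
    """Mean degree / clustering / betweenness of the (largest component of a) graph.

    Betweenness uses the undirected normalization by (N-1)(N-2)/2 and is
    defined as 0 for N <= 2.  Disconnected inputs (salt forms) are reduced to
    their largest connected component first.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty molecular graph")
    if not nx.is_connected(g):
        keep = max(nx.connected_components(g), key=len)
        g = g.subgraph(keep).copy()
    n, e = g.number_of_nodes(), g.number_of_edges()
    clustering = float(np.mean(list(nx.clustering(g).values())))
    betweenness = float(np.mean(list(nx.betweenness_centrality(g, normalized=True).values())))
    return GraphFeatureSet(n_nodes=n, n_edges=e, mean_degree=2.0 * e / n,
                           mean_clustering=clustering, mean_betweenness=betweenness)


# ---------------------------------------------------------------------------
# chemical descriptors
# ---------------------------------------------------------------------------

def chemical_descriptors(ligand: LigandStructure | str,
                         schema: list[str] = DESCRIPTOR_SCHEMA) -> np.ndarray:
    """RDKit descriptor vector ordered per ``schema`` (Wildman-Crippen LogP/MR,
    Ertl TPSA, Labute VSA partitions, QED, ...)."""
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    smiles = ligand if isinstance(ligand, str) else ligand.smiles
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot rebuild molecule from SMILES {smiles!r}")
    values = np.empty(len(schema), dtype=float)
    for k, name in enumerate(schema):
        fn = getattr(Descriptors, name, None)
        if fn is None:
            raise ValueError(f"unknown descriptor {name!r}")
        try:
            values[k] = float(fn(mol))
        except Exception as exc:
            raise ValueError(f"descriptor {name!r} failed: {exc}") from exc
    if not np.all(np.isfinite(values)):
        bad = [schema[k] for k in np.flatnonzero(~np.isfinite(values))]
        raise ValueError(f"non-finite descriptors: {bad}")
    return values


# ---------------------------------------------------------------------------
# protein sequence features
# ---------------------------------------------------------------------------

def _net_charge(counts: dict[str, int], ph: float) -> float:
    pos = sum(counts.get(aa, 0) / (1.0 + 10.0 ** (ph - EMBOSS_PKA[aa])) for aa in "KRH")
    pos += 1.0 / (1.0 + 10.0 ** (ph - EMBOSS_PKA["Nterm"]))
    neg = sum(counts.get(aa, 0) / (1.0 + 10.0 ** (EMBOSS_PKA[aa] - ph)) for aa in "DECY")
    neg += 1.0 / (1.0 + 10.0 ** (EMBOSS_PKA["Cterm"] - ph))
    return pos - neg


def _isoelectric_point(counts: dict[str, int], tol: float = 1e-4) -> float:
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _net_charge(counts, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _mean_scale(seq: str, scale: dict[str, float]) -> float:
    return float(np.mean([scale[aa] for aa in seq]))


def _transmembrane_helices(seq: str, window: int = 19, cutoff: float = 1.6) -> int:
    """Count of non-overlapping windows with mean Kyte-Doolittle above cutoff."""
    count, i = 0, 0
    while i + window <= len(seq):
        if _mean_scale(seq[i:i + window], KYTE_DOOLITTLE) > cutoff:
            count += 1
            i += window
        else:
            i += 1
    return count


def protein_sequence_features(seq: str) -> np.ndarray:
    """ProtParam-style physicochemical vector ordered per ``PROTEIN_SCHEMA``.

    The unknown symbol 'X' counts toward the sequence length but is excluded
    from every scale average and frequency denominator.
    """
    from Bio.SeqUtils.ProtParam import ProteinAnalysis

    if not seq:
        raise ValueError("empty protein sequence")
    bad = set(seq) - set(PROTEIN_ALPHABET) - {UNKNOWN_RESIDUE}
    if bad:
        raise ValueError(f"non-canonical letters in sequence: {sorted(bad)}")
    canonical = "".join(aa for aa in seq if aa != UNKNOWN_RESIDUE)
    if not canonical:
        raise ValueError("sequence contains only unknown residues")

    counts = {aa: canonical.count(aa) for aa in PROTEIN_ALPHABET}
    n = len(canonical)
    pa = ProteinAnalysis(canonical)
    helix, turn, sheet = pa.secondary_structure_fraction()
    flex_windows = pa.flexibility() if n >= 9 else []
    flexibility = float(np.mean(flex_windows)) if len(flex_windows) else 0.0
    instability = pa.instability_index() if n >= 2 else 0.0
    pi = _isoelectric_point(counts)
    aliphatic = 100.0 * (counts["A"] + 2.9 * counts["V"]
                         + 3.9 * (counts["I"] + counts["L"])) / n
    extinction = 5500.0 * counts["W"] + 1490.0 * counts["Y"]
    n_acidic = counts["D"] + counts["E"]
    n_basic = counts["K"] + counts["R"] + counts["H"]

    values = {
        "length": float(len(seq)),
        **{f"freq_{aa}": counts[aa] / n for aa in PROTEIN_ALPHABET},
        "hydrophobicity": _mean_scale(canonical, KYTE_DOOLITTLE),
        "hydrophilicity": _mean_scale(canonical, HOPP_WOODS),
        "polarity": _mean_scale(canonical, GRANTHAM_POLARITY),
        "charge": _net_charge(counts, 7.0),
        "extinction_coefficient": extinction,
        "isoelectric_point": pi,
        "helix_fraction": helix,
        "turn_fraction": turn,
        "sheet_fraction": sheet,
        "aromaticity": sum(counts[aa] for aa in AROMATIC_AA) / n,
        "instability_index": instability,
        "flexibility": flexibility,
        "aliphatic_index": aliphatic,
        "gravy": _mean_scale(canonical, KYTE_DOOLITTLE),
        "isoelectric_point_2": pi,
        "molecular_weight": pa.molecular_weight(),
        "charge_composition": n_basic / max(n_acidic, 1),
        "polar_fraction": sum(counts[aa] for aa in POLAR_AA) / n,
        "basic_fraction": n_basic / n,
        "acidic_fraction": n_acidic / n,
        "turn_fraction_2": turn,
        "sheet_fraction_2": sheet,
        "helix_fraction_2": helix,
        "disulfide_bonds": float(counts["C"] // 2),
        "transmembrane_helices": float(_transmembrane_helices(canonical)),
    }
    out = np.array([values[name] for name in PROTEIN_SCHEMA], dtype=float)
    if not np.all(np.isfinite(out)):
        bad = [PROTEIN_SCHEMA[k] for k in np.flatnonzero(~np.isfinite(out))]
        raise ValueError(f"non-finite protein features: {bad}")
    return out


# ---------------------------------------------------------------------------
# one-hot encodings
# ---------------------------------------------------------------------------

def _load_vocab() -> list[str]:
    with resources.files("seqbind.data").joinpath("smiles_vocab.json").open() as fh:
        payload = json.load(fh)
    return payload["symbols"]


SMILES_VOCAB: list[str] = _load_vocab()
_VOCAB_INDEX = {sym: i for i, sym in enumerate(SMILES_VOCAB)}
_TWO_CHAR = {sym for sym in SMILES_VOCAB if len(sym) == 2}
UNKNOWN_TOKEN = "<unk>"


def tokenize_smiles(smiles: str) -> list[str]:
    """Greedy longest-match tokenization against the 80-symbol vocabulary.

    Two-character element symbols (Cl, Br, Si, ...) and %nn ring closures are
    single tokens; anything unmatched becomes the reserved unknown token.
    """
    tokens, i = [], 0
    while i < len(smiles):
        if smiles[i] == "%" and smiles[i:i + 3] in _VOCAB_INDEX:
            tokens.append(smiles[i:i + 3])
            i += 3
        elif smiles[i:i + 2] in _TWO_CHAR:
            tokens.append(smiles[i:i + 2])
            i += 2
        elif smiles[i] in _VOCAB_INDEX:
            tokens.append(smiles[i])
            i += 1
        else:
            tokens.append(UNKNOWN_TOKEN)
            i += 1
    return tokens


def encode_smiles_onehot(smiles: str) -> np.ndarray:
    """One-hot matrix (325 x 80); rows past the token count are zero padding."""
    if not smiles:
        raise ValueError("empty SMILES string")
    tokens = tokenize_smiles(smiles)
    if len(tokens) > SMILES_MAX_TOKENS:
        logger.warning("SMILES of %d tokens truncated to %d", len(tokens), SMILES_MAX_TOKENS)
        tokens = tokens[:SMILES_MAX_TOKENS]
    mat = np.zeros((SMILES_MAX_TOKENS, SMILES_VOCAB_SIZE), dtype=np.uint8)
    for row, tok in enumerate(tokens):
        mat[row, _VOCAB_INDEX[tok]] = 1
    return mat


def encode_protein_onehot(seq: str) -> np.ndarray:
    """One-hot matrix (150 x 20); 'X' and padding positions are all-zero rows."""
    if not seq:
        raise ValueError("empty protein sequence")
    if len(seq) > PROTEIN_MAX_LEN:
        logger.warning("sequence of %d residues truncated to %d", len(seq), PROTEIN_MAX_LEN)
        seq = seq[:PROTEIN_MAX_LEN]
    mat = np.zeros((PROTEIN_MAX_LEN, len(PROTEIN_ALPHABET)), dtype=np.uint8)
    for row, aa in enumerate(seq):
        col = PROTEIN_ALPHABET.find(aa)
        if col >= 0:
            mat[row, col] = 1
    return mat


def _pad_to(vec: np.ndarray, length: int, label: str) -> np.ndarray:
    if len(vec) > length:
        logger.warning("%s vector of %d scalars truncated to %d", label, len(vec), length)
        return np.asarray(vec[:length], dtype=float)
    out = np.zeros(length, dtype=float)
    out[:len(vec)] = vec
    return out


def assemble_structural_vectors(graph_fs: GraphFeatureSet, descriptors: np.ndarray,
                                protein_features: np.ndarray,
                                ligand_stats: tuple[np.ndarray, np.ndarray] | None = None,
                                protein_stats: tuple[np.ndarray, np.ndarray] | None = None,
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Pack the scalar catalogs into the fixed-length structural vectors.

    Ligand side = [graph || chemical || additional] zero-padded to 88; protein
    side = protein catalog padded to 74.  When per-channel (mean, std) training
    statistics are supplied the populated channels are standardized with them.
    """
    lig = np.concatenate([graph_fs.as_array(), np.asarray(descriptors, dtype=float)])
    lig = _pad_to(lig, LIGAND_STRUCT_LEN, "ligand structural")
    prot = _pad_to(np.asarray(protein_features, dtype=float), PROTEIN_STRUCT_LEN,
                   "protein structural")
    if ligand_stats is not None:
        mean, std = ligand_stats
        lig = (lig - mean) / np.where(std > 0, std, 1.0)
    if protein_stats is not None:
        mean, std = protein_stats
        prot = (prot - mean) / np.where(std > 0, std, 1.0)
    return lig, prot


# ---------------------------------------------------------------------------
# per-complex bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncodedComplex:
    complex_id: str
    ligand_onehot: np.ndarray       # (325, 80) uint8
    protein_onehot: np.ndarray      # (150, 20) uint8
    ligand_struct_vec: np.ndarray   # (88,) raw (unstandardized)
    protein_struct_vec: np.ndarray  # (74,) raw
    n_tokens: int
    n_residues: int


def encode_complex(record) -> EncodedComplex:
    """Full featurization of one complex record into the fixed-shape bundle."""
    g = build_ligand_graph(record.ligand)
    gf = graph_features(g)
    desc = chemical_descriptors(record.ligand)
    prot = protein_sequence_features(record.pocket_sequence)
    lig_vec, prot_vec = assemble_structural_vectors(gf, desc, prot)
    tokens = tokenize_smiles(record.ligand.smiles)
    return EncodedComplex(
        complex_id=record.complex_id,
        ligand_onehot=encode_smiles_onehot(record.ligand.smiles),
        protein_onehot=encode_protein_onehot(record.pocket_sequence),
        ligand_struct_vec=lig_vec,
        protein_struct_vec=prot_vec,
        n_tokens=min(len(tokens), SMILES_MAX_TOKENS),
        n_residues=min(len(record.pocket_sequence), PROTEIN_MAX_LEN),
    )


def descriptor_slice(encoded: "EncodedDataset | np.ndarray") -> slice:
    """Columns of the ligand structural vector holding the chemical+additional block."""
    start = len(GRAPH_FEATURE_NAMES)
    return slice(start, start + len(DESCRIPTOR_SCHEMA))


@dataclass
class EncodedDataset:
    """Column-stacked arrays for a list of encoded complexes."""
    complex_ids: list[str]
    ligand_onehot: np.ndarray     # (n, 325, 80) uint8
    protein_onehot: np.ndarray    # (n, 150, 20) uint8
    ligand_struct: np.ndarray     # (n, 88)
    protein_struct: np.ndarray    # (n, 74)
    n_tokens: np.ndarray          # (n,)
    n_residues: np.ndarray        # (n,)

    def __len__(self) -> int:
        return len(self.complex_ids)

    def subset(self, idx) -> "EncodedDataset":
        idx = np.asarray(idx)
        return EncodedDataset(
            complex_ids=[self.complex_ids[i] for i in idx],
            ligand_onehot=self.ligand_onehot[idx],
            protein_onehot=self.protein_onehot[idx],
            ligand_struct=self.ligand_struct[idx],
            protein_struct=self.protein_struct[idx],
            n_tokens=self.n_tokens[idx],
            n_residues=self.n_residues[idx],
        )


def stack_encoded(encoded: list[EncodedComplex]) -> EncodedDataset:
    return EncodedDataset(
        complex_ids=[e.complex_id for e in encoded],
        ligand_onehot=np.stack([e.ligand_onehot for e in encoded]),
        protein_onehot=np.stack([e.protein_onehot for e in encoded]),
        ligand_struct=np.stack([e.ligand_struct_vec for e in encoded]),
        protein_struct=np.stack([e.protein_struct_vec for e in encoded]),
        n_tokens=np.array([e.n_tokens for e in encoded], dtype=np.int64),
        n_residues=np.array([e.n_residues for e in encoded], dtype=np.int64),
    )


def feature_matrix(dataset: EncodedDataset) -> tuple[np.ndarray, list[str]]:
    """Named numeric feature matrix [ligand catalog || protein catalog].

    Only the populated schema columns are included (padding channels dropped).
    """
    lig = dataset.ligand_struct[:, :len(LIGAND_SCHEMA)]
    prot = dataset.protein_struct[:, :len(PROTEIN_SCHEMA)]
    names = [f"ligand:{n}" for n in LIGAND_SCHEMA] + [f"protein:{n}" for n in PROTEIN_SCHEMA]
    return np.hstack([lig, prot]), names
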