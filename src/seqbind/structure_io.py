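"""Readers for ligand MOL2, binding-pocket PDB and affinity index files.

A protein-ligand complex is represented here the way PDBbind distributes it:
one TRIPOS MOL2 file for the ligand, one PDB file for the protein binding
pocket, and one index line mapping the complex id to a measured Kd/Ki/IC50.
The pocket *sequence* used by the downstream featurizer is derived from the
pocket structure by keeping every residue with a heavy atom within a fixed
radius (default 6 A) of any ligand heavy atom.
"""

from __future__ import annotations

import csv
import io
import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist


class StructureParseError(ValueError):
    """Raised when a MOL2/PDB document cannot be parsed into a structure."""


class EmptyPocketError(ValueError):
    """No residue lies within the cutoff radius of the ligand (mis-paired complex)."""


#: elements accepted in atom records (small-molecule + common metal set)
RECOGNIZED_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Mo Ru Rh Pd Ag Cd Sn Sb Te I Cs Ba W Re Os "
    "Ir Pt Au Hg Tl Pb Bi".split()
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common variants: selenomethionine and protonation-state histidines
    "MSE": "M", "HSD": "H", "HSE": "H", "HSP": "H",
}

#: letter used for residues outside the canonical table; one-hot rows for it are all-zero
UNKNOWN_RESIDUE = "X"

_UNIT_TO_MOLAR = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # micro sign
    "μM": 1e-6,  # greek mu
    "nM": 1e-9,
    "pM": 1e-12,
    "fM": 1e-15,
}


@dataclass(frozen=True)
class AtomRecord:
    element: str
    coords: tuple[float, float, float]
    residue_name: str = ""
    residue_id: int = 0

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass(frozen=True)
class LigandStructure:
    atoms: tuple[AtomRecord, ...]
    bonds: tuple[tuple[int, int, str], ...]
    smiles: str

    @property
    def heavy_atoms(self) -> tuple[AtomRecord, ...]:
        return tuple(a for a in self.atoms if a.is_heavy)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy], dtype=float)

    def heavy_bonds(self) -> list[tuple[int, int, str]]:
        """Bonds between heavy atoms, re-indexed over the heavy-atom list."""
        heavy_idx = {}
        for i, a in enumerate(self.atoms):
            if a.is_heavy:
                heavy_idx[i] = len(heavy_idx)
        out = []
        for i, j, order in self.bonds:
            if i in heavy_idx and j in heavy_idx:
                out.append((heavy_idx[i], heavy_idx[j], order))
        return out


@dataclass(frozen=True)
class PocketStructure:
    #: ordered (residue_id, 3-letter code, atoms) as encountered in the file
    residues: tuple[tuple[int, str, tuple[AtomRecord, ...]], ...]


@dataclass(frozen=True)
class AffinityRecord:
    complex_id: str
    measurement: str  # Kd | Ki | IC50
    value_molar: float
    pK: float

    def __post_init__(self):
        if not self.value_molar > 0:
            raise ValueError(f"non-positive affinity for {self.complex_id}")
        if abs(self.pK + math.log10(self.value_molar)) > 1e-9:
            raise ValueError(f"inconsistent pK for {self.complex_id}")


@dataclass(frozen=True)
class ComplexRecord:
    complex_id: str
    ligand: LigandStructure
    pocket: PocketStructure
    pocket_sequence: str
    affinity: AffinityRecord | None = None


# ---------------------------------------------------------------------------
# MOL2
# ---------------------------------------------------------------------------

def _mol2_sections(text: str) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current = None
    for raw in text.splitlines():
        line = raw.rstrip()
        if line.startswith("@<TRIPOS>"):
            current = line[len("@<TRIPOS>"):].strip().upper()
            sections.setdefault(current, [])
        elif current is not None and line.strip() and not line.startswith("#"):
            sections[current].append(line)
    return sections


_MOL2_BOND_ORDER = {"1": "1", "2": "2", "3": "3", "am": "am", "ar": "ar",
                    "du": "1", "un": "1", "nc": "nc"}


def parse_mol2(text: str) -> LigandStructure:
    """Parse a TRIPOS MOL2 document into a ligand structure.

    Hydrogens are retained (flagged via ``AtomRecord.is_heavy``).  The
    canonical SMILES is derived from the connection table with RDKit; a
    valence-inconsistent table raises :class:`StructureParseError` naming the
    offending molecule.
    """
    sections = _mol2_sections(text)
    if "ATOM" not in sections or "BOND" not in sections:
        raise StructureParseError("MOL2 document lacks @<TRIPOS>ATOM or @<TRIPOS>BOND block")

    atoms: list[AtomRecord] = []
    for line in sections["ATOM"]:
        parts = line.split()
        if len(parts) < 6:
            raise StructureParseError(f"short MOL2 ATOM record: {line!r}")
        try:
            xyz = (float(parts[2]), float(parts[3]), float(parts[4]))
        except ValueError as exc:
            raise StructureParseError(f"unparsable coordinates in ATOM record: {line!r}") from exc
        if not all(math.isfinite(c) for c in xyz):
            raise StructureParseError(f"non-finite coordinates in ATOM record: {line!r}")
        sybyl = parts[5]
        element = sybyl.split(".")[0]
        element = element[:1].upper() + element[1:].lower()
        if element not in RECOGNIZED_ELEMENTS:
            raise StructureParseError(f"unrecognized element {element!r} in ATOM record: {line!r}")
        atoms.append(AtomRecord(element=element, coords=xyz))

    bonds: list[tuple[int, int, str]] = []
    for line in sections["BOND"]:
        parts = line.split()
        if len(parts) < 4:
            raise StructureParseError(f"short MOL2 BOND record: {line!r}")
        i, j = int(parts[1]) - 1, int(parts[2]) - 1
        if not (0 <= i < len(atoms) and 0 <= j < len(atoms)):
            raise StructureParseError(
                f"BOND record references atom index beyond ATOM count: {line!r}")
        if i == j:
            raise StructureParseError(f"self-bond in BOND record: {line!r}")
        order = _MOL2_BOND_ORDER.get(parts[3], None)
        if order is None:
            raise StructureParseError(f"unknown bond type in BOND record: {line!r}")
        bonds.append((i, j, order))

    smiles = _smiles_from_table(atoms, bonds)
    return LigandStructure(atoms=tuple(atoms), bonds=tuple(bonds), smiles=smiles)


def _smiles_from_table(atoms: list[AtomRecord], bonds: list[tuple[int, int, str]]) -> str:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    mol = Chem.RWMol()
    for a in atoms:
        mol.AddAtom(Chem.Atom(a.element))
    bond_type = {
        "1": Chem.BondType.SINGLE, "2": Chem.BondType.DOUBLE,
        "3": Chem.BondType.TRIPLE, "am": Chem.BondType.SINGLE,
        "ar": Chem.BondType.AROMATIC, "nc": Chem.BondType.SINGLE,
    }
    for i, j, order in bonds:
        mol.AddBond(i, j, bond_type[order])
        if order == "ar":
            mol.GetAtomWithIdx(i).SetIsAromatic(True)
            mol.GetAtomWithIdx(j).SetIsAromatic(True)
    try:
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        m = Chem.RemoveHs(m)
        smiles = Chem.MolToSmiles(m)
    except Exception as exc:  # rdkit raises several sanitization error types
        raise StructureParseError(f"valence-inconsistent connection table: {exc}") from exc
    if not smiles:
        raise StructureParseError("empty SMILES derived from connection table")
    return smiles


# ---------------------------------------------------------------------------
# PDB pockets
# ---------------------------------------------------------------------------

def parse_pocket_pdb(text: str) -> PocketStructure:
    """Parse ATOM/HETATM records of a pocket PDB document.

    Residues are grouped by (chain, residue number, insertion code) in file
    order; only the first model is considered and alternate locations resolve
    to the highest-occupancy conformer (ties broken by first occurrence).
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("pocket", io.StringIO(text))
    residues = []
    models = list(structure)
    if models:
        for chain in models[0]:
            for residue in chain:
                atoms = tuple(
                    AtomRecord(
                        element=(atom.element or "C").strip().capitalize(),
                        coords=tuple(float(c) for c in atom.coord),
                        residue_name=residue.get_resname().strip(),
                        residue_id=residue.id[1],
                    )
                    # plain iteration selects the highest-occupancy altloc
                    for atom in residue
                )
                if atoms:
                    residues.append((residue.id[1], residue.get_resname().strip(), atoms))
    if not residues:
        raise StructureParseError("no residues parsed from PDB document")
    return PocketStructure(residues=tuple(residues))


def three_to_one(resname: str) -> str:
    return THREE_TO_ONE.get(resname.upper(), UNKNOWN_RESIDUE)


def extract_pocket_sequence(pocket: PocketStructure, ligand: LigandStructure,
                            radius: float = 6.0) -> str:
    """One-letter sequence of residues within ``radius`` A of the ligand.

    A residue qualifies when *any* of its heavy atoms lies within ``radius``
    of any ligand heavy atom (Euclidean, inclusive boundary).  Hydrogens are
    ignored on both sides, since pocket files frequently omit them.
    """
    lig = ligand.heavy_coords()
    if lig.size == 0:
        raise ValueError("ligand has no heavy atoms")
    letters = []
    for _, resname, atoms in pocket.residues:
        coords = np.array([a.coords for a in atoms if a.is_heavy], dtype=float)
        if coords.size == 0:
            continue
        if cdist(coords, lig).min() <= radius:
            letters.append(three_to_one(resname))
    if not letters:
        raise EmptyPocketError(f"no residue within {radius} A of the ligand")
    return "".join(letters)


# ---------------------------------------------------------------------------
# Affinity index
# ---------------------------------------------------------------------------

_PDBBIND_MEASURE = re.compile(
    r"(Kd|Ki|IC50)\s*[=<>~≤≥]+\s*([0-9.eE+\-]+)\s*"
    r"(fM|pM|nM|uM|µM|μM|mM|M)\b")


@dataclass
class RejectedRecord:
    complex_id: str
    reason: str


def load_affinity_index(text: str, keep_ic50: bool = False
                        ) -> tuple[list[AffinityRecord], list[RejectedRecord]]:
    """Load an affinity index in PDBbind-INDEX or generic CSV dialect.

    Units are normalized to mol/L and pK = -log10(value) is computed.  IC50
    rows are excluded unless ``keep_ic50`` is set, mirroring the data-curation
    rule that only Kd/Ki labels serve as regression targets.  Malformed rows
    are collected into the rejects list rather than raising.
    """
    records: list[AffinityRecord] = []
    rejects: list[RejectedRecord] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "," in line:
            _load_csv_row(line, records, rejects, keep_ic50)
        else:
            _load_index_row(line, records, rejects, keep_ic50)
    return records, rejects


def _append(records, rejects, keep_ic50, complex_id, measurement, value, unit):
    if measurement == "IC50" and not keep_ic50:
        rejects.append(RejectedRecord(complex_id, "IC50-only measurement excluded"))
        return
    scale = _UNIT_TO_MOLAR.get(unit)
    if scale is None:
        rejects.append(RejectedRecord(complex_id, f"unknown unit {unit!r}"))
        return
    try:
        value = float(value)
    except ValueError:
        rejects.append(RejectedRecord(complex_id, f"unparsable value {value!r}"))
        return
    if value <= 0 or not math.isfinite(value):
        rejects.append(RejectedRecord(complex_id, f"non-positive value {value!r}"))
        return
    molar = value * scale
    records.append(AffinityRecord(complex_id=complex_id, measurement=measurement,
                                  value_molar=molar, pK=-math.log10(molar)))


def _load_index_row(line, records, rejects, keep_ic50):
    complex_id = line.split()[0]
    m = _PDBBIND_MEASURE.search(line)
    if m is None:
        rejects.append(RejectedRecord(complex_id, "no Kd/Ki/IC50 measurement found"))
        return
    _append(records, rejects, keep_ic50, complex_id, m.group(1), m.group(2), m.group(3))


def _load_csv_row(line, records, rejects, keep_ic50):
    row = next(csv.reader([line]))
    if len(row) < 4:
        rejects.append(RejectedRecord(row[0] if row else "?", "short CSV row"))
        return
    complex_id, measurement, value, unit = (f.strip() for f in row[:4])
    if complex_id.lower() in ("id", "complex_id"):  # header row
        return
    if measurement not in ("Kd", "Ki", "IC50"):
        rejects.append(RejectedRecord(complex_id, f"unknown measurement {measurement!r}"))
        return
    _append(records, rejects, keep_ic50, complex_id, measurement, value, unit)


def write_rejects_report(path, rejects: list[RejectedRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "reason"])
        for rej in rejects:
            writer.writerow([rej.complex_id, rej.reason])


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def build_complex(complex_id: str, mol2_text: str, pdb_text: str,
                  affinity: AffinityRecord | None = None,
                  radius: float = 6.0) -> ComplexRecord:
    ligand = parse_mol2(mol2_text)
    pocket = parse_pocket_pdb(pdb_text)
    seq = extract_pocket_sequence(pocket, ligand, radius=radius)
    return ComplexRecord(complex_id=complex_id, ligand=ligand, pocket=pocket,
                         pocket_sequence=seq, affinity=affinity)


def load_dataset(ligand_dir, pocket_dir, index_path, keep_ic50: bool = False,
                 radius: float = 6.0) -> tuple[list[ComplexRecord], list[RejectedRecord]]:
    """Load all complexes named in an index file from MOL2/PDB directories.

    Files are looked up as ``<id>_ligand.mol2`` / ``<id>_pocket.pdb`` either
    flat in the directory or under a per-complex subdirectory ``<id>/``.
    """
    from pathlib import Path

    ligand_dir, pocket_dir = Path(ligand_dir), Path(pocket_dir)
    with open(index_path) as fh:
        records, rejects = load_affinity_index(fh.read(), keep_ic50=keep_ic50)
    complexes = []
    for rec in records:
        try:
            mol2 = _find_file(ligand_dir, rec.complex_id, "_ligand.mol2")
            pdb = _find_file(pocket_dir, rec.complex_id, "_pocket.pdb")
            complexes.append(build_complex(rec.complex_id, mol2.read_text(),
                                           pdb.read_text(), affinity=rec, radius=radius))
        except (FileNotFoundError, ValueError) as exc:
            rejects.append(RejectedRecord(rec.complex_id, str(exc)))
    return complexes, rejects


def _find_file(root, complex_id, suffix):
    for candidate in (root / f"{complex_id}{suffix}", root / complex_id / f"{complex_id}{suffix}"):
        if candidate.exists():
            return candidate
    raise FileNotFoundError(f"missing {complex_id}{suffix} under {root}")
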