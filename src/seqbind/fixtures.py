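"""Seeded generators for synthetic complexes with planted affinities.

The generators emit the same text formats the readers consume: valence-legal
random small molecules as TRIPOS MOL2, Gly-like pocket residues placed at
controlled distances from the ligand as PDB, and affinity index files whose
pK values are a known linear function of computed ligand descriptors plus
Gaussian noise.  They replace curated complex databases as the test bed: the
planted coefficients act on descriptors the featurizer actually computes, so
end-to-end recovery exercises the whole chain, not just the regressor.

Geometric realism is not a goal: coordinates live in a 30 A box with only a
2.5 A minimum-separation rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import structure_io
from .featurization import DESCRIPTOR_SCHEMA, chemical_descriptors
from .structure_io import AffinityRecord, ComplexRecord, LigandStructure, PocketStructure

#: heavy-atom valence caps for the random-molecule sampler
_MAX_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}
_ELEMENTS = ["C", "C", "C", "C", "N", "O", "S"]  # carbon-rich draw

_RESIDUE_TYPES = list(structure_io.THREE_TO_ONE)[:20]  # canonical 3-letter codes


# ---------------------------------------------------------------------------
# ligand generation
# ---------------------------------------------------------------------------

def generate_ligand(seed: int, min_atoms: int = 5, max_atoms: int = 30
                    ) -> tuple[LigandStructure, str]:
    """Random tree + optional ring closures over {C,N,O,S}, all single bonds.

    Returns the parsed structure and the emitted MOL2 text; the emitted text
    re-parses to an isomorphic heavy-atom graph by construction.
    """
    if not (1 <= min_atoms <= max_atoms):
        raise ValueError("invalid atom-count range")
    rng = np.random.default_rng(seed)
    n = int(rng.integers(min_atoms, max_atoms + 1))
    elements = [str(rng.choice(_ELEMENTS)) for _ in range(n)]
    degree = [0] * n
    bonds: list[tuple[int, int]] = []
    for i in range(1, n):
        candidates = [j for j in range(i) if degree[j] < _MAX_VALENCE[elements[j]]]
        if not candidates:
            # all previous atoms saturated; widen the least-bonded one to carbon
            # (a tree on i nodes always has a node of degree <= 1 < 4)
            j_min = int(np.argmin(degree[:i]))
            elements[j_min] = "C"
            candidates = [j_min]
        parent = int(rng.choice(candidates))
        bonds.append((parent, i))
        degree[parent] += 1
        degree[i] += 1
    # occasional ring closure between valence-spare, non-adjacent atoms
    adjacency = {frozenset(b) for b in bonds}
    for _ in range(int(rng.integers(0, 3))):
        spare = [j for j in range(n) if degree[j] < _MAX_VALENCE[elements[j]]]
        if len(spare) < 2:
            break
        i, j = rng.choice(spare, size=2, replace=False)
        i, j = int(i), int(j)
        if i == j or frozenset((i, j)) in adjacency:
            continue
        bonds.append((min(i, j), max(i, j)))
        adjacency.add(frozenset((i, j)))
        degree[i] += 1
        degree[j] += 1

    coords = _embed_coords(n, bonds, rng)
    mol2 = write_mol2(f"LIG{seed}", elements, coords, bonds)
    return structure_io.parse_mol2(mol2), mol2


def _embed_coords(n: int, bonds: list[tuple[int, int]], rng) -> np.ndarray:
    """Place atoms by a bond-length random walk inside a 30 A box."""
    coords = np.zeros((n, 3))
    parent = {}
    for i, j in bonds:
        parent.setdefault(j, i)
    for i in range(1, n):
        base = coords[parent.get(i, i - 1)]
        for _ in range(20):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            candidate = base + 1.54 * direction
            if np.linalg.norm(coords[:i] - candidate, axis=1).min() > 1.0:
                break
        coords[i] = np.clip(candidate, -15.0, 15.0)
    return coords


def write_mol2(name: str, elements: list[str], coords: np.ndarray,
               bonds: list[tuple[int, int]]) -> str:
    lines = ["@<TRIPOS>MOLECULE", name,
             f"{len(elements)} {len(bonds)} 0 0 0", "SMALL", "NO_CHARGES", "",
             "@<TRIPOS>ATOM"]
    for i, (el, xyz) in enumerate(zip(elements, coords), start=1):
        lines.append(f"{i:>4} {el}{i:<3} {xyz[0]:>10.4f} {xyz[1]:>10.4f} "
                     f"{xyz[2]:>10.4f} {el:<5} 1 LIG 0.0000")
    lines.append("@<TRIPOS>BOND")
    for k, (i, j) in enumerate(bonds, start=1):
        lines.append(f"{k:>4} {i + 1:>4} {j + 1:>4} 1")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# pocket generation
# ---------------------------------------------------------------------------

def generate_pocket(seed: int, ligand: LigandStructure, n_inside: int,
                    n_outside: int, radius: float = 6.0
                    ) -> tuple[PocketStructure, str]:
    """Pocket with ``n_inside`` residues whose nearest-ligand-atom distance
    falls in [2.5, radius-0.1] A and ``n_outside`` residues in
    [radius+0.1, 15] A, as Gly-like 4-atom backbones."""
    if n_inside < 0 or n_outside < 0:
        raise ValueError("residue counts must be non-negative")
    rng = np.random.default_rng(seed)
    lig = ligand.heavy_coords()
    residues = []
    targets = ([(True, float(rng.uniform(2.5, radius - 0.1))) for _ in range(n_inside)]
               + [(False, float(rng.uniform(radius + 0.1, 15.0))) for _ in range(n_outside)])
    for idx, (inside, d_target) in enumerate(targets, start=1):
        resname = str(rng.choice(_RESIDUE_TYPES))
        atoms = _place_residue(lig, d_target, rng)
        residues.append((idx, resname, atoms))
    pdb = write_pocket_pdb(residues)
    return structure_io.parse_pocket_pdb(pdb), pdb


def _place_residue(lig: np.ndarray, d_target: float, rng,
                   max_tries: int = 200) -> np.ndarray:
    """Four collinear pseudo-atoms whose min distance to the ligand is d_target.

    The anchor point is found by bisection of the min-distance function along
    a random ray from a random ligand atom; trailing atoms extend outward.
    """
    diameter = float(np.linalg.norm(lig.max(0) - lig.min(0))) + 1.0
    for _ in range(max_tries):
        origin = lig[rng.integers(len(lig))]
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)

        def min_dist(t):
            return float(np.linalg.norm(lig - (origin + t * u), axis=1).min())

        lo, hi = 0.0, d_target + diameter
        if min_dist(hi) < d_target:
            continue
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if min_dist(mid) < d_target:
                lo = mid
            else:
                hi = mid
        anchor = origin + hi * u
        offsets = [0.0, 0.7, 1.4, 2.1]
        pts = np.array([anchor + off * u for off in offsets])
        dmins = [float(np.linalg.norm(lig - p, axis=1).min()) for p in pts]
        # anchor realizes the target; trailing atoms must not undercut it
        if abs(dmins[0] - d_target) < 1e-3 and min(dmins) >= d_target - 1e-3:
            return pts
    raise RuntimeError("could not place residue at the requested distance")


_BACKBONE = ["N", "CA", "C", "O"]


def write_pocket_pdb(residues) -> str:
    lines = []
    serial = 1
    for res_id, resname, atoms in residues:
        coords = np.asarray(atoms, dtype=float)
        for atom_name, xyz in zip(_BACKBONE, coords):
            element = atom_name[0]
            lines.append(
                f"ATOM  {serial:>5} {atom_name:^4} {resname:>3} A{res_id:>4}    "
                f"{xyz[0]:>8.3f}{xyz[1]:>8.3f}{xyz[2]:>8.3f}{1.0:>6.2f}{0.0:>6.2f}"
                f"          {element:>2}")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# planted-affinity datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedModel:
    """Affinity = intercept + beta . standardized(descriptors) + N(0, sigma^2)."""
    descriptors: tuple[str, ...] = ("MolWt", "MolLogP", "TPSA", "RingCount")
    beta: tuple[float, ...] = (1.0, 0.8, -0.5, 0.4)
    intercept: float = 7.0
    sigma: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if len(self.descriptors) != len(self.beta):
            raise ValueError("descriptors and beta must have equal length")
        unknown = set(self.descriptors) - set(DESCRIPTOR_SCHEMA)
        if unknown:
            raise ValueError(f"unknown descriptor names in planted model: {sorted(unknown)}")


@dataclass
class FixtureDataset:
    records: list[ComplexRecord]
    manifest: dict

    def __len__(self):
        return len(self.records)

    @property
    def y(self) -> np.ndarray:
        return np.array([r.affinity.pK for r in self.records])


def generate_dataset(n: int, planted: PlantedModel | None = None,
                     pocket_radius: float = 6.0) -> FixtureDataset:
    """n synthetic complexes with affinities from the planted model.

    Descriptors are standardized across the generated population before the
    linear map, which keeps pK mostly within [2, 12] at the default
    coefficients.  Same seed, same dataset, byte-identical manifest.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    planted = planted or PlantedModel()
    rng = np.random.default_rng(planted.seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n)

    ligands, pockets, mol2s, pdbs, seqs = [], [], [], [], []
    for i, s in enumerate(seeds):
        ligand, mol2 = generate_ligand(int(s))
        n_inside = int(rng.integers(5, 13))
        n_outside = int(rng.integers(2, 7))
        pocket, pdb = generate_pocket(int(s) + 1, ligand, n_inside, n_outside,
                                      radius=pocket_radius)
        seq = structure_io.extract_pocket_sequence(pocket, ligand, radius=pocket_radius)
        ligands.append(ligand)
        pockets.append(pocket)
        mol2s.append(mol2)
        pdbs.append(pdb)
        seqs.append(seq)

    cols = [DESCRIPTOR_SCHEMA.index(name) for name in planted.descriptors]
    desc = np.array([chemical_descriptors(lig)[cols] for lig in ligands])
    mean = desc.mean(axis=0)
    std = np.where(desc.std(axis=0) > 0, desc.std(axis=0), 1.0)
    z = (desc - mean) / std
    noise = rng.normal(0.0, planted.sigma, size=n) if planted.sigma > 0 else np.zeros(n)
    pk = planted.intercept + z @ np.array(planted.beta) + noise
    pk = np.clip(pk, 0.5, 13.5)  # keep Kd physically sensible

    records = []
    for i in range(n):
        cid = f"syn{i:04d}"
        affinity = AffinityRecord(complex_id=cid, measurement="Kd",
                                  value_molar=10.0 ** (-pk[i]), pK=float(pk[i]))
        records.append(ComplexRecord(complex_id=cid, ligand=ligands[i],
                                     pocket=pockets[i], pocket_sequence=seqs[i],
                                     affinity=affinity))
    manifest = {
        "n": n,
        "seed": planted.seed,
        "sigma": planted.sigma,
        "intercept": planted.intercept,
        "descriptors": list(planted.descriptors),
        "beta": list(planted.beta),
        "descriptor_mean": [round(float(v), 10) for v in mean],
        "descriptor_std": [round(float(v), 10) for v in std],
    }
    dataset = FixtureDataset(records=records, manifest=manifest)
    dataset._texts = (mol2s, pdbs)  # kept for write_dataset
    return dataset


def write_dataset(dataset: FixtureDataset, out_dir) -> None:
    """Write MOL2/PDB/index/manifest files readable by ``structure_io``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mol2s, pdbs = dataset._texts
    index_lines = ["id,type,value,unit"]
    for rec, mol2, pdb in zip(dataset.records, mol2s, pdbs):
        (out / f"{rec.complex_id}_ligand.mol2").write_text(mol2)
        (out / f"{rec.complex_id}_pocket.pdb").write_text(pdb)
        index_lines.append(
            f"{rec.complex_id},{rec.affinity.measurement},"
            f"{float(rec.affinity.value_molar)!r},M")
    (out / "index.csv").write_text("\n".join(index_lines) + "\n")
    (out / "manifest.json").write_text(
        json.dumps(dataset.manifest, indent=2, sort_keys=True) + "\n")
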