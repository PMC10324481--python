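"""Paired (Patterson, density) example generation.

The training task is: given the Patterson map of a small peptide in a P1 box,
predict its electron density.  This module produces those pairs either from
parsed PDB structures (dipeptide extraction, optional truncation to
dialanine) or from the built-in idealized dipeptide generator, then pushes
each molecule through the crystallographic pipeline:

    center on mass -> structure factors to d_min -> density + Patterson
    synthesis on the configured grid -> per-map normalization to [-1, 1].

Examples whose periodic images clash are rejected, mirroring what happens
when a large side chain does not fit the chosen cell.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from . import peptides
from .crystal import (
    Atom,
    AtomList,
    MapGrid,
    UnitCell,
    VoxelMap,
    density_from_reflections,
    normalize_map,
    patterson_from_reflections,
    structure_factors,
)

__all__ = [
    "DatasetConfig",
    "ExamplePair",
    "DatasetManifest",
    "Dataset",
    "extract_dipeptide",
    "truncate_to_dialanine",
    "center_by_mass",
    "clash_check",
    "synth_dipeptide",
    "make_example",
    "build_dataset",
]

# re-export: the generator lives with the geometry tables
synth_dipeptide = peptides.synth_dipeptide

#: atoms kept per residue when truncating to alanine
_ALANINE_ATOMS = ("N", "CA", "C", "O", "CB")


@dataclass(frozen=True)
class DatasetConfig:
    """Recipe for one dataset: geometry, chemistry and bookkeeping."""

    cell_edge: float = 10.0  # A, cubic P1 cell
    spacing: float = 0.5  # A per voxel
    d_min: float = 1.5  # A, high-resolution cutoff
    residue_alphabet: str = "ALA"  # "ALA" or "all20"
    truncate: bool = True  # truncate extracted dipeptides to dialanine
    clash_distance: float = 2.0  # A, periodic-image rejection threshold
    train_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cell_edge <= 0:
            raise ValueError("cell edge must be positive")
        if self.spacing > self.d_min / 2.0:
            raise ValueError("spacing must be <= d_min/2 (Nyquist)")
        if self.residue_alphabet not in ("ALA", "all20"):
            raise ValueError("residue_alphabet must be 'ALA' or 'all20'")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")

    @property
    def cell(self) -> UnitCell:
        return UnitCell.cubic(self.cell_edge)

    @property
    def grid(self) -> MapGrid:
        return MapGrid.from_spacing(self.cell, self.spacing)


@dataclass
class ExamplePair:
    """One training example: normalized Patterson input and density target."""

    patterson: VoxelMap
    density: VoxelMap
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.patterson.grid.shape != self.density.grid.shape:
            raise ValueError("patterson and density must share one grid")


@dataclass
class DatasetManifest:
    """Per-example records with split assignment; JSON-serializable."""

    config: DatasetConfig
    records: list[dict]
    summary: dict = field(default_factory=dict)

    def split_indices(self, split: str) -> list[int]:
        return [i for i, r in enumerate(self.records) if r["split"] == split]

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": dataclasses.asdict(self.config),
                "records": self.records,
                "summary": self.summary,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        obj = json.loads(text)
        return cls(DatasetConfig(**obj["config"]), obj["records"],
                   obj.get("summary", {}))


class Dataset:
    """In-memory dataset: aligned (N, nx, ny, nz) arrays plus the manifest."""

    def __init__(self, pattersons: np.ndarray, densities: np.ndarray,
                 manifest: DatasetManifest):
        if pattersons.shape != densities.shape:
            raise ValueError("patterson/density array shape mismatch")
        if len(pattersons) != len(manifest.records):
            raise ValueError("array length does not match manifest")
        self.pattersons = pattersons
        self.densities = densities
        self.manifest = manifest

    def __len__(self) -> int:
        return len(self.pattersons)

    @property
    def grid(self) -> MapGrid:
        return self.manifest.config.grid

    def split_arrays(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.manifest.split_indices(split)
        return self.pattersons[idx], self.densities[idx]

    def save(self, path: str | Path) -> None:
        """Write an HDF5 container with the JSON manifest embedded."""
        with h5py.File(path, "w") as f:
            f.create_dataset("patterson", data=self.pattersons.astype(np.float32))
            f.create_dataset("density", data=self.densities.astype(np.float32))
            f.attrs["manifest"] = self.manifest.to_json()

    @classmethod
    def load(cls, path: str | Path) -> "Dataset":
        with h5py.File(path, "r") as f:
            return cls(
                np.asarray(f["patterson"], dtype=float),
                np.asarray(f["density"], dtype=float),
                DatasetManifest.from_json(f.attrs["manifest"]),
            )


# ---------------------------------------------------------------------------
# molecule-level operations
# ---------------------------------------------------------------------------


def extract_dipeptide(structure, start_index: int, chain: str | None = None) -> AtomList:
    """All heavy atoms of two sequence-adjacent residues of a parsed structure.

    ``structure`` is the residue list produced by :func:`pattnet.io.read_pdb`
    (non-protein records already removed, first altloc kept).  The pair is
    (start_index, start_index + 1) in residue numbering of the selected chain;
    a numbering gap there is a chain break and raises.
    """
    residues = [r for r in structure if chain is None or r["chain"] == chain]
    by_num = {r["seqid"]: r for r in residues}
    if start_index not in by_num or start_index + 1 not in by_num:
        raise ValueError(
            f"no adjacent residue pair at position {start_index} "
            f"(chain break or out of range)"
        )
    atoms: list[Atom] = []
    for offset in (0, 1):
        res = by_num[start_index + offset]
        for a in res["atoms"]:
            if a["element"].upper() == "H":
                continue
            atoms.append(
                Atom(
                    element=a["element"],
                    xyz=np.asarray(a["xyz"], dtype=float),
                    name=a["name"],
                    resname=res["resname"],
                    res_index=offset + 1,
                )
            )
    if not atoms:
        raise ValueError("selected residues contain no heavy atoms")
    label = f"{by_num[start_index]['resname']}-{by_num[start_index + 1]['resname']}"
    return AtomList(atoms, label=label)


def truncate_to_dialanine(atoms: AtomList) -> AtomList:
    """Strip side chains beyond C-beta and rename both residues to ALA.

    Glycine keeps its four backbone atoms and gains no C-beta: truncation
    never invents atoms.  A missing backbone atom is a data error.
    """
    out: list[Atom] = []
    seen: dict[int, set] = {1: set(), 2: set()}
    for a in atoms:
        if a.name in _ALANINE_ATOMS:
            out.append(dataclasses.replace(a, resname="ALA"))
            seen.setdefault(a.res_index, set()).add(a.name)
    for ri in (1, 2):
        missing = set(peptides.BACKBONE_ATOMS) - seen.get(ri, set())
        if missing:
            raise ValueError(f"residue {ri} missing backbone atoms {sorted(missing)}")
    return AtomList(out, label=atoms.label)


def center_by_mass(atoms: AtomList, cell: UnitCell) -> AtomList:
    """Rigid translation placing the mass-weighted centroid at the cell center."""
    coords = atoms.coords()
    masses = atoms.masses()
    centroid = masses @ coords / masses.sum()
    target = cell.edges / 2.0
    return atoms.translated(target - centroid)


def clash_check(atoms: AtomList, cell: UnitCell, min_dist: float = 2.0,
                bond_cutoff: float = 1.9) -> bool:
    """True (pass) iff no forbidden contact below ``min_dist`` exists.

    Uses minimum-image distances under the cell's periodicity.  Covalently
    bonded pairs — direct distance below ``bond_cutoff`` with the direct
    distance also being the minimum image — are legitimate; everything else
    below ``min_dist``, in particular contacts with periodic neighbors,
    fails.  An atom's distance to its own images is the shortest cell edge.
    """
    if float(np.min(cell.edges)) < min_dist:
        return False
    coords = atoms.coords()
    n = len(coords)
    if n < 2:
        return True
    delta = coords[:, None, :] - coords[None, :, :]
    d_direct = np.linalg.norm(delta, axis=-1)
    frac = delta / cell.edges
    frac -= np.rint(frac)
    d_mic = np.linalg.norm(frac * cell.edges, axis=-1)
    iu = np.triu_indices(n, k=1)
    direct, mic = d_direct[iu], d_mic[iu]
    bonded = (direct < bond_cutoff) & (np.abs(mic - direct) < 1e-9)
    return not bool(np.any((mic < min_dist) & ~bonded))


def make_example(atoms: AtomList, config: DatasetConfig,
                 meta: dict | None = None) -> ExamplePair:
    """Full pipeline from a molecule to a normalized (Patterson, density) pair."""
    cell, grid = config.cell, config.grid
    centered = center_by_mass(atoms, cell)
    rset = structure_factors(centered, cell, config.d_min)
    density = normalize_map(density_from_reflections(rset, grid))
    patterson = normalize_map(patterson_from_reflections(rset, grid))
    info = {"label": atoms.label, "n_atoms": len(atoms)}
    if meta:
        info.update(meta)
    return ExamplePair(patterson=patterson, density=density, meta=info)


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------


def _synthetic_molecules(config: DatasetConfig, n_examples: int,
                         rng: np.random.Generator):
    """Yield (molecule, meta) pairs from the idealized dipeptide generator."""
    attempts = 0
    max_attempts = 50 * n_examples + 100  # caller stops once filled
    while attempts < max_attempts:
        attempts += 1
        if config.residue_alphabet == "ALA":
            pair = ("ALA", "ALA")
        else:
            pair = tuple(rng.choice(peptides.AMINO_ACIDS, size=2))
        seed = int(rng.integers(0, 2**31 - 1))
        mol = peptides.synth_dipeptide(pair, seed)
        if config.truncate:
            mol = truncate_to_dialanine(mol)
        meta = {"source": f"synthetic:{pair[0]}-{pair[1]}:{seed}",
                "residues": list(pair)}
        yield mol, meta


def build_dataset(
    config: DatasetConfig,
    n_examples: int,
    sources: Sequence[tuple[AtomList, dict]] | None = None,
) -> Dataset:
    """Generate a dataset of paired maps with a train/validation split.

    ``sources`` may supply pre-extracted molecules as (AtomList, meta) pairs
    (meta must carry a ``source`` id); otherwise molecules come from the
    seeded synthetic dipeptide generator.  Clash failures are skipped and
    logged in the manifest summary.  The split is assigned at the level of
    source ids so no source leaks across splits.
    """
    if n_examples < 1:
        raise ValueError("n_examples must be >= 1")
    rng = np.random.default_rng(config.seed)

    pattersons, densities, records = [], [], []
    n_rejected = 0
    if sources is None:
        stream = _synthetic_molecules(config, n_examples, rng)
    else:
        stream = ((mol, dict(meta)) for mol, meta in sources)

    for mol, meta in stream:
        if len(records) >= n_examples:
            break
        centered = center_by_mass(mol, config.cell)
        if not clash_check(centered, config.cell, config.clash_distance):
            n_rejected += 1
            continue
        pair = make_example(mol, config, meta)
        pattersons.append(pair.patterson.values)
        densities.append(pair.density.values)
        records.append({"index": len(records), **pair.meta})

    if not records:
        raise ValueError("no examples survived clash rejection")

    # source-level split: every example of one source lands in one split
    source_ids = sorted({r["source"] for r in records})
    shuffled = list(source_ids)
    np.random.default_rng(config.seed + 1).shuffle(shuffled)
    n_train_sources = max(1, int(round(config.train_fraction * len(shuffled))))
    if n_train_sources == len(shuffled) and len(shuffled) > 1:
        n_train_sources -= 1
    train_sources = set(shuffled[:n_train_sources])
    for r in records:
        r["split"] = "train" if r["source"] in train_sources else "validation"

    manifest = DatasetManifest(config, records, summary={"n_rejected": n_rejected})
    return Dataset(np.array(pattersons), np.array(densities), manifest)
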