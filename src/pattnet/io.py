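"""File formats: PDB structures in, CCP4/MRC map volumes in and out.

Maps are written with axis order x, y, z fastest-to-slowest matching the
in-memory (ix, iy, iz) indexing, orthogonal P1 cells only.  PDB reading keeps
ATOM records (HETATM and waters are non-protein and dropped), the first
alternate location, and infers elements from atom names when the element
column is blank.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np

from .crystal import MapGrid, UnitCell, VoxelMap

__all__ = ["read_pdb", "write_map", "read_map"]

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE",  # selenomethionine is protein
}


def _validate_pdb_text(path: Path) -> None:
    """Pre-scan coordinate records so malformed lines fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ValueError(f"{path}:{lineno}: truncated coordinate record")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: unparseable coordinates"
                ) from exc


def read_pdb(path: str | Path) -> list[dict]:
    """Parse a PDB file into a residue list.

    Returns a list of dicts ``{chain, seqid, resname, atoms}`` where each
    atom is ``{name, element, xyz, altloc}``.  Only protein residues from
    ATOM records survive; hydrogens are kept here (dipeptide extraction
    drops them) and only the first altloc of each atom is retained.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_text(path)
    structure = gemmi.read_pdb(str(path))
    structure.setup_entities()
    residues = []
    model = structure[0]
    for chain in model:
        for res in chain:
            if res.het_flag != "A" or res.name not in _AA3:
                continue  # non-protein atoms are removed
            atoms = []
            seen = set()
            for atom in res:
                if atom.name in seen:
                    continue  # later altloc
                seen.add(atom.name)
                element = atom.element.name.upper()
                if not element:
                    element = atom.name.lstrip("0123456789")[0]
                atoms.append(
                    {
                        "name": atom.name,
                        "element": element,
                        "xyz": [atom.pos.x, atom.pos.y, atom.pos.z],
                        "altloc": atom.altloc or "",
                    }
                )
            residues.append(
                {
                    "chain": chain.name,
                    "seqid": res.seqid.num,
                    "resname": res.name,
                    "atoms": atoms,
                }
            )
    return residues


def write_map(vmap: VoxelMap, path: str | Path) -> None:
    """Write a VoxelMap as a CCP4/MRC volume (P1, orthogonal cell)."""
    grid = gemmi.FloatGrid(np.asarray(vmap.values, dtype=np.float32))
    cell = vmap.grid.cell
    grid.unit_cell = gemmi.UnitCell(cell.a, cell.b, cell.c, 90, 90, 90)
    grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def read_map(path: str | Path, role: str = "density") -> VoxelMap:
    """Read a CCP4/MRC volume; rejects non-orthogonal cells.

    The file's axis order is normalized to x fastest so the returned values
    index as (ix, iy, iz); cell lengths are preserved exactly.
    """
    ccp4 = gemmi.read_ccp4_map(str(path))
    ccp4.setup(float("nan"))  # reorder axes to x,y,z; full cell
    uc = ccp4.grid.unit_cell
    if not (
        abs(uc.alpha - 90) < 1e-6
        and abs(uc.beta - 90) < 1e-6
        and abs(uc.gamma - 90) < 1e-6
    ):
        raise ValueError("only orthogonal (90,90,90) cells are supported")
    values = np.array(ccp4.grid, copy=True, dtype=float)
    cell = UnitCell(uc.a, uc.b, uc.c)
    grid = MapGrid(cell, *values.shape)
    return VoxelMap(grid, values, role=role)
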