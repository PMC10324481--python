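import numpy as np
import pytest

from pattnet.crystal import Atom, AtomList, MapGrid, UnitCell


def pdb_line(serial, name, resname, chain, resseq, xyz, element="",
             altloc=" ", record="ATOM"):
    """One fixed-column PDB coordinate record."""
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:>5d} {name_field}{altloc}{resname:<3s} {chain}"
        f"{resseq:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.0:6.2f}{15.0:6.2f}          {element:>2s}\n"
    )


@pytest.fixture
def small_cell():
    return UnitCell.cubic(8.0)


@pytest.fixture
def small_grid(small_cell):
    return MapGrid(small_cell, 16, 16, 16)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_atoms(rng, cell, n):
    elements = ["C", "N", "O", "S"]
    return AtomList(
        [Atom(element=elements[i % 4], xyz=rng.random(3) * cell.edges)
         for i in range(n)]
    )


@pytest.fixture
def demo_pdb(tmp_path):
    """Synthetic four-residue chain with a numbering gap, altlocs and HETATM.

    Chain A: GLY 1 - ALA 2 - SER 3, gap, LYS 5 - SER 6.  Coordinates are
    plausible spacings only; parsing and extraction logic is what is tested.
    """
    rows = []
    serial = iter(range(1, 100))
    base = np.array([0.0, 0.0, 0.0])

    def add(resname, resseq, names, origin, altloc_extra=None):
        for i, name in enumerate(names):
            xyz = origin + np.array([1.4 * i, 0.3 * i, 0.1 * i])
            el = name[0] if name[0] in "CNOS" else "C"
            rows.append(pdb_line(next(serial), name, resname, "A", resseq, xyz, el))
            if altloc_extra == name:
                rows.append(
                    pdb_line(next(serial), name, resname, "A", resseq,
                             xyz + 0.3, el, altloc="B")
                )

    add("GLY", 1, ["N", "CA", "C", "O"], base)
    add("ALA", 2, ["N", "CA", "C", "O", "CB"], base + [0, 3, 0],
        altloc_extra="CB")
    add("SER", 3, ["N", "CA", "C", "O", "CB", "OG"], base + [0, 6, 0])
    add("LYS", 5, ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"],
        base + [0, 9, 0])
    add("SER", 6, ["N", "CA", "C", "O", "CB", "OG"], base + [0, 12, 0])
    rows.append(pdb_line(next(serial), "O", "HOH", "A", 101, [20.0, 20, 20],
                         "O", record="HETATM"))
    path = tmp_path / "demo.pdb"
    path.write_text("".join(rows) + "END\n")
    return path
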