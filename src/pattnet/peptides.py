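"""Idealized heavy-atom dipeptide geometry.

Builds dipeptides of the 20 standard amino acids from internal coordinates
(standard bond lengths and angles), with backbone torsions drawn from broadly
allowed alpha/beta rectangles and side-chain torsions uniform.  Both residues
are built with fixed L chirality at the alpha carbon, which is what lets a
Patterson-to-density model resolve the centrosymmetric ambiguity on real
peptides.  Geometry is plausible rather than energy-minimized: rings are
idealized planar (proline approximated), and no clash relaxation is done.

Atoms are produced with Cartesian coordinates via the natural-extension
reference frame (NeRF) construction: each new atom D is placed from three
previously placed atoms A-B-C given bond length |CD|, angle B-C-D and torsion
A-B-C-D.
"""

from __future__ import annotations

import numpy as np

from .crystal import Atom, AtomList

__all__ = [
    "AMINO_ACIDS",
    "HEAVY_ATOM_COUNTS",
    "BACKBONE_ATOMS",
    "place_atom",
    "chiral_volume",
    "synth_dipeptide",
]

#: Three-letter codes of the 20 standard amino acids.
AMINO_ACIDS = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# bond lengths (A)
_CC = 1.52  # sp3 C-C
_CAR = 1.39  # aromatic C-C
_CN = 1.47  # C-N single
_CO = 1.43  # C-O single
_CS = 1.81  # C-S
_CO2 = 1.25  # carboxylate C-O
_CND = 1.34  # amide / aromatic C-N

# Side-chain internal coordinates per residue.  Each entry places one atom:
#   (name, ref_atoms (A, B, C), bond, angle_deg, torsion)
# torsion is a number (degrees) or "chi" for a uniformly sampled rotamer
# torsion; refs name atoms already placed in the same residue.
_SIDE_CHAINS: dict[str, list[tuple]] = {
    "ALA": [],
    "GLY": [],  # no CB at all
    "SER": [("OG", ("N", "CA", "CB"), _CO, 110.5, "chi")],
    "CYS": [("SG", ("N", "CA", "CB"), _CS, 113.0, "chi")],
    "THR": [
        ("OG1", ("N", "CA", "CB"), _CO, 109.5, "chi"),
        ("CG2", ("OG1", "CA", "CB"), _CC, 110.5, -120.0),
    ],
    "VAL": [
        ("CG1", ("N", "CA", "CB"), _CC, 110.5, "chi"),
        ("CG2", ("CG1", "CA", "CB"), _CC, 110.5, 120.0),
    ],
    "LEU": [
        ("CG", ("N", "CA", "CB"), _CC, 116.0, "chi"),
        ("CD1", ("CA", "CB", "CG"), _CC, 110.5, "chi"),
        ("CD2", ("CD1", "CB", "CG"), _CC, 110.5, 120.0),
    ],
    "ILE": [
        ("CG1", ("N", "CA", "CB"), _CC, 110.5, "chi"),
        ("CG2", ("CG1", "CA", "CB"), _CC, 110.5, -120.0),
        ("CD1", ("CA", "CB", "CG1"), _CC, 113.0, "chi"),
    ],
    "MET": [
        ("CG", ("N", "CA", "CB"), _CC, 114.0, "chi"),
        ("SD", ("CA", "CB", "CG"), _CS, 112.7, "chi"),
        ("CE", ("CB", "CG", "SD"), _CS, 100.2, "chi"),
    ],
    "PRO": [
        # ring closed only approximately; idealized flat pucker
        ("CG", ("N", "CA", "CB"), _CC, 104.5, 30.0),
        ("CD", ("CA", "CB", "CG"), _CC, 106.0, -35.0),
    ],
    "ASP": [
        ("CG", ("N", "CA", "CB"), _CC, 112.6, "chi"),
        ("OD1", ("CA", "CB", "CG"), _CO2, 118.4, "chi"),
        ("OD2", ("OD1", "CB", "CG"), _CO2, 118.4, 180.0),
    ],
    "ASN": [
        ("CG", ("N", "CA", "CB"), _CC, 112.6, "chi"),
        ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, "chi"),
        ("ND2", ("OD1", "CB", "CG"), _CND, 116.4, 180.0),
    ],
    "GLU": [
        ("CG", ("N", "CA", "CB"), _CC, 114.0, "chi"),
        ("CD", ("CA", "CB", "CG"), _CC, 112.6, "chi"),
        ("OE1", ("CB", "CG", "CD"), _CO2, 118.4, "chi"),
        ("OE2", ("OE1", "CG", "CD"), _CO2, 118.4, 180.0),
    ],
    "GLN": [
        ("CG", ("N", "CA", "CB"), _CC, 114.0, "chi"),
        ("CD", ("CA", "CB", "CG"), _CC, 112.6, "chi"),
        ("OE1", ("CB", "CG", "CD"), 1.23, 120.8, "chi"),
        ("NE2", ("OE1", "CG", "CD"), _CND, 116.4, 180.0),
    ],
    "LYS": [
        ("CG", ("N", "CA", "CB"), _CC, 114.0, "chi"),
        ("CD", ("CA", "CB", "CG"), _CC, 111.3, "chi"),
        ("CE", ("CB", "CG", "CD"), _CC, 111.3, "chi"),
        ("NZ", ("CG", "CD", "CE"), _CN, 111.5, "chi"),
    ],
    "ARG": [
        ("CG", ("N", "CA", "CB"), _CC, 114.0, "chi"),
        ("CD", ("CA", "CB", "CG"), _CC, 111.3, "chi"),
        ("NE", ("CB", "CG", "CD"), _CN, 112.0, "chi"),
        ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, "chi"),
        ("NH1", ("CD", "NE", "CZ"), _CND, 120.0, 0.0),
        ("NH2", ("NH1", "NE", "CZ"), _CND, 120.0, 180.0),
    ],
    "HIS": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, "chi"),
        ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, "chi"),
        ("CD2", ("ND1", "CB", "CG"), 1.36, 131.0, 180.0),
        ("CE1", ("CB", "CG", "ND1"), 1.32, 109.2, 180.0),
        ("NE2", ("CB", "CG", "CD2"), 1.37, 107.2, 180.0),
    ],
    "PHE": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, "chi"),
        ("CD1", ("CA", "CB", "CG"), _CAR, 120.7, "chi"),
        ("CD2", ("CD1", "CB", "CG"), _CAR, 120.7, 180.0),
        ("CE1", ("CB", "CG", "CD1"), _CAR, 120.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), _CAR, 120.0, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), _CAR, 120.0, 0.0),
    ],
    "TYR": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, "chi"),
        ("CD1", ("CA", "CB", "CG"), _CAR, 120.7, "chi"),
        ("CD2", ("CD1", "CB", "CG"), _CAR, 120.7, 180.0),
        ("CE1", ("CB", "CG", "CD1"), _CAR, 120.0, 180.0),
        ("CE2", ("CB", "CG", "CD2"), _CAR, 120.0, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), _CAR, 120.0, 0.0),
        ("OH", ("CD1", "CE1", "CZ"), 1.37, 120.0, 180.0),
    ],
    "TRP": [
        ("CG", ("N", "CA", "CB"), 1.50, 113.8, "chi"),
        ("CD1", ("CA", "CB", "CG"), 1.37, 127.0, "chi"),
        ("CD2", ("CD1", "CB", "CG"), 1.43, 126.6, 180.0),
        ("NE1", ("CB", "CG", "CD1"), 1.38, 110.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.41, 107.3, 180.0),
        ("CE3", ("CE2", "CG", "CD2"), 1.40, 133.9, 180.0),
        ("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.4, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.6, 180.0),
        ("CH2", ("CD2", "CE3", "CZ3"), 1.37, 121.1, 0.0),
    ],
}

#: Heavy-atom counts of each residue inside a chain (no terminal OXT).
HEAVY_ATOM_COUNTS = {
    name: 4 + (0 if name == "GLY" else 1) + len(chain)
    for name, chain in _SIDE_CHAINS.items()
}

_ELEMENT_FROM_NAME_START = {"C": "C", "N": "N", "O": "O", "S": "S"}


def _element_of(atom_name: str) -> str:
    return _ELEMENT_FROM_NAME_START[atom_name[0]]


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom D from frame A-B-C.

    |CD| = bond, angle(B,C,D) = angle_deg, torsion(A,B,C,D) = torsion_deg.
    """
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def chiral_volume(n: np.ndarray, ca: np.ndarray, c: np.ndarray,
                  cb: np.ndarray) -> float:
    """Signed volume (N-CA) . [(C-CA) x (CB-CA)]; positive for L-amino acids."""
    return float(np.dot(n - ca, np.cross(c - ca, cb - ca)))


def _sample_phi_psi(rng: np.random.Generator) -> tuple[float, float]:
    """Backbone torsions from broad alpha/beta rectangles of the allowed region."""
    if rng.random() < 0.5:  # alpha basin
        return rng.uniform(-90.0, -50.0), rng.uniform(-60.0, -20.0)
    return rng.uniform(-150.0, -90.0), rng.uniform(100.0, 160.0)  # beta basin


def _build_residue_side_chain(resname: str, pos: dict[str, np.ndarray],
                              rng: np.random.Generator) -> list[str]:
    """Append side-chain atoms beyond CB to ``pos``; returns names in order."""
    names = []
    for name, (ra, rb, rc), bond, angle, torsion in _SIDE_CHAINS[resname]:
        tor = rng.uniform(-180.0, 180.0) if torsion == "chi" else float(torsion)
        pos[name] = place_atom(pos[ra], pos[rb], pos[rc], bond, angle, tor)
        names.append(name)
    return names


def synth_dipeptide(residue_pair: tuple[str, str] | str, seed: int) -> AtomList:
    """Deterministic idealized heavy-atom dipeptide.

    Parameters
    ----------
    residue_pair:
        Two three-letter codes, e.g. ``("ALA", "ALA")`` or ``"ALA-ALA"``.
    seed:
        Seeds backbone and side-chain torsion sampling; the same
        (pair, seed) always yields the identical atom list.
    """
    if isinstance(residue_pair, str):
        residue_pair = tuple(residue_pair.split("-"))  # type: ignore[assignment]
    res1, res2 = (r.upper() for r in residue_pair)
    for r in (res1, res2):
        if r not in _SIDE_CHAINS:
            raise ValueError(f"unknown residue code {r!r}")
    rng = np.random.default_rng(seed)
    phi2, _ = _sample_phi_psi(rng)  # phi of residue 2
    _, psi1 = _sample_phi_psi(rng)  # psi of residue 1
    psi2 = _sample_phi_psi(rng)[1]  # orients the terminal carbonyl

    atoms: list[Atom] = []

    def emit(res_index: int, resname: str, name: str, xyz: np.ndarray) -> None:
        atoms.append(
            Atom(element=_element_of(name), xyz=xyz, name=name,
                 resname=resname, res_index=res_index)
        )

    # residue 1 backbone seed frame
    p: dict[str, np.ndarray] = {}
    p["N"] = np.array([0.0, 0.0, 0.0])
    p["CA"] = np.array([1.458, 0.0, 0.0])
    ang = np.deg2rad(111.0)  # N-CA-C
    p["C"] = p["CA"] + 1.525 * np.array([-np.cos(ang), np.sin(ang), 0.0])
    # CB via improper torsion chosen for L chirality (positive chiral volume)
    if res1 != "GLY":
        p["CB"] = place_atom(p["N"], p["C"], p["CA"], 1.53, 110.5, 123.0)
        if chiral_volume(p["N"], p["CA"], p["C"], p["CB"]) < 0:
            p["CB"] = place_atom(p["N"], p["C"], p["CA"], 1.53, 110.5, -123.0)
    p["O"] = place_atom(p["N"], p["CA"], p["C"], 1.231, 120.5, psi1 + 180.0)

    emit(1, res1, "N", p["N"])
    emit(1, res1, "CA", p["CA"])
    emit(1, res1, "C", p["C"])
    emit(1, res1, "O", p["O"])
    if res1 != "GLY":
        emit(1, res1, "CB", p["CB"])
        for name in _build_residue_side_chain(res1, p, rng):
            emit(1, res1, name, p[name])

    # peptide bond and residue 2 backbone (omega fixed trans)
    q: dict[str, np.ndarray] = {}
    q["N"] = place_atom(p["N"], p["CA"], p["C"], 1.329, 116.2, psi1)
    q["CA"] = place_atom(p["CA"], p["C"], q["N"], 1.458, 121.7, 180.0)
    q["C"] = place_atom(p["C"], q["N"], q["CA"], 1.525, 111.0, phi2)
    q["O"] = place_atom(q["N"], q["CA"], q["C"], 1.231, 120.5, psi2 + 180.0)
    if res2 != "GLY":
        q["CB"] = place_atom(q["N"], q["C"], q["CA"], 1.53, 110.5, 123.0)
        if chiral_volume(q["N"], q["CA"], q["C"], q["CB"]) < 0:
            q["CB"] = place_atom(q["N"], q["C"], q["CA"], 1.53, 110.5, -123.0)

    emit(2, res2, "N", q["N"])
    emit(2, res2, "CA", q["CA"])
    emit(2, res2, "C", q["C"])
    emit(2, res2, "O", q["O"])
    if res2 != "GLY":
        emit(2, res2, "CB", q["CB"])
        for name in _build_residue_side_chain(res2, q, rng):
            emit(2, res2, name, q[name])

    return AtomList(atoms, label=f"{res1}-{res2}/seed{seed}")
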