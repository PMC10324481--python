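"""Crystallographic core: reflections, structure factors, density and Patterson synthesis.

All cells are primitive (P1) orthogonal boxes with 90 degree angles.  Maps are
periodic real fields sampled on a regular voxel grid; voxel index ``i`` on an
axis with ``n`` voxels corresponds to fractional coordinate ``i / n`` (0-based,
half-open, index ``n`` wraps to 0).

Structure factors follow the crystallographic convention

    F(h,k,l) = sum_j f_j * g_j(d) * exp(+2*pi*i * (h x_j + k y_j + l z_j))

with ``f_j`` a per-element point-scatterer weight (the atomic number by
default) and ``g_j(d) = exp(-B/(4 d^2))`` an isotropic displacement
attenuation that damps series-termination ripple.  Density synthesis is the
inverse transform with prefactor ``1/V``; the Patterson synthesis squares the
amplitudes and zeroes the phases, producing the autocorrelation of the
band-limited density.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ELEMENT_NUMBERS",
    "ELEMENT_MASSES",
    "DEFAULT_B_ISO",
    "UnitCell",
    "MapGrid",
    "Atom",
    "AtomList",
    "ReflectionSet",
    "VoxelMap",
    "enumerate_hkl",
    "structure_factors",
    "density_from_reflections",
    "patterson_from_reflections",
    "reflections_from_density",
    "normalize_map",
]

# Point-scatterer weights (atomic numbers) and masses for the elements found
# in heavy-atom protein models.
ELEMENT_NUMBERS = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "P": 15, "SE": 34}
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}

#: Global isotropic displacement parameter (A^2) applied to every atom unless
#: overridden per atom; damps high-resolution termination ripple.
DEFAULT_B_ISO = 15.0


@dataclass(frozen=True)
class UnitCell:
    """Orthogonal P1 unit cell with edges in Angstrom (angles fixed at 90)."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError("unit-cell edges must be positive")

    @property
    def volume(self) -> float:
        """Cell volume V = a*b*c in A^3."""
        return self.a * self.b * self.c

    @property
    def edges(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c], dtype=float)

    @classmethod
    def cubic(cls, edge: float) -> "UnitCell":
        return cls(edge, edge, edge)


@dataclass(frozen=True)
class MapGrid:
    """Voxel sampling of a unit cell: ``n`` voxels per axis, spacing = edge/n."""

    cell: UnitCell
    nx: int
    ny: int
    nz: int

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("voxel counts must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel spacing in Angstrom."""
        return self.cell.edges / np.array(self.shape, dtype=float)

    @classmethod
    def from_spacing(cls, cell: UnitCell, spacing: float, even: bool = True) -> "MapGrid":
        """Grid with counts ``round(edge / spacing)``, rounded up to even if asked."""
        counts = np.rint(cell.edges / spacing).astype(int)
        if even:
            counts += counts % 2
        return cls(cell, int(counts[0]), int(counts[1]), int(counts[2]))


@dataclass
class Atom:
    """A point scatterer.

    Coordinates are Cartesian Angstrom; fractional coordinates are derived
    relative to a cell when needed.  ``f`` is the scattering weight in
    electrons, ``b_iso`` the isotropic displacement parameter in A^2.
    """

    element: str
    xyz: np.ndarray
    f: float | None = None
    b_iso: float = DEFAULT_B_ISO
    mass: float | None = None
    name: str = ""
    resname: str = ""
    res_index: int = 0

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        el = self.element.upper()
        if self.f is None:
            if el not in ELEMENT_NUMBERS:
                raise ValueError(f"no scattering weight for element {self.element!r}")
            self.f = float(ELEMENT_NUMBERS[el])
        if self.mass is None:
            if el not in ELEMENT_MASSES:
                raise ValueError(f"no mass for element {self.element!r}")
            self.mass = float(ELEMENT_MASSES[el])
        if self.f <= 0:
            raise ValueError("scattering weight must be positive")
        if self.mass <= 0:
            raise ValueError("mass must be positive")


@dataclass
class AtomList:
    """Ordered collection of atoms forming the unit-cell contents."""

    atoms: list[Atom]
    label: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    def coords(self) -> np.ndarray:
        """Cartesian coordinates, shape (N, 3)."""
        return np.array([a.xyz for a in self.atoms], dtype=float).reshape(-1, 3)

    def fractional(self, cell: UnitCell) -> np.ndarray:
        """Fractional coordinates wrapped into [0, 1), shape (N, 3)."""
        return np.mod(self.coords() / cell.edges, 1.0)

    def weights(self) -> np.ndarray:
        return np.array([a.f for a in self.atoms], dtype=float)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def b_factors(self) -> np.ndarray:
        return np.array([a.b_iso for a in self.atoms], dtype=float)

    def translated(self, shift_xyz: Sequence[float]) -> "AtomList":
        """Rigidly translated copy (Cartesian shift in Angstrom)."""
        shift = np.asarray(shift_xyz, dtype=float)
        return AtomList(
            [dataclasses.replace(a, xyz=a.xyz + shift) for a in self.atoms],
            label=self.label,
        )

    def inverted(self, center_xyz: Sequence[float]) -> "AtomList":
        """Point inversion through a Cartesian center (the centrosymmetric twin)."""
        center = np.asarray(center_xyz, dtype=float)
        return AtomList(
            [dataclasses.replace(a, xyz=2.0 * center - a.xyz) for a in self.atoms],
            label=self.label,
        )


class ReflectionSet:
    """Friedel-unique reflections with amplitude and phase.

    Stored as parallel arrays ``hkl`` (N, 3) int, ``amplitude`` (N,) and
    ``phase_deg`` (N,) with phases normalized to (-180, 180].  The Friedel
    mate F(-h,-k,-l) is implied as the complex conjugate.  F(0,0,0) is kept
    out of the set by default (experimental data lack it); synthesis routines
    accept it explicitly via ``f000``.
    """

    def __init__(
        self,
        cell: UnitCell,
        d_min: float,
        hkl: np.ndarray,
        amplitude: np.ndarray | None = None,
        phase_deg: np.ndarray | None = None,
        f000: float | None = None,
    ):
        self.cell = cell
        self.d_min = float(d_min)
        self.hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
        n = len(self.hkl)
        self.amplitude = (
            np.zeros(n) if amplitude is None else np.asarray(amplitude, dtype=float)
        )
        self.phase_deg = (
            np.zeros(n) if phase_deg is None else np.asarray(phase_deg, dtype=float)
        )
        self.f000 = f000
        if len(self.amplitude) != n or len(self.phase_deg) != n:
            raise ValueError("hkl / amplitude / phase length mismatch")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitudes must be non-negative")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def complex_values(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * np.deg2rad(self.phase_deg))

    def d_spacings(self) -> np.ndarray:
        """Interplanar spacing d(h,k,l) = 1/sqrt(h^2/a^2 + k^2/b^2 + l^2/c^2)."""
        inv_d2 = np.sum((self.hkl / self.cell.edges) ** 2, axis=1)
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(inv_d2)

    def copy_with(self, amplitude=None, phase_deg=None, f000="keep") -> "ReflectionSet":
        return ReflectionSet(
            self.cell,
            self.d_min,
            self.hkl.copy(),
            self.amplitude.copy() if amplitude is None else amplitude,
            self.phase_deg.copy() if phase_deg is None else phase_deg,
            self.f000 if f000 == "keep" else f000,
        )

    # -- text serialization -------------------------------------------------

    def to_tsv(self) -> str:
        """Tab-separated export: header lines (cell, d_min), then h k l |F| phase."""
        buf = io.StringIO()
        buf.write(f"# cell\t{self.cell.a:.6f}\t{self.cell.b:.6f}\t{self.cell.c:.6f}\n")
        buf.write(f"# d_min\t{self.d_min:.6f}\n")
        buf.write("h\tk\tl\tamplitude\tphase_deg\n")
        for (h, k, l), amp, ph in zip(self.hkl, self.amplitude, self.phase_deg):
            buf.write(f"{h}\t{k}\t{l}\t{amp:.10g}\t{ph:.10g}\n")
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "ReflectionSet":
        cell = None
        d_min = None
        rows = []
        for line in text.splitlines():
            if line.startswith("# cell"):
                parts = line.split("\t")[1:]
                cell = UnitCell(float(parts[0]), float(parts[1]), float(parts[2]))
            elif line.startswith("# d_min"):
                d_min = float(line.split("\t")[1])
            elif line and not line.startswith(("#", "h\t")):
                rows.append(line.split("\t"))
        if cell is None or d_min is None:
            raise ValueError("missing cell or d_min header")
        arr = np.array(rows, dtype=float).reshape(-1, 5)
        return cls(cell, d_min, arr[:, :3].astype(int), arr[:, 3], arr[:, 4])


@dataclass
class VoxelMap:
    """Periodic real 3D field on a MapGrid; role is 'density' or 'patterson'."""

    grid: MapGrid
    values: np.ndarray
    role: str = "density"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"value shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.role not in ("density", "patterson"):
            raise ValueError(f"unknown map role {self.role!r}")


# ---------------------------------------------------------------------------
# reflection enumeration and structure factors
# ---------------------------------------------------------------------------


def _wrap_phase_deg(phase: np.ndarray) -> np.ndarray:
    """Normalize phases to (-180, 180]."""
    wrapped = np.mod(-np.asarray(phase) + 180.0, 360.0)
    return 180.0 - wrapped


def enumerate_hkl(cell: UnitCell, d_min: float) -> ReflectionSet:
    """All Friedel-unique Miller indices with d(h,k,l) >= d_min (inclusive).

    (0,0,0) is excluded.  Of each Friedel pair the lexicographically larger of
    (h,k,l) and (-h,-k,-l) is stored.
    """
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    edges = cell.edges
    hmax = np.floor(edges / d_min).astype(int)
    axes = [np.arange(-m, m + 1) for m in hmax]
    h, k, l = np.meshgrid(*axes, indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    inv_d2 = np.sum((hkl / edges) ** 2, axis=1)
    keep = (inv_d2 > 0) & (inv_d2 <= 1.0 / d_min**2 + 1e-12)
    hkl = hkl[keep]
    # Friedel-unique: keep the lexicographically larger of (h,k,l), (-h,-k,-l)
    neg = -hkl
    larger = np.array([tuple(p) > tuple(q) for p, q in zip(hkl, neg)], dtype=bool)
    hkl = hkl[larger]
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return ReflectionSet(cell, d_min, hkl[order])


def structure_factors(atoms: AtomList, cell: UnitCell, d_min: float) -> ReflectionSet:
    """Direct-summation structure factors for all Friedel-unique reflections.

    F(h) = sum_j f_j exp(-B_j /(4 d^2)) exp(+2 pi i h.x_j), phases stored in
    degrees in (-180, 180].  F(0,0,0) (= sum_j f_j) is recorded on the set's
    ``f000`` attribute but excluded from the indexed reflections.
    """
    if len(atoms) == 0:
        raise ValueError("atom list is empty")
    rset = enumerate_hkl(cell, d_min)
    frac = atoms.fractional(cell)
    if not np.all(np.isfinite(frac)):
        raise ValueError("non-finite atomic coordinates")
    f = atoms.weights()
    b = atoms.b_factors()
    inv_d2 = np.sum((rset.hkl / cell.edges) ** 2, axis=1)  # 1/d^2 per reflection
    # (R, J) attenuated weights and phase terms
    atten = np.exp(-np.outer(inv_d2, b) / 4.0)
    phase = 2.0 * np.pi * (rset.hkl @ frac.T)
    F = np.sum(f[None, :] * atten * np.exp(1j * phase), axis=1)
    rset.amplitude = np.abs(F)
    rset.phase_deg = _wrap_phase_deg(np.rad2deg(np.angle(F)))
    rset.f000 = float(np.sum(f))  # g_j(d=inf) = 1
    return rset


# ---------------------------------------------------------------------------
# map synthesis
# ---------------------------------------------------------------------------


def _check_nyquist(rset: ReflectionSet, grid: MapGrid, alias: str) -> None:
    if alias not in ("error", "warn", "ignore"):
        raise ValueError(f"unknown aliasing policy {alias!r}")
    if np.any(grid.spacing > rset.d_min / 2.0 + 1e-12):
        msg = (
            f"grid spacing {grid.spacing} exceeds d_min/2 = {rset.d_min / 2:.3f} A; "
            "the synthesis would alias"
        )
        if alias == "error":
            raise ValueError(msg)
        if alias == "warn":
            import warnings

            warnings.warn(msg, stacklevel=3)


def _fill_complex_grid(rset: ReflectionSet, grid: MapGrid, values: np.ndarray,
                       f000: float) -> np.ndarray:
    """Scatter reflection values (and Friedel mates as conjugates) onto the grid."""
    n = np.array(grid.shape)
    G = np.zeros(grid.shape, dtype=complex)
    idx = np.mod(rset.hkl, n)
    neg = np.mod(-rset.hkl, n)
    np.add.at(G, (idx[:, 0], idx[:, 1], idx[:, 2]), values)
    np.add.at(G, (neg[:, 0], neg[:, 1], neg[:, 2]), np.conj(values))
    G[0, 0, 0] += f000
    return G


def density_from_reflections(
    rset: ReflectionSet,
    grid: MapGrid,
    include_f000: bool = False,
    alias: str = "error",
) -> VoxelMap:
    """Fourier synthesis rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x) on the grid.

    Friedel completion makes the output real; the imaginary residue must be
    <= 1e-8 of the maximum amplitude and is discarded.  With the F(0,0,0)
    term excluded (the default) the map has zero mean.
    """
    _check_nyquist(rset, grid, alias)
    f000 = rset.f000 if (include_f000 and rset.f000 is not None) else 0.0
    G = _fill_complex_grid(rset, grid, rset.complex_values, f000)
    rho = np.fft.fftn(G) / rset.cell.volume
    scale = np.max(np.abs(rho)) or 1.0
    if np.max(np.abs(rho.imag)) > 1e-8 * scale:
        raise ValueError("synthesis produced a non-negligible imaginary component")
    return VoxelMap(grid, rho.real, role="density")


def patterson_from_reflections(
    rset: ReflectionSet,
    grid: MapGrid,
    include_f000: bool = False,
    alias: str = "error",
) -> VoxelMap:
    """Patterson synthesis P(u) = (1/V) sum_h |F(h)|^2 cos(2 pi h.u).

    Uses amplitudes only; the result is exactly real and centrosymmetric
    about the origin voxel.
    """
    _check_nyquist(rset, grid, alias)
    f000 = rset.f000**2 if (include_f000 and rset.f000 is not None) else 0.0
    G = _fill_complex_grid(
        rset, grid, rset.amplitude.astype(complex) ** 2, f000
    )
    P = np.fft.fftn(G).real / rset.cell.volume
    return VoxelMap(grid, P, role="patterson")


def reflections_from_density(vmap: VoxelMap, d_min: float) -> ReflectionSet:
    """Forward transform of a density map, truncated to d >= d_min.

    Normalized so that composing with :func:`density_from_reflections` is the
    identity on the retained reflections.  The F(0,0,0) term (V * map mean)
    is stored on ``f000``.
    """
    if vmap.role != "density":
        raise ValueError("reflections_from_density expects a density-role map")
    grid = vmap.grid
    cell = grid.cell
    Fgrid = np.fft.ifftn(vmap.values) * cell.volume
    rset = enumerate_hkl(cell, d_min)
    n = np.array(grid.shape)
    if np.any(np.max(np.abs(rset.hkl), axis=0) > n // 2):
        raise ValueError("grid too coarse to index reflections to the requested d_min")
    idx = np.mod(rset.hkl, n)
    F = Fgrid[idx[:, 0], idx[:, 1], idx[:, 2]]
    rset.amplitude = np.abs(F)
    rset.phase_deg = _wrap_phase_deg(np.rad2deg(np.angle(F)))
    rset.f000 = float(Fgrid[0, 0, 0].real)
    return rset


def normalize_map(vmap: VoxelMap, mode: str = "minmax") -> VoxelMap:
    """Affine per-map rescaling into [-1, 1].

    ``minmax``: v' = 2 (v - min)/(max - min) - 1, so min -> -1, max -> +1.
    ``maxabs``: v' = v / max|v| (symmetric about zero).
    Constant maps normalize to all-zero rather than raising.  Idempotent.
    """
    v = vmap.values
    if not np.all(np.isfinite(v)):
        raise ValueError("map contains non-finite values")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        out = np.zeros_like(v)
    elif mode == "minmax":
        out = 2.0 * (v - lo) / (hi - lo) - 1.0
    elif mode == "maxabs":
        out = v / max(abs(lo), abs(hi))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return VoxelMap(vmap.grid, out, role=vmap.role)
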