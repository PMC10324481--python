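"""Independent brute-force references for the crystallographic core.

These deliberately avoid the FFT synthesis path: structure factors are summed
atom by atom with ``cmath``, densities are summed reflection by reflection at
each voxel, and the circular autocorrelation is accumulated shift by shift
with ``np.roll``.  They exist to pin down the fast implementations and are
quadratic-or-worse on purpose; use tiny problems.
"""

from __future__ import annotations

import cmath

import numpy as np

from .crystal import AtomList, MapGrid, ReflectionSet, UnitCell

__all__ = [
    "direct_structure_factor",
    "direct_density",
    "circular_autocorrelation",
]


def direct_structure_factor(atoms: AtomList, cell: UnitCell,
                            hkl: tuple[int, int, int]) -> complex:
    """Per-reflection direct sum F = sum_j f_j g_j exp(2 pi i h.x_j)."""
    h, k, l = hkl
    inv_d2 = (h / cell.a) ** 2 + (k / cell.b) ** 2 + (l / cell.c) ** 2
    total = 0.0 + 0.0j
    frac = atoms.fractional(cell)
    for atom, (x, y, z) in zip(atoms, frac):
        g = cmath.exp(-atom.b_iso * inv_d2 / 4.0)
        total += atom.f * g * cmath.exp(2j * cmath.pi * (h * x + k * y + l * z))
    return total


def direct_density(rset: ReflectionSet, grid: MapGrid,
                   squared_amplitudes: bool = False) -> np.ndarray:
    """Per-voxel complex summation of the synthesis (no FFT).

    With ``squared_amplitudes`` the Patterson synthesis is evaluated instead
    (amplitudes squared, phases zeroed).  F(0,0,0) excluded, matching the
    synthesis defaults.
    """
    nx, ny, nz = grid.shape
    fx = np.arange(nx) / nx
    fy = np.arange(ny) / ny
    fz = np.arange(nz) / nz
    if squared_amplitudes:
        values = rset.amplitude.astype(complex) ** 2
    else:
        values = rset.complex_values
    out = np.zeros(grid.shape, dtype=complex)
    for (h, k, l), F in zip(rset.hkl, values):
        phase = -2j * np.pi * (
            h * fx[:, None, None] + k * fy[None, :, None] + l * fz[None, None, :]
        )
        out += F * np.exp(phase) + np.conj(F) * np.exp(-phase)
    return (out / rset.cell.volume).real


def circular_autocorrelation(values: np.ndarray) -> np.ndarray:
    """A(u) = sum_x v(x) v(x+u) with periodic wrapping, one shift at a time."""
    nx, ny, nz = values.shape
    out = np.empty_like(values, dtype=float)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                out[ix, iy, iz] = float(
                    np.sum(values * np.roll(values, (-ix, -iy, -iz), axis=(0, 1, 2)))
                )
    return out
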