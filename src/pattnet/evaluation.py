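"""Prediction quality metrics: Pearson CC and phase error per resolution shell.

A predicted density is compared with the truth in two complementary ways:

* real space — the Pearson product-moment correlation over all voxels, or
  over a centered cube (useful when examples sit in artificially enlarged
  cells whose borders are empty);
* reciprocal space — both maps are Fourier-transformed back to structure
  factors, and the absolute wrapped phase difference per reflection is
  averaged within resolution shells (equal-width bins in 1/d^2), amplitude
  weighted by default.  Because phases ignore overall scale and CC ignores
  any positive affine rescaling, normalized maps need no denormalization.

F(0,0,0) carries no phase information and is excluded throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crystal import VoxelMap, reflections_from_density
from .training import pearson_cc_flat

__all__ = [
    "ShellScheme",
    "EvaluationReport",
    "pearson_cc",
    "phase_error_by_shell",
    "fraction_below",
    "summarize",
]


@dataclass(frozen=True)
class ShellScheme:
    """Resolution binning: n_shells equal-width bins in 1/d^2 from d_max to d_min.

    ``d_max = inf`` starts the first shell at 1/d^2 = 0.  Every reflection
    with d >= d_min falls in exactly one shell.
    """

    d_min: float
    n_shells: int = 20
    d_max: float = np.inf

    def __post_init__(self) -> None:
        if self.d_min <= 0 or self.n_shells < 1:
            raise ValueError("d_min must be positive and n_shells >= 1")

    @property
    def edges(self) -> np.ndarray:
        """Bin edges in 1/d^2 (ascending, length n_shells + 1)."""
        lo = 0.0 if np.isinf(self.d_max) else 1.0 / self.d_max**2
        return np.linspace(lo, 1.0 / self.d_min**2, self.n_shells + 1)

    def assign(self, d: np.ndarray) -> np.ndarray:
        """Shell index per d-spacing (0 = lowest resolution)."""
        inv_d2 = 1.0 / np.asarray(d, dtype=float) ** 2
        idx = np.searchsorted(self.edges, inv_d2, side="left") - 1
        return np.clip(idx, 0, self.n_shells - 1)

    def shell_d_ranges(self) -> list[tuple[float, float]]:
        """(d_low_res, d_high_res) bounds per shell in Angstrom."""
        e = self.edges
        with np.errstate(divide="ignore"):
            d = 1.0 / np.sqrt(e)
        return [(float(d[i]), float(d[i + 1])) for i in range(self.n_shells)]


@dataclass
class EvaluationReport:
    """Aggregate metrics over a validation set."""

    per_example: pd.DataFrame  # columns: cc, mean_phase_error
    per_shell: pd.DataFrame  # columns: d_low, d_high, mean_phase_error, fraction_below_60
    median_cc: float
    median_phase_error: float

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_examples": [len(self.per_example)],
                "median_pearson_cc": [self.median_cc],
                "median_phase_error_deg": [self.median_phase_error],
            }
        )


def _central_slices(shape, grid, region_angstrom: float):
    counts = np.rint(region_angstrom / grid.spacing).astype(int)
    slices = []
    for n, m in zip(shape, counts):
        m = int(min(max(m, 1), n))
        start = n // 2 - m // 2
        slices.append(slice(start, start + m))
    return tuple(slices)


def pearson_cc(pred: VoxelMap, target: VoxelMap,
               region: float | None = None) -> float:
    """Pearson correlation over all voxels, or over a centered cube.

    ``region`` selects the central cube of ``round(region / spacing)`` voxels
    per axis (in Angstrom), e.g. the central 6 A box of an enlarged cell.
    """
    if pred.grid.shape != target.grid.shape:
        raise ValueError("maps must share one grid")
    a, b = pred.values, target.values
    if region is not None:
        sl = _central_slices(pred.grid.shape, pred.grid, region)
        a, b = a[sl], b[sl]
    return pearson_cc_flat(a, b)


def _wrap_deg(delta: np.ndarray) -> np.ndarray:
    """Wrap angle differences into (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(delta), 360.0)


def phase_error_by_shell(
    pred_density: VoxelMap,
    true_density: VoxelMap,
    d_min: float,
    scheme: ShellScheme | None = None,
    weighted: bool = True,
) -> tuple[np.ndarray, float]:
    """Mean absolute phase error per resolution shell, plus the overall mean.

    Both maps are transformed to structure factors truncated at ``d_min``;
    per reflection the error is |wrap(phi_pred - phi_true)| in [0, 180]
    degrees.  Means are weighted by the true amplitudes unless ``weighted``
    is False.  Shells containing no reflections are reported as NaN.
    """
    if pred_density.grid.shape != true_density.grid.shape:
        raise ValueError("maps must share one grid")
    scheme = scheme or ShellScheme(d_min)
    rp = reflections_from_density(pred_density, d_min)
    rt = reflections_from_density(true_density, d_min)
    # identical enumeration by construction
    err = np.abs(_wrap_deg(rp.phase_deg - rt.phase_deg))
    w = rt.amplitude if weighted else np.ones_like(err)
    shells = scheme.assign(rt.d_spacings())
    per_shell = np.full(scheme.n_shells, np.nan)
    for s in range(scheme.n_shells):
        sel = shells == s
        if np.any(sel) and w[sel].sum() > 0:
            per_shell[s] = np.average(err[sel], weights=w[sel])
    overall = float(np.average(err, weights=w)) if w.sum() > 0 else np.nan
    return per_shell, overall


def fraction_below(shell_errors: np.ndarray, threshold: float = 60.0) -> np.ndarray:
    """Per-shell fraction of examples with shell-mean phase error < threshold.

    ``shell_errors`` has shape (n_examples, n_shells); NaN entries (empty
    shells) are excluded from both numerator and denominator.
    """
    if not 0.0 < threshold < 180.0:
        raise ValueError("threshold must be in (0, 180) degrees")
    errors = np.atleast_2d(np.asarray(shell_errors, dtype=float))
    if errors.size == 0:
        raise ValueError("empty example set")
    valid = ~np.isnan(errors)
    below = (errors < threshold) & valid
    with np.errstate(invalid="ignore"):
        return below.sum(axis=0) / valid.sum(axis=0)


def summarize(
    pred_densities: list[VoxelMap],
    true_densities: list[VoxelMap],
    d_min: float,
    scheme: ShellScheme | None = None,
    cc_region: float | None = None,
    weighted: bool = True,
) -> EvaluationReport:
    """Table-style summary over a validation set.

    Per example: global (or central-region) CC and overall mean phase error.
    Per shell: mean phase error across examples and the fraction of examples
    below 60 degrees.  Headline numbers are medians across examples.
    """
    if len(pred_densities) != len(true_densities) or not pred_densities:
        raise ValueError("need equal, non-empty prediction and truth lists")
    scheme = scheme or ShellScheme(d_min)
    rows = []
    shell_mat = []
    for pred, true in zip(pred_densities, true_densities):
        per_shell, overall = phase_error_by_shell(pred, true, d_min, scheme,
                                                  weighted)
        rows.append({"cc": pearson_cc(pred, true, cc_region),
                     "mean_phase_error": overall})
        shell_mat.append(per_shell)
    per_example = pd.DataFrame(rows)
    shell_mat = np.array(shell_mat)
    d_ranges = scheme.shell_d_ranges()
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN (empty) shells
        shell_means = np.nanmean(shell_mat, axis=0)
    per_shell = pd.DataFrame(
        {
            "d_low": [r[0] for r in d_ranges],
            "d_high": [r[1] for r in d_ranges],
            "mean_phase_error": shell_means,
            "fraction_below_60": fraction_below(shell_mat, 60.0),
        }
    )
    return EvaluationReport(
        per_example=per_example,
        per_shell=per_shell,
        median_cc=float(per_example["cc"].median()),
        median_phase_error=float(per_example["mean_phase_error"].median()),
    )
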