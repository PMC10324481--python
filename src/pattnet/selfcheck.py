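"""End-to-end oracle and invariant checks on synthetic fixtures.

Each ``check_*`` function runs the package against an independent reference
and returns the measured quantities; :func:`run_selfcheck` converts them to
pass/fail at the documented tolerances.  ``scripts/acceptance.py`` and the
``pattnet selfcheck`` CLI both drive these functions, so the numbers a user
sees are always recomputed, never cached.
"""

from __future__ import annotations

import numpy as np

from . import oracles
from .crystal import (
    Atom,
    AtomList,
    MapGrid,
    UnitCell,
    density_from_reflections,
    patterson_from_reflections,
    structure_factors,
)
from .dataset import DatasetConfig, build_dataset, center_by_mass
from .evaluation import phase_error_by_shell, summarize
from .model import ModelConfig, build_model, count_parameters
from .peptides import synth_dipeptide
from .profiles import PROFILES
from .training import TrainConfig, mse_loss, pearson_cc_flat, train

__all__ = [
    "random_structure",
    "check_convolution_theorem",
    "check_direct_summation",
    "check_patterson_symmetries",
    "check_metric_identities",
    "check_model_size",
    "check_profile_geometry",
    "run_overfit_demo",
    "run_selfcheck",
]

_ELEMENTS = ("C", "N", "O", "S")


def random_structure(rng: np.random.Generator, cell: UnitCell,
                     max_atoms: int = 6) -> AtomList:
    """A random few-atom molecule with fractional coordinates in the cell."""
    n = int(rng.integers(1, max_atoms + 1))
    atoms = [
        Atom(
            element=str(rng.choice(_ELEMENTS)),
            xyz=rng.random(3) * cell.edges,
        )
        for _ in range(n)
    ]
    return AtomList(atoms, label=f"random{n}")


def check_convolution_theorem(seed: int, n_structures: int = 20,
                              grid_n: int = 16) -> float:
    """Max relative deviation of the Patterson map from (V/N) x the circular
    autocorrelation of the band-limited density, over random structures."""
    rng = np.random.default_rng(seed)
    cell = UnitCell.cubic(8.0)
    grid = MapGrid(cell, grid_n, grid_n, grid_n)
    d_min = 2.5 * float(np.max(grid.spacing))  # strictly inside Nyquist
    worst = 0.0
    for _ in range(n_structures):
        atoms = random_structure(rng, cell)
        rset = structure_factors(atoms, cell, d_min)
        patterson = patterson_from_reflections(rset, grid).values
        density = density_from_reflections(rset, grid).values
        auto = oracles.circular_autocorrelation(density)
        scaled = auto * cell.volume / density.size
        err = np.max(np.abs(patterson - scaled)) / np.max(np.abs(patterson))
        worst = max(worst, float(err))
    return worst


def check_direct_summation(seed: int, n_instances: int = 10) -> float:
    """Max relative error of FFT-free oracles vs the implementation:
    per-reflection structure factors and per-voxel density synthesis."""
    rng = np.random.default_rng(seed)
    cell = UnitCell.cubic(8.0)
    grid = MapGrid(cell, 16, 16, 16)
    d_min = 2.5 * float(np.max(grid.spacing))  # strictly inside Nyquist
    worst = 0.0
    for _ in range(n_instances):
        atoms = random_structure(rng, cell, max_atoms=5)
        rset = structure_factors(atoms, cell, d_min)
        # structure factors against the cmath loop, on a reflection sample
        sample = rng.choice(len(rset), size=min(25, len(rset)), replace=False)
        for i in sample:
            ref = oracles.direct_structure_factor(atoms, cell, tuple(rset.hkl[i]))
            err = abs(ref - rset.complex_values[i]) / max(abs(ref), 1e-300)
            worst = max(worst, float(err))
        # density synthesis against the per-voxel sum
        rho = density_from_reflections(rset, grid).values
        ref_rho = oracles.direct_density(rset, grid)
        err = np.max(np.abs(rho - ref_rho)) / np.max(np.abs(ref_rho))
        worst = max(worst, float(err))
    return worst


def check_patterson_symmetries(seed: int, n_instances: int = 5) -> dict[str, float]:
    """Translation invariance, inversion-twin identity, map centrosymmetry."""
    rng = np.random.default_rng(seed)
    cell = UnitCell.cubic(8.0)
    grid = MapGrid(cell, 16, 16, 16)
    d_min = 2.5 * float(np.max(grid.spacing))  # strictly inside Nyquist
    worst = {"translation": 0.0, "inversion_twin": 0.0, "centrosymmetry": 0.0}
    for _ in range(n_instances):
        atoms = random_structure(rng, cell)
        P = patterson_from_reflections(structure_factors(atoms, cell, d_min), grid)
        scale = np.max(np.abs(P.values))

        shifted = atoms.translated(rng.random(3) * cell.edges)
        P_shift = patterson_from_reflections(
            structure_factors(shifted, cell, d_min), grid
        )
        worst["translation"] = max(
            worst["translation"],
            float(np.max(np.abs(P.values - P_shift.values)) / scale),
        )

        twin = atoms.inverted(rng.random(3) * cell.edges)
        P_twin = patterson_from_reflections(
            structure_factors(twin, cell, d_min), grid
        )
        worst["inversion_twin"] = max(
            worst["inversion_twin"],
            float(np.max(np.abs(P.values - P_twin.values)) / scale),
        )

        flipped = P.values[
            np.ix_(*(np.mod(-np.arange(n), n) for n in grid.shape))
        ]
        worst["centrosymmetry"] = max(
            worst["centrosymmetry"],
            float(np.max(np.abs(P.values - flipped)) / scale),
        )
    return worst


def check_metric_identities(seed: int) -> dict[str, float]:
    """Truth-vs-truth CC / phase error, and the uniform-random-phase mean.

    A correct metric stack gives CC = 1 and 0 degrees against itself, and a
    mean absolute wrapped error of 90 degrees when predicted phases are
    uniform random (>= 2000 reflections keep the sampling error small).
    """
    rng = np.random.default_rng(seed)
    cell = UnitCell.cubic(20.0)
    grid = MapGrid.from_spacing(cell, 0.5)
    d_min = 1.5
    atoms = center_by_mass(synth_dipeptide(("ALA", "ALA"), seed + 7), cell)
    rset = structure_factors(atoms, cell, d_min)
    truth = density_from_reflections(rset, grid)

    report = summarize([truth], [truth], d_min)
    shell_errors = report.per_shell["mean_phase_error"].to_numpy()
    max_shell_err = float(np.nanmax(np.abs(shell_errors)))

    random_phases = rng.uniform(-180.0, 180.0, size=len(rset))
    scrambled = rset.copy_with(phase_deg=random_phases)
    pred = density_from_reflections(scrambled, grid)
    _, random_mean = phase_error_by_shell(pred, truth, d_min)

    return {
        "self_cc": float(report.median_cc),
        "self_phase_error_max_shell": max_shell_err,
        "random_phase_mean": float(random_mean),
        "n_reflections": float(len(rset)),
    }


def check_model_size() -> dict[str, int]:
    """Trainable-parameter counts of the named architectures."""
    baseline = count_parameters(build_model(ModelConfig.baseline()))
    enlarged = count_parameters(build_model(ModelConfig.enlarged()))
    return {"baseline": baseline, "enlarged": enlarged}


def check_profile_geometry() -> dict[str, tuple[int, int, int]]:
    """Voxel grid shapes the named dataset profiles expand to."""
    return {name: prof.dataset.grid.shape for name, prof in PROFILES.items()}


def run_overfit_demo(seed: int, epochs: int = 250) -> dict[str, float]:
    """Memorization check: a reduced model on 8 dialanine examples.

    Builds 9 synthetic examples in a 10 A cell at 0.5 A spacing (20^3 grids,
    8 train / 1 validation), trains a reduced U-net, and reports the training
    MSE before and after plus the final median training-set CC.
    """
    cfg = DatasetConfig(cell_edge=10.0, spacing=0.5, residue_alphabet="ALA",
                        train_fraction=8.0 / 9.0, seed=seed)
    ds = build_dataset(cfg, 9)
    xtr, ytr = ds.split_arrays("train")
    model = build_model(ModelConfig.reduced(), seed=seed)
    tcfg = TrainConfig(optimizer="adam", base_lr=2e-3, phase1_decay=1.0,
                       phase2_decay=1.0, batch_size=8, epochs=epochs,
                       loss_cc_weight=0.1, seed=seed)

    pred0 = model.forward(xtr[:, None], training=False)[:, 0]
    initial_mse = mse_loss(pred0, ytr)
    model, log = train(model, ds, tcfg, validate=False)
    pred1 = model.forward(xtr[:, None], training=False)[:, 0]
    final_mse = mse_loss(pred1, ytr)
    ccs = [pearson_cc_flat(p, t) for p, t in zip(pred1, ytr)]
    return {
        "initial_mse": float(initial_mse),
        "final_mse": float(final_mse),
        "mse_ratio": float(final_mse / initial_mse),
        "median_train_cc": float(np.median(ccs)),
        "n_train": float(len(xtr)),
    }


def run_selfcheck(seed: int = 0) -> dict[str, bool]:
    """Fast oracle/invariant suite (the slow overfit demo is separate)."""
    results: dict[str, bool] = {}
    results["convolution_theorem"] = check_convolution_theorem(seed, 5) <= 1e-6
    results["direct_summation"] = check_direct_summation(seed, 3) <= 1e-8
    sym = check_patterson_symmetries(seed, 3)
    for name, err in sym.items():
        results[f"patterson_{name}"] = err <= 1e-8
    ident = check_metric_identities(seed)
    results["self_comparison"] = (
        abs(ident["self_cc"] - 1.0) <= 1e-9
        and ident["self_phase_error_max_shell"] <= 1e-6
    )
    results["random_phase_90deg"] = abs(ident["random_phase_mean"] - 90.0) <= 2.0
    sizes = check_model_size()
    results["baseline_three_million"] = 2.5e6 <= sizes["baseline"] <= 3.5e6
    results["enlarged_bigger"] = sizes["enlarged"] > sizes["baseline"]
    grids = check_profile_geometry()
    results["profile_grids"] = (
        grids["1a"] == (40, 40, 40)
        and grids["1b"] == (20, 20, 20)
        and grids["2"] == (20, 20, 20)
    )
    return results
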