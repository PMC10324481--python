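"""Named experiment profiles tying dataset, model and training presets together.

* ``1a`` — dialanine in an artificially enlarged 20 A cell (0.5 A grid,
  40^3 voxels): empty borders make the Patterson-vector origin unambiguous.
* ``1b`` — dialanine in a tight 10 A cell (0.5 A grid, 20^3 voxels).
* ``2``  — unrestricted dipeptides of all 20 residues in a 12 A cell
  (0.6 A grid, 20^3 voxels) with the enlarged model and AdamW.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dataset import DatasetConfig
from .model import ModelConfig
from .training import DATASET1_PROFILE, DATASET2_PROFILE, TrainConfig

__all__ = ["RunProfile", "PROFILES", "get_profile"]


@dataclass(frozen=True)
class RunProfile:
    name: str
    dataset: DatasetConfig
    model: ModelConfig
    training: TrainConfig


PROFILES: dict[str, RunProfile] = {
    "1a": RunProfile(
        name="1a",
        dataset=DatasetConfig(cell_edge=20.0, spacing=0.5, d_min=1.5,
                              residue_alphabet="ALA", truncate=True),
        model=ModelConfig.baseline(),
        training=DATASET1_PROFILE,
    ),
    "1b": RunProfile(
        name="1b",
        dataset=DatasetConfig(cell_edge=10.0, spacing=0.5, d_min=1.5,
                              residue_alphabet="ALA", truncate=True),
        model=ModelConfig.baseline(),
        training=DATASET1_PROFILE,
    ),
    "2": RunProfile(
        name="2",
        dataset=DatasetConfig(cell_edge=12.0, spacing=0.6, d_min=1.5,
                              residue_alphabet="all20", truncate=False),
        model=ModelConfig.enlarged(),
        training=DATASET2_PROFILE,
    ),
}


def get_profile(name: str) -> RunProfile:
    try:
        return PROFILES[name]
    except KeyError:
        raise ValueError(
            f"unknown profile {name!r}; available: {sorted(PROFILES)}"
        ) from None
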