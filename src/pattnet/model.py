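"""The 3D residual U-net mapping Patterson maps to electron densities.

Three phases:

* Encoding — two 7x7x7 convolutions (batch norm + ReLU after each) with
  periodic padding, then 2x2x2 stride-2 max pooling.
* Learning Features — a stack of residual blocks (7x7x7 conv/BN/ReLU,
  7x7x7 conv/BN, optional squeeze-and-excitation gate, skip add, ReLU), all
  periodically padded, closed by naive (nearest-neighbor) x2 upsampling back
  to the input size.
* Decoding — a 5x5x5 conv/BN/ReLU and a final 5x5x5 conv to one channel
  with zero same-padding, then tanh so predictions live in (-1, 1) like the
  normalized targets.

Periodic padding in the first two phases reflects that a Patterson map is a
function on the torus of the unit cell; the Decoding phase predicts a
centered molecule and uses ordinary zero padding.

The baseline width assignment (1 -> 23 -> 25 channels in, seven residual
blocks at 25, 25 -> 23 -> 1 out) carries about 3.3 million trainable
parameters; the enlarged variant widens 23 -> 25 and 25 -> 30 and adds an
eighth residual block.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import h5py
import numpy as np

from .crystal import VoxelMap
from .nn import (
    BatchNorm3d,
    Conv3d,
    MaxPool3d,
    Module,
    ReLU,
    ResidualBlock3d,
    Sequential,
    Tanh,
    UpsampleNearest3d,
)

__all__ = [
    "ModelConfig",
    "PattersonUNet",
    "build_model",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the Patterson U-net."""

    enc_channels: tuple[int, int] = (23, 25)
    res_channels: int = 25
    n_res_blocks: int = 7
    use_se: bool = True
    se_reduction: int = 2
    dec_channels: int = 23
    enc_kernel: int = 7
    dec_kernel: int = 5

    def __post_init__(self) -> None:
        widths = (*self.enc_channels, self.res_channels, self.dec_channels)
        if min(widths) < 1 or self.n_res_blocks < 1:
            raise ValueError("channel widths and block count must be >= 1")
        if self.enc_channels[1] != self.res_channels:
            raise ValueError("second encoding width must match residual width")

    @classmethod
    def baseline(cls) -> "ModelConfig":
        """Dialanine-scale configuration (about three million parameters)."""
        return cls()

    @classmethod
    def enlarged(cls) -> "ModelConfig":
        """All-residue-scale configuration: widened channels, eight blocks."""
        return cls(enc_channels=(25, 30), res_channels=30, n_res_blocks=8,
                   dec_channels=25)

    @classmethod
    def reduced(cls) -> "ModelConfig":
        """Small configuration for CPU-scale experiments and overfit demos."""
        return cls(enc_channels=(8, 10), res_channels=10, n_res_blocks=2,
                   dec_channels=8, enc_kernel=5, dec_kernel=3)


class PattersonUNet(Module):
    """See module docstring for the phase layout."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        c1, c2 = config.enc_channels
        self.config = config
        self.encode = Sequential(
            Conv3d(1, c1, config.enc_kernel, "circular", rng),
            BatchNorm3d(c1),
            ReLU(),
            Conv3d(c1, c2, config.enc_kernel, "circular", rng),
            BatchNorm3d(c2),
            ReLU(),
            MaxPool3d(),
        )
        self.features = Sequential(
            *[
                ResidualBlock3d(config.res_channels, config.enc_kernel,
                                config.use_se, config.se_reduction, rng)
                for _ in range(config.n_res_blocks)
            ],
            UpsampleNearest3d(),
        )
        self.decode = Sequential(
            Conv3d(c2, config.dec_channels, config.dec_kernel, "zeros", rng),
            BatchNorm3d(config.dec_channels),
            ReLU(),
            Conv3d(config.dec_channels, 1, config.dec_kernel, "zeros", rng),
            Tanh(),
        )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError("expected input of shape (batch, 1, d, h, w)")
        if any(n % 2 for n in x.shape[2:]):
            raise ValueError("spatial dimensions must be even (2x pooling)")
        h = self.encode.forward(x, training)
        h = self.features.forward(h, training)
        return self.decode.forward(h, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.encode.backward(self.features.backward(self.decode.backward(grad)))

    def periodic_features(self, x: np.ndarray) -> np.ndarray:
        """Activations after the periodically padded phases (pre-Decoding)."""
        return self.features.forward(self.encode.forward(x, False), False)

    def predict_map(self, patterson: VoxelMap) -> VoxelMap:
        """Single-map convenience wrapper: VoxelMap in, VoxelMap out."""
        x = patterson.values[None, None]
        y = self.forward(x, training=False)[0, 0]
        return VoxelMap(patterson.grid, y, role="density")


def build_model(config: ModelConfig, seed: int = 0) -> PattersonUNet:
    """Construct a seeded, He-initialized Patterson U-net."""
    return PattersonUNet(config, seed)


def count_parameters(model: Module) -> int:
    """Number of trainable scalars, batch-norm affine terms included."""
    return int(sum(p.size for p in model.parameters()))


def save_checkpoint(model: PattersonUNet, path) -> None:
    """HDF5 checkpoint with the architecture config embedded."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = json.dumps(asdict(model.config))
        for name, arr in model.state_arrays().items():
            f.create_dataset(name, data=arr)


def load_checkpoint(path) -> PattersonUNet:
    with h5py.File(path, "r") as f:
        cfg_dict = json.loads(f.attrs["config"])
        cfg_dict["enc_channels"] = tuple(cfg_dict["enc_channels"])
        model = PattersonUNet(ModelConfig(**cfg_dict))
        model.load_state_arrays({k: np.asarray(f[k]) for k in f.keys()})
    return model
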