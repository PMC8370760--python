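"""Layer-feature preparation: spatial pooling, log transform, level grouping.

Deep-network layer activations enter the encoding models after two
reductions that mimic the limited retinotopic precision of surface-based
fMRI: convolutional feature maps are block-averaged down to a 3x3 spatial
grid, and activations are log-transformed (``log(1+x)``, so exact zeros
from rectified units stay at zero).  The 16 layers are grouped into four
feature levels — low (1-4), mid (5-9), high (10-13) and semantic (14-16) —
which are the units of all downstream reactivation analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LEVELS",
    "LEVEL_ORDER",
    "N_LAYERS",
    "FeatureTensor",
    "assign_level",
    "pool_spatial",
    "log_transform",
    "prepare_tensor",
]

#: Partition of the 16 layers into named feature levels.
LEVELS: dict[str, tuple[int, ...]] = {
    "low": (1, 2, 3, 4),
    "mid": (5, 6, 7, 8, 9),
    "high": (10, 11, 12, 13),
    "semantic": (14, 15, 16),
}

LEVEL_ORDER: tuple[str, ...] = ("low", "mid", "high", "semantic")

N_LAYERS = 16

#: Layers without an explicit spatial map (fully connected); they bypass pooling.
FULLY_CONNECTED_LAYERS: tuple[int, ...] = (14, 15, 16)

_LAYER_TO_LEVEL = {lay: lvl for lvl, lays in LEVELS.items() for lay in lays}


def assign_level(layer_id: int) -> str:
    """Return the feature level ('low'/'mid'/'high'/'semantic') owning *layer_id*."""
    try:
        return _LAYER_TO_LEVEL[int(layer_id)]
    except (KeyError, ValueError, TypeError):
        raise ValueError(f"layer_id must be an integer in 1..16, got {layer_id!r}")


def _block_edges(n: int, grid: int) -> np.ndarray:
    # Near-equal integer block boundaries via rounding (224/3 -> 75/74/75).
    return np.array([round(i * n / grid) for i in range(grid + 1)], dtype=int)


def pool_spatial(feature_map: np.ndarray, grid: int = 3) -> np.ndarray:
    """Block-average an H x W x C feature map to ``grid x grid x C``.

    Blocks are as equal as integer division allows, with the remainder
    distributed by rounding (e.g. 224 rows split 75/74/75).  A 2-D map is
    treated as H x W x 1 and returned as grid x grid.
    """
    arr = np.asarray(feature_map, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError(f"expected H x W x C array, got shape {arr.shape}")
    h, w, _ = arr.shape
    if h < grid or w < grid:
        raise ValueError(f"spatial dims {h}x{w} smaller than pooling grid {grid}")
    re_ = _block_edges(h, grid)
    ce = _block_edges(w, grid)
    out = np.empty((grid, grid, arr.shape[2]))
    for i in range(grid):
        for j in range(grid):
            out[i, j] = arr[re_[i]:re_[i + 1], ce[j]:ce[j + 1]].mean(axis=(0, 1))
    return out[:, :, 0] if squeeze else out


def log_transform(x: np.ndarray, offset: float = 1.0) -> np.ndarray:
    """Elementwise ``log(offset + x)`` for non-negative activations.

    With the default offset of 1 this is ``log1p``: strictly monotone,
    maps 0 to 0, and is well defined for the exact zeros that rectified
    units produce.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log_transform requires non-negative input")
    if offset == 1.0:
        return np.log1p(arr)
    if offset <= 0:
        raise ValueError("offset must be positive")
    return np.log(offset + arr)


@dataclass
class FeatureTensor:
    """Activations of one network layer for one image.

    ``values`` is grid x grid x channels for convolutional layers (1-13)
    or a flat vector for fully connected layers (14-16).
    """

    image_id: str
    layer_id: int
    values: np.ndarray = field(repr=False)
    log_transformed: bool = False
    pooled: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.layer_id <= N_LAYERS:
            raise ValueError(f"layer_id must be in 1..{N_LAYERS}, got {self.layer_id}")
        self.values = np.asarray(self.values, dtype=float)
        if not self.log_transformed and np.any(self.values < 0):
            raise ValueError("raw activations must be non-negative")

    @property
    def level(self) -> str:
        return assign_level(self.layer_id)

    @property
    def is_fully_connected(self) -> bool:
        return self.layer_id in FULLY_CONNECTED_LAYERS

    def flatten(self) -> np.ndarray:
        return self.values.ravel()


def prepare_tensor(tensor: FeatureTensor, grid: int = 3, log_offset: float = 1.0,
                   pool_first: bool = True) -> FeatureTensor:
    """Pool (convolutional layers only) and log-transform a feature tensor.

    Applying the log transform twice is an error; the ``log_transformed``
    flag guards against it.  ``pool_first`` controls the order of the two
    steps (pooling first by default).
    """
    if tensor.log_transformed:
        raise ValueError(
            f"layer {tensor.layer_id} of image {tensor.image_id} is already "
            "log-transformed; refusing to transform twice"
        )
    values = tensor.values
    needs_pool = not tensor.is_fully_connected and not tensor.pooled
    if pool_first:
        if needs_pool:
            values = pool_spatial(values, grid=grid)
        values = log_transform(values, offset=log_offset)
    else:
        values = log_transform(values, offset=log_offset)
        if needs_pool:
            values = pool_spatial(values, grid=grid)
    return replace(tensor, values=values, log_transformed=True, pooled=True)
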