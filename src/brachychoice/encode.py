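"""Build the 3-channel classifier input from a label volume and tandem.

Channel 1 is the coded label volume (float-cast).  Channels 2 and 3 carry,
in millimetres, the distance of every CTV voxel (code 1) and OAR voxel
(code 3) to the tandem's central axis, and zero everywhere else.  Distances
are 3D point-to-polyline distances evaluated at voxel centers; the dilated
5 mm tube is display plumbing only and plays no role here.  No
normalization is applied anywhere: the raw mm values are what give the
network absolute size and distance information.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .grid import GridSpec, point_to_polyline_distance, validate_polyline
from .structures import LABEL_CTV, LABEL_OAR, LabelVolume


class InputMode(str, Enum):
    FULL = "full"  # 3 channels: labels + CTV/OAR distance maps
    MASK_ONLY = "mask_only"  # 1 channel: labels alone (ablation mode)


@dataclass
class DistanceMap:
    """Non-negative mm distances on a grid, supported on one structure."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError("distance array shape does not match grid")
        if (self.values < 0).any():
            raise ValueError("distances must be non-negative")


@dataclass
class ModelInput:
    """Channels-first float array (C, nz, ny, nx) plus its grid and mode."""

    grid: GridSpec
    channels: np.ndarray
    mode: InputMode = InputMode.FULL

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float32)
        expected = 1 if self.mode == InputMode.MASK_ONLY else 3
        if self.channels.ndim != 4 or self.channels.shape[0] != expected:
            raise ValueError(
                f"{self.mode.value} input requires {expected} channels, "
                f"got shape {self.channels.shape}"
            )
        if self.channels.shape[1:] != tuple(self.grid.shape):
            raise ValueError("channel shape does not match grid")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]


def distance_to_axis(points_xyz: np.ndarray, tandem) -> np.ndarray:
    """Minimum 3D distance (mm) from points to the tandem central axis."""
    line = validate_polyline(tandem, require_monotone_z=False)
    pts = np.asarray(points_xyz, dtype=float)
    if pts.size == 0:
        return np.zeros(0)
    return point_to_polyline_distance(pts, line)


def _support_distance_map(label_volume: LabelVolume, tandem, code: int) -> np.ndarray:
    values = np.zeros(label_volume.grid.shape, dtype=np.float32)
    mask = label_volume.values == code
    if mask.any():
        centers = label_volume.grid.voxel_centers_xyz(mask)
        values[mask] = distance_to_axis(centers, tandem)
    return values


def build_input(
    label_volume: LabelVolume, tandem, mode: InputMode = InputMode.FULL
) -> ModelInput:
    """Assemble the network input for one insertion.

    In FULL mode channel 2 carries ``distance_to_axis`` at CTV voxels and
    channel 3 the same at OAR voxels (zero elsewhere, including voxels
    re-coded 2 by tandem precedence).  MASK_ONLY returns the label channel
    alone.
    """
    mode = InputMode(mode)
    label_channel = label_volume.values.astype(np.float32)
    if mode == InputMode.MASK_ONLY:
        return ModelInput(label_volume.grid, label_channel[None], mode)
    ctv_dist = _support_distance_map(label_volume, tandem, LABEL_CTV)
    oar_dist = _support_distance_map(label_volume, tandem, LABEL_OAR)
    channels = np.stack([label_channel, ctv_dist, oar_dist])
    return ModelInput(label_volume.grid, channels, mode)


def to_mask_only(model_input: ModelInput) -> ModelInput:
    """Drop the distance channels of a FULL input (for the ablation study)."""
    if model_input.mode == InputMode.MASK_ONLY:
        return model_input
    return ModelInput(model_input.grid, model_input.channels[:1], InputMode.MASK_ONLY)
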