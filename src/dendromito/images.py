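"""Image containers: multi-channel stacks and time-lapse movies.

Geometry is always carried in µm; arrays stay in acquisition order
(``(z,) y, x`` for stacks, ``t, (z,) y, x`` for movies).  TIFF round-trips,
with a JSON sidecar carrying voxel size and frame interval, live in
:mod:`dendromito.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VolumeStack:
    """Single-channel 2-D or 3-D intensity stack with voxel size in µm."""

    intensities: np.ndarray
    voxel_size: np.ndarray  # µm per axis, same ndim as intensities
    channel_name: str = ""

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities)
        self.voxel_size = np.atleast_1d(np.asarray(self.voxel_size, dtype=float))
        if len(self.voxel_size) == 1:
            self.voxel_size = np.repeat(self.voxel_size, self.intensities.ndim)
        if len(self.voxel_size) != self.intensities.ndim:
            raise ValueError("voxel_size must have one entry per image axis")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be > 0")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def shape(self):
        return self.intensities.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))


@dataclass
class TimeLapse:
    """Time-lapse series: ``(t, (z,) y, x)`` frames at a fixed frame interval."""

    frames: np.ndarray
    frame_interval: float
    voxel_size: np.ndarray  # µm per spatial axis

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        self.voxel_size = np.atleast_1d(np.asarray(self.voxel_size, dtype=float))
        if len(self.voxel_size) == 1:
            self.voxel_size = np.repeat(self.voxel_size, self.frames.ndim - 1)
        if len(self.voxel_size) != self.frames.ndim - 1:
            raise ValueError("voxel_size must have one entry per spatial axis")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.frame_interval

    def frame(self, i: int) -> VolumeStack:
        return VolumeStack(self.frames[i], self.voxel_size)
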