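"""Organelle track containers.

A :class:`TrackSet` stores per-organelle arc-length positions along a
dendritic path, sampled at a fixed frame interval.  Tracks may come from the
synthetic generator (with ground-truth state labels), from the automatic
linker, or from manual-tracking CSV exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# per-frame state codes
STATIONARY, RUN, PAUSE, ARRESTED = 0, 1, 2, 3
STATE_NAMES = {STATIONARY: "stationary", RUN: "run", PAUSE: "pause", ARRESTED: "arrested"}
_STATE_CODES = {v: k for k, v in STATE_NAMES.items()}


@dataclass
class TrackSet:
    """Positions of tracked organelles along a 1-D dendritic path.

    Parameters
    ----------
    positions
        ``(n_organelles, n_frames)`` arc positions in µm; NaN marks frames in
        which an organelle was not observed.
    frame_interval
        Seconds between frames.
    states
        Optional ``(n_organelles, n_frames)`` integer state labels
        (0 stationary, 1 run, 2 pause, 3 arrested); ground truth only.
    source
        Provenance: ``"ground_truth"``, ``"linker"`` or ``"manual"``.
    path_length
        Length in µm of the path the positions live on, if known.
    """

    positions: np.ndarray
    frame_interval: float
    states: np.ndarray | None = None
    source: str = "ground_truth"
    path_length: float | None = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.positions.shape[1] < 2:
            raise ValueError("need at least 2 frames")
        if self.states is not None:
            self.states = np.asarray(self.states)
            if self.states.shape != self.positions.shape:
                raise ValueError("states must match positions shape")

    @property
    def n_organelles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.frame_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def step_speeds(self) -> np.ndarray:
        """``(n, T-1)`` frame-pair speeds |Δx|/Δt in µm/s (NaN where unobserved)."""
        return np.abs(np.diff(self.positions, axis=1)) / self.frame_interval

    def to_dataframe(self) -> pd.DataFrame:
        n, t = self.positions.shape
        oid, frame = np.meshgrid(np.arange(n), np.arange(t), indexing="ij")
        df = pd.DataFrame({
            "organelle_id": oid.ravel(),
            "frame": frame.ravel(),
            "time_s": (frame * self.frame_interval).ravel(),
            "arc_position_um": self.positions.ravel(),
        })
        if self.states is not None:
            df["state"] = [STATE_NAMES[int(s)] for s in self.states.ravel()]
        return df.dropna(subset=["arc_position_um"]).reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame_interval: float | None = None,
                       source: str = "manual") -> "TrackSet":
        """Build from a tidy table with columns ``organelle_id, frame,
        arc_position_um`` (``time_s`` and ``state`` optional)."""
        required = {"organelle_id", "frame", "arc_position_um"}
        if not required.issubset(df.columns):
            raise ValueError(f"track table needs columns {sorted(required)}")
        if frame_interval is None:
            if "time_s" not in df.columns:
                raise ValueError("frame_interval not given and no time_s column")
            by_frame = df.drop_duplicates("frame").sort_values("frame")
            dts = np.diff(by_frame["time_s"].to_numpy()) / np.maximum(
                np.diff(by_frame["frame"].to_numpy()), 1)
            frame_interval = float(np.median(dts))
        ids = np.sort(df["organelle_id"].unique())
        t_max = int(df["frame"].max()) + 1
        pos = np.full((len(ids), t_max), np.nan)
        states = None
        if "state" in df.columns:
            states = np.zeros((len(ids), t_max), dtype=np.int8)
        for i, oid in enumerate(ids):
            sub = df[df["organelle_id"] == oid].sort_values("frame")
            fr = sub["frame"].to_numpy(int)
            if len(np.unique(fr)) != len(fr):
                raise ValueError(f"duplicate frames in track {oid}")
            pos[i, fr] = sub["arc_position_um"].to_numpy()
            if states is not None:
                states[i, fr] = [_STATE_CODES[s] for s in sub["state"]]
        return cls(positions=pos, frame_interval=frame_interval,
                   states=states, source=source)

    @classmethod
    def from_csv(cls, path, frame_interval: float | None = None,
                 source: str = "manual") -> "TrackSet":
        return cls.from_dataframe(pd.read_csv(path), frame_interval, source)
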