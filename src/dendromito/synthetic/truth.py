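"""Ground-truth bundle produced by the synthetic generators."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from ..skeleton import ArborSkeleton, SkeletonPoints
from ..tracks import TrackSet


@dataclass
class CalciumEvent:
    onset_s: float
    duration_s: float
    kind: str                  # "global" | "local"
    center_um: float | None = None   # arc position for local events
    extent_um: float | None = None


@dataclass
class GroundTruth:
    """Hidden parameters and labels behind a synthetic dataset.

    Only the fields relevant to a given generator are populated; the bundle
    is the oracle every estimator is tested against.
    """

    skeleton: ArborSkeleton | None = None
    synapses: SkeletonPoints | None = None
    mitochondria: SkeletonPoints | None = None
    tracks: TrackSet | None = None
    motile: np.ndarray | None = None          # per-organelle motile-state flag
    params: Any = None
    calcium_events: list[CalciumEvent] = field(default_factory=list)
    # continuous-time bout durations actually drawn by the transport
    # simulator (complete bouts only; the final truncated bout is excluded)
    run_durations: np.ndarray | None = None
    pause_durations: np.ndarray | None = None
    run_speeds: np.ndarray | None = None

    def validate(self) -> None:
        if self.skeleton is not None:
            for pts in (self.synapses, self.mitochondria):
                if pts is not None:
                    pts.validate_on(self.skeleton)
        if self.tracks is not None and self.tracks.states is None:
            raise ValueError("ground-truth tracks must carry state labels")

    def events_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"onset_s": e.onset_s, "duration_s": e.duration_s, "kind": e.kind,
             "center_um": e.center_um, "extent_um": e.extent_um}
            for e in self.calcium_events])
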