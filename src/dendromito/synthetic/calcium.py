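"""Synthetic dendritic Ca²⁺ activity coupled (optionally) to organelle motility.

Events arrive as Poisson processes: *global* events raise ΔF/F in every
window of the dendrite, *local* events only within ``local_extent`` of a
random arc position.  The waveform is a step rise followed by exponential
decay with time constant ``decay_tau``, on a baseline of 1, plus Gaussian
noise.  If ``motility_coupling`` > 0, each motile organelle arrests with
that probability for the duration of each event.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from ..tracks import TrackSet, ARRESTED, RUN
from ..activity import ActivityTrace
from .truth import GroundTruth, CalciumEvent


@dataclass(frozen=True)
class CalciumParams:
    global_rate: float = 0.0141        # events/s
    local_rate: float = 0.0102        # events/s
    local_extent: float = 10.0        # µm
    amplitude_dff: float = 1.0
    decay_tau: float = 2.0            # s
    noise_sd: float = 0.05            # fraction of baseline
    motility_coupling: float = 0.0
    event_duration_s: float = 5.0     # arrest / supra-threshold duration
    seed: int = 0

    def __post_init__(self):
        if self.global_rate < 0 or self.local_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be > 0")
        if not 0 <= self.motility_coupling <= 1:
            raise ValueError("motility_coupling must be in [0, 1]")


def dff_waveform(t: np.ndarray, onset: float, amplitude: float, tau: float) -> np.ndarray:
    """Step rise at ``onset`` followed by exponential decay."""
    dt = t - onset
    return np.where(dt >= 0, amplitude * np.exp(-np.maximum(dt, 0) / tau), 0.0)


def simulate_calcium(params: CalciumParams, tracks: TrackSet,
                     window_length_um: float = 10.0,
                     ) -> tuple[list[ActivityTrace], TrackSet, GroundTruth]:
    """Simulate Ca²⁺ traces on the dendrite carrying ``tracks``.

    Returns one raw-intensity :class:`ActivityTrace` per dendrite window
    (baseline 1), the possibly modified :class:`TrackSet`, and the ground
    truth.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    duration = tracks.duration
    L = tracks.path_length if tracks.path_length is not None else float(
        np.nanmax(tracks.positions))
    L = max(L, window_length_um)
    n_windows = int(np.ceil(L / window_length_um))
    centers = (np.arange(n_windows) + 0.5) * window_length_um
    t = tracks.times

    events: list[CalciumEvent] = []
    for _ in range(rng.poisson(params.global_rate * duration)):
        events.append(CalciumEvent(onset_s=rng.uniform(0, duration),
                                   duration_s=params.event_duration_s, kind="global"))
    for _ in range(rng.poisson(params.local_rate * duration)):
        events.append(CalciumEvent(onset_s=rng.uniform(0, duration),
                                   duration_s=params.event_duration_s, kind="local",
                                   center_um=rng.uniform(0, L),
                                   extent_um=params.local_extent))
    events.sort(key=lambda e: e.onset_s)

    dff = np.zeros((n_windows, len(t)))
    for ev in events:
        wave = dff_waveform(t, ev.onset_s, params.amplitude_dff, params.decay_tau)
        if ev.kind == "global":
            dff += wave[None, :]
        else:
            hit = np.abs(centers - ev.center_um) <= ev.extent_um / 2
            dff[hit] += wave[None, :]
    intensity = 1.0 + dff
    if params.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, params.noise_sd, size=intensity.shape)
    traces = [ActivityTrace(values=intensity[w], frame_interval=tracks.frame_interval,
                            roi=f"window_{w}_{centers[w]:.1f}um")
              for w in range(n_windows)]

    out_tracks = tracks
    if params.motility_coupling > 0 and events:
        pos = tracks.positions.copy()
        states = tracks.states.copy() if tracks.states is not None else None
        for ev in events:
            f0 = int(np.searchsorted(t, ev.onset_s))
            f1 = min(int(np.searchsorted(t, ev.onset_s + ev.duration_s)),
                     tracks.n_frames - 1)
            if f0 >= tracks.n_frames - 1 or f1 <= f0:
                continue
            for i in range(tracks.n_organelles):
                if rng.uniform() >= params.motility_coupling:
                    continue
                shift = pos[i, f1] - pos[i, f0]
                pos[i, f0:f1 + 1] = pos[i, f0]
                pos[i, f1 + 1:] -= shift
                if states is not None:
                    states[i, f0:f1 + 1] = ARRESTED
        if tracks.path_length is not None:
            np.clip(pos, 0.0, tracks.path_length, out=pos)
        out_tracks = TrackSet(positions=pos, frame_interval=tracks.frame_interval,
                              states=states, source=tracks.source,
                              path_length=tracks.path_length)

    truth = GroundTruth(tracks=out_tracks, params=params, calcium_events=events)
    return traces, out_tracks, truth
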