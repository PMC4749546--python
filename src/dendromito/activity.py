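"""Ca²⁺-trace and spike-train analysis.

Covers ΔF/F normalization, transient detection at a mean + k·SD threshold,
global/local event classification, peri-event alignment of organelle
motility, pre/post speed changes, and cross-correlation between cells
corrected for slow nonstationary rate drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import TrackSet

__all__ = [
    "ActivityTrace", "EventSet", "PeriEventProfile", "DeltaSpeedResult",
    "Correlogram", "compute_dff", "detect_events", "classify_event_extent",
    "event_frequency", "peri_event_motility", "delta_speed",
    "pairwise_correlation", "instantaneous_motile_series",
]


@dataclass
class ActivityTrace:
    """Fluorescence (raw or ΔF/F) time series for one region of interest."""

    values: np.ndarray
    frame_interval: float
    roi: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class EventSet:
    """Detected transients: maximal supra-threshold runs of frames."""

    onsets: np.ndarray            # first frame of each run
    offsets: np.ndarray           # last supra-threshold frame of each run
    threshold: float
    percent_time_above: float
    frame_interval: float

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=int)
        self.offsets = np.asarray(self.offsets, dtype=int)
        if np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if not 0 <= self.percent_time_above <= 100:
            raise ValueError("percent_time_above must be in [0, 100]")

    @property
    def n_events(self) -> int:
        return len(self.onsets)

    @property
    def onset_times(self) -> np.ndarray:
        return self.onsets * self.frame_interval

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"onset_frame": self.onsets, "offset_frame": self.offsets,
                             "onset_s": self.onset_times})


def compute_dff(raw: ActivityTrace, baseline_method: str | float = "lowest_quartile",
                ) -> ActivityTrace:
    """ΔF/F = (F − F₀)/F₀.

    ``baseline_method``: ``"lowest_quartile"`` (default; mean of the lowest
    25% of frames — robust to sparse transients riding on a flat baseline),
    ``"mean"``, or an explicit numeric F₀.
    """
    f = raw.values
    if isinstance(baseline_method, (int, float)):
        f0 = float(baseline_method)
    elif baseline_method == "lowest_quartile":
        q = np.quantile(f, 0.25)
        f0 = float(f[f <= q].mean())
    elif baseline_method == "mean":
        f0 = float(f.mean())
    else:
        raise ValueError(f"unknown baseline method {baseline_method!r}")
    if f0 <= 0:
        raise ValueError(f"baseline F0={f0:.4g} is not positive")
    return ActivityTrace(values=(f - f0) / f0, frame_interval=raw.frame_interval,
                         roi=raw.roi)


def detect_events(trace: ActivityTrace, k_sd: float = 2.0) -> EventSet:
    """Threshold at mean + ``k_sd``·SD over the whole recording.

    Events are maximal runs of supra-threshold frames; the onset is the first
    frame of each run.  Also reports the percentage of frames above
    threshold.  Invariant to affine rescaling of the trace (the threshold
    co-scales with mean and SD).
    """
    v = trace.values
    thr = float(v.mean() + k_sd * v.std())
    above = v > thr
    if not above.any():
        return EventSet(onsets=np.empty(0, int), offsets=np.empty(0, int),
                        threshold=thr, percent_time_above=0.0,
                        frame_interval=trace.frame_interval)
    edges = np.diff(above.astype(int))
    onsets = np.flatnonzero(edges == 1) + 1
    offsets = np.flatnonzero(edges == -1)
    if above[0]:
        onsets = np.concatenate([[0], onsets])
    if above[-1]:
        offsets = np.concatenate([offsets, [len(v) - 1]])
    return EventSet(onsets=onsets, offsets=offsets, threshold=thr,
                    percent_time_above=100.0 * above.mean(),
                    frame_interval=trace.frame_interval)


def classify_event_extent(traces: list[ActivityTrace], k_sd: float = 2.0,
                          min_global_fraction: float = 0.8) -> pd.DataFrame:
    """Label events across local windows as global or local.

    Each window trace is thresholded at its own mean + ``k_sd``·SD; frames
    where any window is supra-threshold are merged into candidate events.  An
    event is *global* when at least ``min_global_fraction`` of windows go
    supra-threshold during its frame run, else *local*.
    """
    if not traces:
        raise ValueError("no traces")
    above = np.stack([t.values > t.values.mean() + k_sd * t.values.std()
                      for t in traces])          # (n_windows, T)
    any_above = above.any(axis=0)
    rows = []
    t0 = None
    for f in range(len(any_above) + 1):
        active = f < len(any_above) and any_above[f]
        if active and t0 is None:
            t0 = f
        elif not active and t0 is not None:
            frac = above[:, t0:f].any(axis=1).mean()
            rows.append({"onset_frame": t0, "offset_frame": f - 1,
                         "fraction_windows": float(frac),
                         "label": "global" if frac >= min_global_fraction else "local"})
            t0 = None
    return pd.DataFrame(rows, columns=["onset_frame", "offset_frame",
                                       "fraction_windows", "label"])


def event_frequency(events: EventSet, duration: float) -> float:
    """Events per second."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    return events.n_events / duration


# ----------------------------------------------------------------- motility
def instantaneous_motile_series(tracks: TrackSet, move_threshold: float = 0.4,
                                ) -> np.ndarray:
    """Fraction of organelles moving between each pair of consecutive frames.

    An organelle moves across a frame pair when |Δposition| exceeds
    ``move_threshold`` (µm).  NaN where no organelle is observed in both
    frames of a pair.
    """
    dx = np.abs(np.diff(tracks.positions, axis=1))
    observed = np.isfinite(dx)
    moved = (dx > move_threshold) & observed
    n_obs = observed.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_obs > 0, moved.sum(axis=0) / n_obs, np.nan)


@dataclass
class PeriEventProfile:
    """Instantaneous motile fraction aligned on event onsets."""

    lag_centers: np.ndarray    # s, symmetric around 0
    mean: np.ndarray
    sem: np.ndarray
    per_event: np.ndarray      # (n_events, n_bins)
    n_events: int
    n_organelles: int

    def pre_post_difference(self) -> tuple[float, tuple[float, float]]:
        """Mean post − pre difference per event, with a 95% CI across events."""
        pre = np.nanmean(self.per_event[:, self.lag_centers < 0], axis=1)
        post = np.nanmean(self.per_event[:, self.lag_centers > 0], axis=1)
        d = post - pre
        d = d[np.isfinite(d)]
        m = float(np.mean(d))
        sem = float(np.std(d, ddof=1) / np.sqrt(len(d))) if len(d) > 1 else np.inf
        return m, (m - 1.96 * sem, m + 1.96 * sem)


def _event_onset_times(events, frame_interval: float) -> np.ndarray:
    if isinstance(events, EventSet):
        return events.onset_times
    return np.asarray(events, dtype=float)


def peri_event_motility(tracks: TrackSet, events, half_window: float = 10.0,
                        bin_s: float | None = None,
                        move_threshold: float = 0.4) -> PeriEventProfile:
    """Instantaneous motile fraction in lag bins around each event onset.

    ``events`` may be an :class:`EventSet` (sharing the tracks' time base) or
    an array of onset times in seconds.  ``bin_s`` defaults to one frame
    interval.
    """
    onsets = _event_onset_times(events, tracks.frame_interval)
    if len(onsets) == 0:
        raise ValueError("no events to align")
    if bin_s is None:
        bin_s = tracks.frame_interval
    inst = instantaneous_motile_series(tracks, move_threshold)
    pair_times = tracks.times[:-1] + tracks.frame_interval / 2.0
    n_half = int(np.ceil(half_window / bin_s))
    edges = (np.arange(-n_half, n_half + 1)) * bin_s
    centers = (edges[:-1] + edges[1:]) / 2.0
    per_event = np.full((len(onsets), len(centers)), np.nan)
    for k, t0 in enumerate(onsets):
        lag = pair_times - t0
        which = np.digitize(lag, edges) - 1
        ok = (which >= 0) & (which < len(centers)) & np.isfinite(inst)
        for b in np.unique(which[ok]):
            per_event[k, b] = np.nanmean(inst[ok & (which == b)])
    mean = np.nanmean(per_event, axis=0)
    with np.errstate(invalid="ignore"):
        n = np.sum(np.isfinite(per_event), axis=0)
        sem = np.nanstd(per_event, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
    return PeriEventProfile(lag_centers=centers, mean=mean, sem=sem,
                            per_event=per_event, n_events=len(onsets),
                            n_organelles=tracks.n_organelles)


@dataclass
class DeltaSpeedResult:
    """Per-organelle change in mean speed across events (post − pre)."""

    deltas: np.ndarray
    mean: float
    sem: float
    p_value: float
    n_included: int
    n_excluded: int
    window: float


def delta_speed(tracks: TrackSet, events, window: float = 5.0,
                min_pre_speed: float = 0.1) -> DeltaSpeedResult:
    """Mean speed in the ``window`` s after vs before each event onset.

    Only organelles moving in the pre window (mean speed above
    ``min_pre_speed`` µm/s) are included; the paired test is a two-sided
    Wilcoxon signed-rank across (organelle, event) pairs.
    """
    onsets = _event_onset_times(events, tracks.frame_interval)
    if len(onsets) == 0:
        raise ValueError("no events to align")
    speeds = tracks.step_speeds()
    pair_times = tracks.times[:-1] + tracks.frame_interval / 2.0
    deltas, excluded = [], 0
    for t0 in onsets:
        pre = (pair_times >= t0 - window) & (pair_times < t0)
        post = (pair_times >= t0) & (pair_times < t0 + window)
        if not pre.any() or not post.any():
            continue
        for i in range(tracks.n_organelles):
            v_pre = np.nanmean(speeds[i, pre])
            v_post = np.nanmean(speeds[i, post])
            if not np.isfinite(v_pre) or v_pre <= min_pre_speed:
                excluded += 1
                continue
            if np.isfinite(v_post):
                deltas.append(v_post - v_pre)
    deltas = np.asarray(deltas)
    if len(deltas) == 0:
        return DeltaSpeedResult(deltas=deltas, mean=np.nan, sem=np.nan,
                                p_value=np.nan, n_included=0,
                                n_excluded=excluded, window=window)
    mean = float(deltas.mean())
    sem = float(deltas.std(ddof=1) / np.sqrt(len(deltas))) if len(deltas) > 1 else np.inf
    if np.allclose(deltas, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(deltas).pvalue) if len(deltas) > 1 else np.nan
    return DeltaSpeedResult(deltas=deltas, mean=mean, sem=sem, p_value=p,
                            n_included=len(deltas), n_excluded=excluded,
                            window=window)


# -------------------------------------------------------------- correlation
@dataclass
class Correlogram:
    lags: np.ndarray         # s
    values: np.ndarray
    bin_s: float
    correction: str | None

    @property
    def zero_lag(self) -> float:
        return float(self.values[np.argmin(np.abs(self.lags))])

    @property
    def peak(self) -> float:
        return float(np.max(self.values))


def _as_binned(x, duration: float | None, bin_s: float) -> np.ndarray:
    if isinstance(x, ActivityTrace):
        return x.values.astype(float)
    x = np.asarray(x, dtype=float)
    if duration is None:
        raise ValueError("duration required for spike-time input")
    n = int(np.ceil(duration / bin_s))
    counts, _ = np.histogram(x, bins=n, range=(0, n * bin_s))
    return counts.astype(float)


def pairwise_correlation(a, b, bin_s: float = 0.1, max_lag: float = 5.0,
                         correction: str | None = "jitter",
                         jitter_window: float = 2.0,
                         duration: float | None = None) -> Correlogram:
    """Normalized cross-correlogram between two cells.

    Inputs may be spike-time arrays (binned at ``bin_s``; ``duration``
    required) or :class:`ActivityTrace` objects (``bin_s`` taken as their
    frame interval).  With ``correction="jitter"`` the expectation under
    slow-timescale rate comovement is removed by subtracting a boxcar-
    smoothed (width ``jitter_window``) rate from each binned train before
    Pearson-normalizing — rate-matched but independent trains then give a
    correlogram near 0 at all lags.  With ``correction=None`` the plain
    Pearson correlation per lag is returned (identical trains peak at 1 at
    lag 0).
    """
    if isinstance(a, ActivityTrace):
        bin_s = a.frame_interval
    xa = _as_binned(a, duration, bin_s)
    xb = _as_binned(b, duration, bin_s)
    n = min(len(xa), len(xb))
    xa, xb = xa[:n], xb[:n]
    if correction == "jitter":
        w = max(int(round(jitter_window / bin_s)), 1)
        kernel = np.ones(w) / w
        xa = xa - np.convolve(xa, kernel, mode="same")
        xb = xb - np.convolve(xb, kernel, mode="same")
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    xa = xa - xa.mean()
    xb = xb - xb.mean()
    sd = xa.std() * xb.std()
    max_shift = int(round(max_lag / bin_s))
    lags = np.arange(-max_shift, max_shift + 1)
    vals = np.empty(len(lags))
    for k, lag in enumerate(lags):
        if lag >= 0:
            seg_a, seg_b = xa[:n - lag] if lag else xa, xb[lag:]
        else:
            seg_a, seg_b = xa[-lag:], xb[:n + lag]
        vals[k] = np.mean(seg_a * seg_b) / sd if sd > 0 else 0.0
    return Correlogram(lags=lags * bin_s, values=vals, bin_s=bin_s,
                       correction=correction)
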