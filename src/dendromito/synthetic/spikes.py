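"""Correlated burst firing across neighboring cells.

Emulates propagating waves of activity: burst onsets shared across the
population arrive as a Poisson process; each cell joins a given burst with
``participation_prob`` and fires Poisson spikes at ``within_burst_rate``
while it lasts, plus an independent Poisson baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SpikeTrainSet:
    """Sorted spike times per unit, with unit positions for neighbor selection."""

    trains: list[np.ndarray]
    duration: float
    positions: np.ndarray | None = None   # (n_units, 2) µm cell-body positions

    def __post_init__(self):
        self.trains = [np.sort(np.asarray(t, dtype=float)) for t in self.trains]
        for t in self.trains:
            if len(t) and (t[0] < 0 or t[-1] > self.duration):
                raise ValueError("spike times outside [0, duration]")

    @property
    def n_units(self) -> int:
        return len(self.trains)

    def neighbor_pairs(self, max_distance: float = 200.0) -> list[tuple[int, int]]:
        """Unit pairs with cell bodies closer than ``max_distance`` µm."""
        if self.positions is None:
            return [(i, j) for i in range(self.n_units)
                    for j in range(i + 1, self.n_units)]
        out = []
        for i in range(self.n_units):
            for j in range(i + 1, self.n_units):
                if np.linalg.norm(self.positions[i] - self.positions[j]) < max_distance:
                    out.append((i, j))
        return out


def simulate_spike_trains(n_cells: int, duration: float,
                          burst_rate: float = 0.014,
                          within_burst_rate: float = 30.0,
                          burst_duration: float = 1.0,
                          participation_prob: float = 0.8,
                          baseline_rate: float = 0.5,
                          field_size_um: float = 200.0,
                          seed: int = 0) -> tuple[SpikeTrainSet, np.ndarray]:
    """Simulate a population of bursting cells; returns the trains and the
    shared burst-onset times."""
    rng = np.random.default_rng(seed)
    n_bursts = rng.poisson(burst_rate * duration)
    onsets = np.sort(rng.uniform(0, duration, size=n_bursts))
    trains = []
    for _ in range(n_cells):
        spikes = []
        if baseline_rate > 0:
            n_b = rng.poisson(baseline_rate * duration)
            spikes.append(rng.uniform(0, duration, size=n_b))
        for t0 in onsets:
            if rng.uniform() < participation_prob:
                n_s = rng.poisson(within_burst_rate * burst_duration)
                spikes.append(np.clip(t0 + rng.uniform(0, burst_duration, size=n_s),
                                      0, duration))
        trains.append(np.sort(np.concatenate(spikes)) if spikes else np.empty(0))
    positions = rng.uniform(0, field_size_um, size=(n_cells, 2))
    return SpikeTrainSet(trains=trains, duration=duration, positions=positions), onsets
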