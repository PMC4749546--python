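"""Stochastic dendritic arbor generator.

Grows a binary-branching tree in a thin 3-D slab — a stand-in for the planar,
stratified morphology of retinal ganglion cell dendrites.  Each branch event
converts one degree-2 node into a degree-3 node, so the number of branch
points equals ``n_branch_events`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..skeleton import ArborSkeleton

# internal morphology constants (µm): branch polylines are drawn with these
# lengths and a mild per-step direction wiggle
_TRUNK_LENGTH = 30.0
_BRANCH_LENGTH_MEAN = 25.0
_BRANCH_LENGTH_JITTER = 0.4          # uniform ±40% around the mean
_WIGGLE_SD = 0.15                    # radians per segment step
# capacity bound: µm of dendrite the field can plausibly hold per µm³
_LENGTH_PER_UM3 = 0.05


@dataclass(frozen=True)
class ArborParams:
    """Parameters of the synthetic arbor.

    ``segment_length_mean`` is the subdivision target: no skeleton link
    exceeds it.  ``field_extent`` is the (x, y, z) bounding box in µm; the
    slab is thin in z, mimicking stratified dendrites.
    """

    n_branch_events: int = 20
    segment_length_mean: float = 1.0
    branch_angle_spread: float = 0.6
    field_extent: tuple[float, float, float] = (120.0, 120.0, 10.0)
    dendrite_radius: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_branch_events < 0:
            raise ValueError("n_branch_events must be >= 0")
        if self.segment_length_mean <= 0:
            raise ValueError("segment_length_mean must be > 0")
        if self.dendrite_radius <= 0:
            raise ValueError("dendrite_radius must be > 0")


def generate_arbor(params: ArborParams) -> ArborSkeleton:
    """Grow a random arbor; deterministic given ``params.seed``.

    Raises
    ------
    ValueError
        If the requested number of branch events implies more dendrite than
        the field volume can hold.
    """
    ext = np.asarray(params.field_extent, dtype=float)
    capacity = _LENGTH_PER_UM3 * float(np.prod(np.maximum(ext, 1.0)))
    planned = _TRUNK_LENGTH + params.n_branch_events * _BRANCH_LENGTH_MEAN
    if planned > capacity:
        raise ValueError(
            f"n_branch_events={params.n_branch_events} implies ~{planned:.0f} µm of "
            f"dendrite, exceeding the {capacity:.0f} µm capacity of "
            f"field_extent={tuple(params.field_extent)}")

    rng = np.random.default_rng(params.seed)
    positions: list[np.ndarray] = []
    parent: list[int] = []
    degree: list[int] = []

    soma = np.array([ext[0] / 2, ext[1] / 2, ext[2] / 2])
    positions.append(soma)
    parent.append(-1)
    degree.append(0)

    def grow_path(start: int, direction: np.ndarray, length: float) -> None:
        """Append a wiggly polyline of ``length`` µm from node ``start``."""
        n_steps = max(int(np.ceil(length / params.segment_length_mean)), 1)
        step = length / n_steps
        d = direction / np.linalg.norm(direction)
        cur = start
        pos = positions[cur].copy()
        for _ in range(n_steps):
            theta = rng.normal(0.0, _WIGGLE_SD)
            c, s = np.cos(theta), np.sin(theta)
            d = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1],
                          d[2] + rng.normal(0.0, 0.02)])
            d /= np.linalg.norm(d)
            nxt = pos + step * d
            for ax in range(3):  # bounce off the field walls
                if nxt[ax] < 0 or nxt[ax] > ext[ax]:
                    d[ax] = -d[ax]
                    nxt[ax] = np.clip(nxt[ax], 0, ext[ax])
            positions.append(nxt)
            parent.append(cur)
            degree.append(1)
            degree[cur] += 1
            cur = len(positions) - 1
            pos = nxt

    # trunk
    phi = rng.uniform(0, 2 * np.pi)
    grow_path(0, np.array([np.cos(phi), np.sin(phi), 0.0]), _TRUNK_LENGTH)

    for _ in range(params.n_branch_events):
        eligible = [i for i in range(1, len(positions)) if degree[i] == 2]
        if not eligible:
            raise ValueError(
                f"cannot place {params.n_branch_events} branch events: ran out of "
                f"attachment sites within field_extent={tuple(params.field_extent)}")
        node = int(eligible[rng.integers(len(eligible))])
        # local direction at the attachment node, deflected sideways
        local = positions[node] - positions[parent[node]]
        theta = rng.choice([-1.0, 1.0]) * (np.pi / 4 + rng.normal(0.0, params.branch_angle_spread / 2))
        c, s = np.cos(theta), np.sin(theta)
        d = np.array([c * local[0] - s * local[1], s * local[0] + c * local[1], local[2]])
        length = _BRANCH_LENGTH_MEAN * rng.uniform(1 - _BRANCH_LENGTH_JITTER,
                                                   1 + _BRANCH_LENGTH_JITTER)
        grow_path(node, d, length)

    return ArborSkeleton(
        positions=np.array(positions),
        parent=np.array(parent, dtype=int),
        radius=np.full(len(positions), params.dendrite_radius),
    )
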