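"""Placement of synapses and mitochondria along a synthetic arbor.

Synapses follow a Poisson process of the stated linear density along arc
length.  Mitochondria are a three-component mixture: a fraction anchored
within ``capture_radius`` (geodesic) of a random synapse, a fraction anchored
near a random branch point, and the remainder uniform along arc length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..skeleton import ArborSkeleton, SkeletonPoints
from .truth import GroundTruth


@dataclass(frozen=True)
class PlacementParams:
    """Synapse/mitochondrion placement parameters.

    ``mito_volume_fraction`` sets the number of mitochondria through
    ``round(fraction * total_length / mito_length_um)``: with organelles of
    roughly ``mito_length_um`` length filling the dendrite cross-section, the
    linear packing fraction equals the volumetric fraction.
    """

    synapse_density: float = 0.5        # puncta per µm dendrite
    mito_volume_fraction: float = 0.1
    synapse_affinity: float = 0.0       # fraction anchored near synapses
    branch_affinity: float = 0.0        # fraction anchored near branch points
    capture_radius: float = 1.0         # µm
    mito_length_um: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.synapse_density < 0 or self.mito_volume_fraction < 0:
            raise ValueError("densities must be >= 0")
        if self.synapse_affinity < 0 or self.branch_affinity < 0:
            raise ValueError("affinities must be >= 0")
        if self.synapse_affinity + self.branch_affinity > 1 + 1e-12:
            raise ValueError("synapse_affinity + branch_affinity must be <= 1")


def place_organelles(skeleton: ArborSkeleton, params: PlacementParams) -> GroundTruth:
    """Place synapses and mitochondria; deterministic given ``params.seed``."""
    if skeleton.total_length <= 0:
        raise ValueError("skeleton has zero total length")
    rng = np.random.default_rng(params.seed)

    n_syn = rng.poisson(params.synapse_density * skeleton.total_length)
    synapses = skeleton.sample_uniform(n_syn, rng, label="synapse")

    n_mito = int(round(params.mito_volume_fraction * skeleton.total_length
                       / params.mito_length_um))
    u = rng.uniform(size=n_mito)
    near_syn = u < params.synapse_affinity
    near_branch = (~near_syn) & (u < params.synapse_affinity + params.branch_affinity)

    segs = np.empty(n_mito, dtype=int)
    offs = np.empty(n_mito)
    # uniform component
    uni = ~(near_syn | near_branch)
    if uni.any():
        pts = skeleton.sample_uniform(int(uni.sum()), rng)
        segs[uni], offs[uni] = pts.segment, pts.offset

    def _anchored(mask: np.ndarray, anchors: SkeletonPoints) -> None:
        if not mask.any():
            return
        if len(anchors) == 0:
            raise ValueError("affinity > 0 but no anchors available")
        idx = rng.integers(len(anchors), size=int(mask.sum()))
        out_s, out_o = [], []
        for k in idx:
            disp = rng.uniform(-params.capture_radius, params.capture_radius)
            s, o = skeleton.walk_from(int(anchors.segment[k]),
                                      float(anchors.offset[k]), disp, rng)
            out_s.append(s)
            out_o.append(o)
        segs[mask] = out_s
        offs[mask] = out_o

    _anchored(near_syn, synapses)
    if near_branch.any():
        branch_pts = skeleton.node_points(skeleton.branch_points)
        if len(branch_pts) == 0:
            raise ValueError("branch_affinity > 0 but skeleton has no branch points")
        _anchored(near_branch, branch_pts)

    mitochondria = SkeletonPoints(segment=segs, offset=offs, label="mitochondrion")
    truth = GroundTruth(skeleton=skeleton, synapses=synapses,
                        mitochondria=mitochondria, params=params)
    truth.validate()
    return truth
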