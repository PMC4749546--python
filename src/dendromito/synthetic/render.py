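"""Rasterization of synthetic scenes into noisy fluorescence images.

Channels are rendered as Gaussian-blurred impulses (organelles, puncta) or
tubes (the cytosolic fill channel), then corrupted with Poisson shot noise
and Gaussian read noise.  Arrays follow acquisition axis order (z, y, x);
world coordinates are (x, y, z) µm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ..images import VolumeStack, TimeLapse
from ..skeleton import ArborSkeleton, SkeletonPoints
from ..tracks import TrackSet
from .truth import GroundTruth

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RenderParams:
    voxel_size: tuple[float, ...] = (0.4, 0.2, 0.2)   # µm per (z, y, x) axis
    psf_sigma: tuple[float, ...] = (0.6, 0.25, 0.25)  # µm per (z, y, x) axis
    photon_scale: float = 200.0     # expected counts at unit brightness
    background: float = 5.0         # counts
    gaussian_read_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if np.any(np.asarray(self.voxel_size) <= 0):
            raise ValueError("voxel_size must be > 0")
        if np.any(np.asarray(self.psf_sigma) < 0):
            raise ValueError("psf_sigma must be >= 0")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be > 0")


@dataclass
class RenderedScene:
    """Rendered channels plus the rasterized ground truth behind them."""

    channels: dict[str, VolumeStack]
    origin_um: np.ndarray            # world (x, y, z) of voxel (0, ..., 0) center
    voxel_size: np.ndarray           # µm per array axis
    tube_mask: np.ndarray | None = None   # ground-truth dendrite voxels


def _check_sampling(params: RenderParams, ndim: int) -> None:
    vs = np.asarray(params.voxel_size[-ndim:])
    ps = np.asarray(params.psf_sigma[-ndim:])
    if np.any(vs > 2 * ps):
        log.warning("voxel size %s coarser than 2x psf sigma %s: undersampled render",
                    tuple(vs), tuple(ps))


def _splat(shape: tuple[int, ...], coords: np.ndarray,
           weights: np.ndarray | None = None) -> np.ndarray:
    """Multilinear deposit of unit (or weighted) impulses at fractional
    voxel coordinates ``(n, ndim)``; preserves sub-voxel centroids."""
    img = np.zeros(shape)
    if len(coords) == 0:
        return img
    w = np.ones(len(coords)) if weights is None else np.asarray(weights, float)
    ndim = coords.shape[1]
    base = np.floor(coords).astype(int)
    frac = coords - base
    for corner in range(2 ** ndim):
        offs = np.array([(corner >> k) & 1 for k in range(ndim)])
        idx = base + offs
        wt = w * np.prod(np.where(offs, frac, 1 - frac), axis=1)
        ok = np.all((idx >= 0) & (idx < np.array(shape)), axis=1)
        np.add.at(img, tuple(idx[ok].T), wt[ok])
    return img


def _peak_normalize(img: np.ndarray, psf_vox: np.ndarray) -> np.ndarray:
    """Scale a blurred impulse image so an isolated impulse peaks near 1
    (unit *brightness* rather than unit integrated mass)."""
    scale = float(np.prod(np.sqrt(2 * np.pi) * np.maximum(psf_vox, 1e-9)))
    return img * scale if np.all(psf_vox > 0) else img


def _apply_noise(signal: np.ndarray, params: RenderParams,
                 rng: np.random.Generator) -> np.ndarray:
    counts = rng.poisson(params.photon_scale * signal + params.background).astype(float)
    if params.gaussian_read_noise_sd > 0:
        counts = counts + rng.normal(0, params.gaussian_read_noise_sd, counts.shape)
    return np.maximum(counts, 0.0)


def _world_to_voxel(xyz_um: np.ndarray, origin: np.ndarray,
                    voxel_size: np.ndarray) -> np.ndarray:
    """(x, y, z) µm -> fractional array coordinates in (z, y, x) order."""
    rel = (np.atleast_2d(xyz_um) - origin) / np.array(
        [voxel_size[-1], voxel_size[-2], voxel_size[0]])
    return rel[:, ::-1]


def render_volume(truth: GroundTruth, params: RenderParams,
                  margin_um: float = 2.0) -> RenderedScene:
    """Render a static 3-D scene (cytosol tube, synapse and mito impulses).

    Deterministic given ``params.seed``.  An empty ground truth (no skeleton)
    is rendered as pure background noise on a small default grid.
    """
    rng = np.random.default_rng(params.seed)
    vs = np.asarray(params.voxel_size, dtype=float)   # (z, y, x)
    _check_sampling(params, 3)

    if truth.skeleton is None:
        shape = (8, 64, 64)
        channels = {
            name: VolumeStack(_apply_noise(np.zeros(shape), params, rng), vs, name)
            for name in ("cytosol", "synapses", "mito")}
        return RenderedScene(channels=channels, origin_um=np.zeros(3), voxel_size=vs)

    sk = truth.skeleton
    lo = sk.positions.min(axis=0) - margin_um
    hi = sk.positions.max(axis=0) + margin_um
    origin = lo
    extent = hi - lo
    shape = tuple(int(np.ceil(e / v)) + 1
                  for e, v in zip(extent[::-1], vs))      # (z, y, x)

    # dense samples along every edge for the tube
    step = float(min(vs)) / 2.0
    pts = []
    for i, (u, v) in enumerate(sk.edges):
        L = sk.edge_lengths[i]
        n = max(int(np.ceil(L / step)), 1)
        f = np.linspace(0, 1, n + 1)[:, None]
        pts.append(sk.positions[u] * (1 - f) + sk.positions[v] * f)
    pts = np.concatenate(pts)
    skel_vox = np.zeros(shape, dtype=bool)
    coords = np.round(_world_to_voxel(pts, origin, vs)).astype(int)
    ok = np.all((coords >= 0) & (coords < np.array(shape)), axis=1)
    skel_vox[tuple(coords[ok].T)] = True
    radius = float(np.median(sk.radius)) if sk.radius is not None else 0.5
    dist = ndimage.distance_transform_edt(~skel_vox, sampling=vs)
    tube = dist <= radius + float(min(vs)) / 2.0

    psf_vox = np.asarray(params.psf_sigma) / vs
    channels: dict[str, VolumeStack] = {}
    cyt = ndimage.gaussian_filter(tube.astype(float), psf_vox)
    channels["cytosol"] = VolumeStack(_apply_noise(cyt, params, rng), vs, "cytosol")

    for name, pset in (("synapses", truth.synapses), ("mito", truth.mitochondria)):
        img = np.zeros(shape)
        if pset is not None and len(pset):
            xyz = sk.point_xyz(pset)
            img = _splat(shape, _world_to_voxel(xyz, origin, vs))
            img = _peak_normalize(ndimage.gaussian_filter(img, psf_vox), psf_vox)
        channels[name] = VolumeStack(_apply_noise(img, params, rng), vs, name)

    return RenderedScene(channels=channels, origin_um=origin, voxel_size=vs,
                         tube_mask=tube)


def path_xy(polyline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative arc length and (n, 2) xy coordinates of a polyline."""
    xy = np.asarray(polyline, dtype=float)[:, :2]
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)]), xy


def arc_to_xy(arc: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Map arc-length positions (µm) to xy world coordinates on a polyline."""
    cum, xy = path_xy(polyline)
    arc = np.clip(np.asarray(arc, dtype=float), 0, cum[-1])
    return np.stack([np.interp(arc, cum, xy[:, 0]),
                     np.interp(arc, cum, xy[:, 1])], axis=-1)


def render_movie(tracks: TrackSet, polyline: np.ndarray, params: RenderParams,
                 margin_um: float = 3.0) -> tuple[TimeLapse, np.ndarray]:
    """Render a 2-D time-lapse of organelles moving along a path.

    Returns the movie and the path polyline expressed in image-relative µm
    (world minus origin), which downstream kymograph code consumes.
    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    vs = np.asarray(params.voxel_size[-2:], dtype=float)     # (y, x)
    _check_sampling(params, 2)
    cum, xy = path_xy(polyline)
    lo = xy.min(axis=0) - margin_um
    hi = xy.max(axis=0) + margin_um
    shape = (int(np.ceil((hi[1] - lo[1]) / vs[0])) + 1,
             int(np.ceil((hi[0] - lo[0]) / vs[1])) + 1)      # (y, x)
    psf_vox = np.asarray(params.psf_sigma[-2:]) / vs

    frames = np.empty((tracks.n_frames,) + shape)
    for f in range(tracks.n_frames):
        pos = tracks.positions[:, f]
        live = np.isfinite(pos)
        img = np.zeros(shape)
        if live.any():
            pxy = arc_to_xy(pos[live], polyline)
            coords = np.stack([(pxy[:, 1] - lo[1]) / vs[0],
                               (pxy[:, 0] - lo[0]) / vs[1]], axis=1)
            img = _splat(shape, coords)
            img = _peak_normalize(ndimage.gaussian_filter(img, psf_vox), psf_vox)
        frames[f] = _apply_noise(img, params, rng)

    rel = xy - lo
    return TimeLapse(frames=frames, frame_interval=tracks.frame_interval,
                     voxel_size=vs), rel


def render_path_still(polyline: np.ndarray, params: RenderParams,
                      margin_um: float = 3.0, tube_radius: float = 0.5,
                      ) -> VolumeStack:
    """Render a static 2-D cytosol-like image of the path tube, on the same
    grid :func:`render_movie` uses for the same polyline and margin."""
    rng = np.random.default_rng(params.seed + 1)
    vs = np.asarray(params.voxel_size[-2:], dtype=float)
    cum, xy = path_xy(polyline)
    lo = xy.min(axis=0) - margin_um
    hi = xy.max(axis=0) + margin_um
    shape = (int(np.ceil((hi[1] - lo[1]) / vs[0])) + 1,
             int(np.ceil((hi[0] - lo[0]) / vs[1])) + 1)
    step = float(min(vs)) / 2.0
    arc = np.arange(0.0, cum[-1] + step, step)
    pts = arc_to_xy(arc, polyline)
    img = np.zeros(shape, dtype=bool)
    iy = np.round((pts[:, 1] - lo[1]) / vs[0]).astype(int)
    ix = np.round((pts[:, 0] - lo[0]) / vs[1]).astype(int)
    ok = (iy >= 0) & (iy < shape[0]) & (ix >= 0) & (ix < shape[1])
    img[iy[ok], ix[ok]] = True
    dist = ndimage.distance_transform_edt(~img, sampling=vs)
    tube = (dist <= tube_radius + float(min(vs)) / 2.0).astype(float)
    tube = ndimage.gaussian_filter(tube, np.asarray(params.psf_sigma[-2:]) / vs)
    return VolumeStack(_apply_noise(tube, params, rng), vs, "cytosol")
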