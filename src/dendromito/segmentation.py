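"""From raw stacks to masks, skeletons, puncta and densities.

The chain is: cytosolic channel -> binary dendrite mask -> skeleton of ~1 µm
linked segments; synapse channel -> puncta by iterative thresholding within
the mask; organelle channel -> voxel mask by local thresholding within the
mask.  Density measures: mitochondrial volumetric fraction (organelle voxels
/ mask voxels) and synapses per µm of skeleton.

All geometry is computed in µm (anisotropic voxels supported); voxel indices
are 0-based and positions sit at ``index * voxel_size`` in image-local
coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import ndimage
from skimage import filters, morphology

from .images import VolumeStack
from .skeleton import ArborSkeleton

log = logging.getLogger(__name__)

__all__ = [
    "DendriteMask", "PunctaSet", "OrganelleMask", "make_dendrite_mask",
    "skeletonize_mask", "detect_synapses", "detect_mitochondria",
    "mito_density", "synapse_density",
]


@dataclass
class DendriteMask:
    """Binary dendrite mask with the thresholding provenance that made it."""

    mask: np.ndarray
    voxel_size: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_size = np.atleast_1d(np.asarray(self.voxel_size, dtype=float))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class PunctaSet:
    """Detected puncta: label image plus per-punctum measurements."""

    labels: np.ndarray            # 0 = background, 1..n = puncta
    centroids_um: np.ndarray      # (n, ndim) in (x, y[, z]) µm, image-local
    voxel_counts: np.ndarray
    intensities: np.ndarray       # integrated intensity per punctum
    voxel_size: np.ndarray
    channel_name: str = ""

    @property
    def n_puncta(self) -> int:
        return len(self.voxel_counts)

    def volumes_um3(self) -> np.ndarray:
        return self.voxel_counts * float(np.prod(self.voxel_size))


@dataclass
class OrganelleMask:
    """Binary organelle voxel mask with its connected components."""

    mask: np.ndarray
    labels: np.ndarray
    centroids_um: np.ndarray
    voxel_counts: np.ndarray
    voxel_size: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.voxel_counts)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _vox_to_um(coords: np.ndarray, voxel_size: np.ndarray) -> np.ndarray:
    """Array-order (z, y, x) voxel coordinates -> (x, y, z) µm."""
    um = np.atleast_2d(coords) * voxel_size
    return um[:, ::-1]


def make_dendrite_mask(cytosol: VolumeStack, method: str = "otsu",
                       quantile: float = 0.95,
                       min_object_volume: float = 1.0,
                       closing_radius: float = 0.3,
                       on_degenerate: str = "error") -> DendriteMask:
    """Binary dendrite mask from the cytosolic channel.

    ``method``: ``"otsu"`` (global Otsu threshold), ``"quantile"``
    (intensity quantile) or ``"fraction"`` (``quantile`` × max intensity —
    a half-maximum cut when ``quantile=0.5``, appropriate for clean
    renders).  Small objects below ``min_object_volume`` µm³ are
    removed and the mask is morphologically closed with a ``closing_radius``
    µm ball.  A constant image raises, or returns an empty mask with
    ``on_degenerate="empty"``.
    """
    img = cytosol.intensities.astype(float)
    if not np.any(img > 0):
        raise ValueError("empty channel: all-zero stack")
    if img.max() == img.min():
        if on_degenerate == "empty":
            return DendriteMask(np.zeros(img.shape, bool), cytosol.voxel_size,
                                {"method": method, "degenerate": True})
        raise ValueError("degenerate (constant) image; pass on_degenerate='empty'")
    if method == "otsu":
        thr = float(filters.threshold_otsu(img))
    elif method == "quantile":
        thr = float(np.quantile(img, quantile))
    elif method == "fraction":
        thr = float(quantile * img.max())
    else:
        raise ValueError(f"unknown method {method!r}")
    mask = img > thr
    vox_vol = float(np.prod(cytosol.voxel_size))
    min_vox = max(int(round(min_object_volume / vox_vol)), 1)
    if min_vox > 1:
        mask = morphology.remove_small_objects(mask, max_size=min_vox - 1)
    rad_vox = np.maximum(np.round(closing_radius / cytosol.voxel_size), 0).astype(int)
    if rad_vox.max() > 0:
        se = np.ones(2 * rad_vox + 1, dtype=bool)
        mask = ndimage.binary_closing(mask, structure=se)
    prov = {"method": method, "threshold": thr, "quantile": quantile,
            "min_object_volume_um3": min_object_volume,
            "closing_radius_um": closing_radius}
    return DendriteMask(mask, cytosol.voxel_size, prov)


# ------------------------------------------------------------- skeletonize
_NEIGHBOR_OFFSETS_CACHE: dict[int, np.ndarray] = {}


def _neighbor_offsets(ndim: int) -> np.ndarray:
    if ndim not in _NEIGHBOR_OFFSETS_CACHE:
        grids = np.meshgrid(*([[-1, 0, 1]] * ndim), indexing="ij")
        offs = np.stack([g.ravel() for g in grids], axis=1)
        offs = offs[np.any(offs != 0, axis=1)]
        _NEIGHBOR_OFFSETS_CACHE[ndim] = offs
    return _NEIGHBOR_OFFSETS_CACHE[ndim]


def skeletonize_mask(mask: DendriteMask, target_segment_length: float = 1.0,
                     prune_length: float = 2.0) -> ArborSkeleton:
    """Medial-axis skeleton resampled into linked segments of at most
    ``target_segment_length`` µm.

    Keeps the largest connected component (logging any discards), reduces
    the skeleton-voxel adjacency graph to a tree by minimum spanning tree,
    prunes side spurs shorter than ``prune_length`` µm, and resamples every
    junction-to-junction path at even spacing.  The root is the endpoint
    with the lexicographically smallest voxel coordinate.
    """
    m = mask.mask
    structure = ndimage.generate_binary_structure(m.ndim, m.ndim)
    labels, n = ndimage.label(m, structure=structure)
    if n == 0:
        raise ValueError("empty mask")
    if n > 1:
        sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        log.info("skeletonize: discarding %d smaller components", n - 1)
        m = labels == keep

    skel = morphology.skeletonize(m)
    coords = np.argwhere(skel)
    if len(coords) == 0:
        raise ValueError("skeletonization produced no voxels")
    index = {tuple(c): i for i, c in enumerate(coords)}
    vs = mask.voxel_size
    g = nx.Graph()
    g.add_nodes_from(range(len(coords)))
    for off in _neighbor_offsets(m.ndim):
        for i, c in enumerate(coords):
            j = index.get(tuple(c + off))
            if j is not None and j > i:
                g.add_edge(i, j, weight=float(np.linalg.norm(off * vs)))
    g = nx.minimum_spanning_tree(g)

    # spur pruning: repeatedly remove leaf paths shorter than prune_length
    # that terminate at a junction
    changed = True
    while changed:
        changed = False
        for leaf in [v for v in g.nodes if g.degree(v) == 1]:
            path = [leaf]
            length = 0.0
            cur, prev = leaf, None
            while g.degree(cur) <= 2:
                nbrs = [w for w in g.neighbors(cur) if w != prev]
                if not nbrs:
                    break
                nxt = nbrs[0]
                length += g.edges[cur, nxt]["weight"]
                prev, cur = cur, nxt
                if g.degree(cur) >= 3:
                    if length < prune_length:
                        g.remove_nodes_from(path)
                        changed = True
                    break
                path.append(cur)
            if changed:
                break

    # root: endpoint with smallest voxel coordinate (deterministic)
    ends = [v for v in g.nodes if g.degree(v) == 1] or list(g.nodes)[:1]
    root_vox = min(ends, key=lambda v: tuple(coords[v]))

    # walk junction-to-junction paths from the root, resampling each
    positions: list[np.ndarray] = []
    parent: list[int] = []

    def um(vox_id: int) -> np.ndarray:
        return _vox_to_um(coords[vox_id], vs)[0]

    positions.append(um(root_vox))
    parent.append(-1)
    node_of = {root_vox: 0}
    stack = [(root_vox, nb) for nb in g.neighbors(root_vox)]
    visited_edges = set()
    while stack:
        start, first = stack.pop()
        if (start, first) in visited_edges:
            continue
        # trace voxel path until the next junction/endpoint
        path_vox = [start, first]
        visited_edges.add((start, first))
        visited_edges.add((first, start))
        while g.degree(path_vox[-1]) == 2:
            nbrs = [w for w in g.neighbors(path_vox[-1]) if w != path_vox[-2]]
            if not nbrs:
                break
            path_vox.append(nbrs[0])
            visited_edges.add((path_vox[-2], path_vox[-1]))
            visited_edges.add((path_vox[-1], path_vox[-2]))
        pts = np.stack([um(v) for v in path_vox])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        n_links = max(int(np.ceil(cum[-1] / target_segment_length)), 1)
        samples = np.linspace(0.0, cum[-1], n_links + 1)[1:]
        prev_node = node_of[start]
        for k, s in enumerate(samples):
            p = np.array([np.interp(s, cum, pts[:, d]) for d in range(pts.shape[1])])
            end_vox = path_vox[-1]
            if k == len(samples) - 1 and end_vox in node_of:
                # closing onto an existing node would form a cycle; MST
                # guarantees this cannot happen on distinct paths
                break
            positions.append(p)
            parent.append(prev_node)
            prev_node = len(positions) - 1
            if k == len(samples) - 1:
                node_of[end_vox] = prev_node
        end_vox = path_vox[-1]
        for nb in g.neighbors(end_vox):
            if (end_vox, nb) not in visited_edges:
                stack.append((end_vox, nb))

    pos = np.stack(positions)
    if pos.shape[1] == 2:    # 2-D images: embed in z = 0
        pos = np.column_stack([pos, np.zeros(len(pos))])
    return ArborSkeleton(positions=pos, parent=np.asarray(parent, int))


# ---------------------------------------------------------------- puncta
def detect_synapses(psd95: VolumeStack, mask: DendriteMask,
                    q_start: float = 0.999, q_floor: float = 0.90,
                    n_steps: int = 20,
                    min_volume: float = 0.05, max_volume: float = 3.0,
                    ) -> PunctaSet:
    """Iterative-threshold puncta detection within the dendrite mask.

    The threshold starts at the ``q_start`` intensity quantile (computed
    within the mask) and steps down to ``q_floor``.  At each step, connected
    components whose volume lies in [``min_volume``, ``max_volume``] µm³ and
    which do not touch an already accepted punctum are accepted and frozen —
    the freeze prevents two nearby puncta from merging as the threshold
    drops.  Centroids are intensity-weighted (sub-voxel).
    """
    if mask.n_voxels == 0:
        raise ValueError("empty dendrite mask")
    img = psd95.intensities.astype(float)
    inside = img[mask.mask]
    thresholds = np.quantile(inside, np.linspace(q_start, q_floor, n_steps))
    vox_vol = float(np.prod(psd95.voxel_size))
    min_vox = max(int(np.ceil(min_volume / vox_vol)), 1)
    max_vox = int(np.floor(max_volume / vox_vol))
    structure = ndimage.generate_binary_structure(img.ndim, img.ndim)

    accepted = np.zeros(img.shape, dtype=np.int32)
    n_accepted = 0
    for thr in thresholds:
        supra = (img >= thr) & mask.mask
        cand = supra | (accepted > 0)
        lab, n = ndimage.label(cand, structure=structure)
        if n == 0:
            continue
        touches = np.zeros(n + 1, dtype=bool)
        touches[np.unique(lab[accepted > 0])] = True
        sizes = ndimage.sum_labels(cand, lab, index=np.arange(1, n + 1))
        for comp in range(1, n + 1):
            if touches[comp]:
                continue
            if min_vox <= sizes[comp - 1] <= max_vox:
                n_accepted += 1
                accepted[lab == comp] = n_accepted
    centroids, counts, intens = [], [], []
    for pid in range(1, n_accepted + 1):
        sel = np.argwhere(accepted == pid)
        w = img[tuple(sel.T)]
        c_vox = (sel * w[:, None]).sum(axis=0) / w.sum()
        centroids.append(_vox_to_um(c_vox, psd95.voxel_size)[0])
        counts.append(len(sel))
        intens.append(float(w.sum()))
    ndim = img.ndim
    return PunctaSet(labels=accepted,
                     centroids_um=np.array(centroids).reshape(-1, ndim),
                     voxel_counts=np.array(counts, dtype=int),
                     intensities=np.array(intens),
                     voxel_size=psd95.voxel_size, channel_name=psd95.channel_name)


def detect_mitochondria(mito: VolumeStack, mask: DendriteMask,
                        window_um: float = 3.0, k: float = 2.0,
                        min_volume: float = 0.05) -> OrganelleMask:
    """Local (neighborhood-window) thresholding of the organelle channel
    within the dendrite mask.

    A voxel is organelle when its intensity exceeds the local mean plus
    ``k`` local standard deviations in a ``window_um`` cube.  Components
    smaller than ``min_volume`` µm³ are dropped.
    """
    img = mito.intensities.astype(float)
    size = np.maximum((window_um / mito.voxel_size).astype(int) | 1, 3)
    local_mean = ndimage.uniform_filter(img, size=size)
    local_sq = ndimage.uniform_filter(img ** 2, size=size)
    local_sd = np.sqrt(np.maximum(local_sq - local_mean ** 2, 0.0))
    # epsilon guards against separable-filter round-off going negative in
    # signal-free regions, which would otherwise pass "0 > threshold"
    eps = 1e-6 * max(float(img.max()), 1.0)
    out = (img > local_mean + k * local_sd + eps) & mask.mask
    vox_vol = float(np.prod(mito.voxel_size))
    min_vox = max(int(np.ceil(min_volume / vox_vol)), 1)
    structure = ndimage.generate_binary_structure(img.ndim, img.ndim)
    if min_vox > 1:
        out = morphology.remove_small_objects(out, max_size=min_vox - 1)
    labels, n = ndimage.label(out, structure=structure)
    if n:
        idx = np.arange(1, n + 1)
        counts = ndimage.sum_labels(out, labels, index=idx).astype(int)
        cents = np.array(ndimage.center_of_mass(img * out, labels, index=idx))
        centroids = _vox_to_um(cents, mito.voxel_size)
    else:
        counts = np.empty(0, dtype=int)
        centroids = np.empty((0, img.ndim))
    return OrganelleMask(mask=out, labels=labels, centroids_um=centroids,
                         voxel_counts=counts, voxel_size=mito.voxel_size)


# --------------------------------------------------------------- densities
def mito_density(mito: OrganelleMask, mask: DendriteMask) -> float:
    """Mitochondrial volumetric fraction: organelle voxels / mask voxels."""
    if mask.n_voxels == 0:
        raise ValueError("empty dendrite mask")
    return mito.n_voxels / mask.n_voxels


def synapse_density(puncta: PunctaSet, skeleton: ArborSkeleton) -> float:
    """Synapses per µm of dendrite."""
    if skeleton.total_length <= 0:
        raise ValueError("zero-length skeleton")
    return puncta.n_puncta / skeleton.total_length
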