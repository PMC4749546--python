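"""Dendritic arbor skeletons and geodesic geometry.

The skeleton is the coordinate system for every spatial statistic in this
package: a rooted tree of short (~1 µm) links with positions in µm.  Points
on the skeleton (synapses, mitochondria, track positions) are addressed as
``(segment id, arc offset)`` pairs, and all distances between them are
measured along the tree unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
import networkx as nx
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "ArborSkeleton",
    "SkeletonPoints",
    "GeodesicField",
    "read_swc",
    "write_swc",
]


@dataclass(frozen=True)
class ArborSkeleton:
    """Rooted geometric tree of short linked segments.

    Parameters
    ----------
    positions
        ``(n_nodes, 3)`` node coordinates in µm.
    parent
        ``(n_nodes,)`` integer parent ids; exactly one entry is ``-1`` (root).
    radius
        Optional per-node radius in µm (kept for SWC round-trips).

    Every non-root node defines one *segment* (the edge to its parent);
    segment ``i`` is the edge owned by the ``i``-th non-root node in id
    order, so segment ids are stable and reproducible.
    """

    positions: np.ndarray
    parent: np.ndarray
    radius: np.ndarray | None = None

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        par = np.asarray(self.parent, dtype=int)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "parent", par)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if par.shape != (pos.shape[0],):
            raise ValueError("parent must be (n,)")
        roots = np.flatnonzero(par < 0)
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, got {len(roots)}")
        # parent pointers on a valid tree always point to already-seen nodes
        # when traversed from the root; detect cycles by walking up.
        order = np.argsort(par)  # root first
        seen = np.zeros(len(par), bool)
        for i in order:
            p = par[i]
            if p >= 0 and not seen[p]:
                raise ValueError("parent array is not topologically ordered / contains a cycle")
            seen[i] = True

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @cached_property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @cached_property
    def edges(self) -> np.ndarray:
        """``(n_segments, 2)`` array of (parent, child) node ids, child-sorted."""
        children = np.flatnonzero(self.parent >= 0)
        return np.stack([self.parent[children], children], axis=1)

    @cached_property
    def edge_lengths(self) -> np.ndarray:
        u, v = self.edges[:, 0], self.edges[:, 1]
        return np.linalg.norm(self.positions[v] - self.positions[u], axis=1)

    @property
    def n_segments(self) -> int:
        return self.edges.shape[0]

    @cached_property
    def total_length(self) -> float:
        return float(self.edge_lengths.sum())

    @cached_property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    @cached_property
    def branch_points(self) -> np.ndarray:
        """Node ids of degree >= 3."""
        return np.flatnonzero(self.degrees >= 3)

    @cached_property
    def leaves(self) -> np.ndarray:
        deg1 = np.flatnonzero(self.degrees == 1)
        return deg1[deg1 != self.root] if self.degrees[self.root] > 1 else deg1

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for i, (u, v) in enumerate(self.edges):
            g.add_edge(int(u), int(v), weight=float(self.edge_lengths[i]), segment=i)
        return g

    @cached_property
    def _adjacency(self) -> csr_matrix:
        u, v = self.edges[:, 0], self.edges[:, 1]
        w = self.edge_lengths
        n = self.n_nodes
        return csr_matrix(
            (np.concatenate([w, w]), (np.concatenate([u, v]), np.concatenate([v, u]))),
            shape=(n, n),
        )

    @cached_property
    def _node_edges(self) -> list[list[int]]:
        """Incident segment ids per node."""
        inc: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, (u, v) in enumerate(self.edges):
            inc[int(u)].append(i)
            inc[int(v)].append(i)
        return inc

    # -------------------------------------------------------------- geometry
    def point_xyz(self, points: "SkeletonPoints") -> np.ndarray:
        """Cartesian µm coordinates of skeleton points."""
        e = points.segment
        u, v = self.edges[e, 0], self.edges[e, 1]
        L = self.edge_lengths[e]
        frac = np.where(L > 0, points.offset / np.where(L > 0, L, 1.0), 0.0)
        return self.positions[u] + frac[:, None] * (self.positions[v] - self.positions[u])

    def sample_uniform(self, n: int, rng: np.random.Generator,
                       label: str = "") -> "SkeletonPoints":
        """Draw ``n`` points uniformly along total arc length."""
        if self.total_length <= 0:
            raise ValueError("cannot sample on a zero-length skeleton")
        cum = np.concatenate([[0.0], np.cumsum(self.edge_lengths)])
        u = rng.uniform(0.0, self.total_length, size=n)
        seg = np.clip(np.searchsorted(cum, u, side="right") - 1, 0, self.n_segments - 1)
        return SkeletonPoints(segment=seg, offset=u - cum[seg], label=label)

    def project(self, xyz: np.ndarray, label: str = "",
                chunk: int = 2000) -> tuple["SkeletonPoints", np.ndarray]:
        """Map Cartesian points to their nearest skeleton point (Euclidean).

        Returns the projected points and the projection distances.  Ties are
        broken toward the lowest segment id.
        """
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        a = self.positions[self.edges[:, 0]]          # (E, 3)
        d = self.positions[self.edges[:, 1]] - a      # (E, 3)
        L2 = np.maximum(np.einsum("ij,ij->i", d, d), 1e-300)
        segs = np.empty(len(xyz), dtype=int)
        offs = np.empty(len(xyz))
        dists = np.empty(len(xyz))
        for s in range(0, len(xyz), chunk):
            p = xyz[s:s + chunk]
            t = np.clip(((p[:, None, :] - a[None]) * d[None]).sum(-1) / L2, 0.0, 1.0)
            foot = a[None] + t[..., None] * d[None]
            dd = np.linalg.norm(p[:, None, :] - foot, axis=-1)
            best = np.argmin(dd, axis=1)  # first (lowest segment id) on ties
            idx = np.arange(len(p))
            segs[s:s + chunk] = best
            offs[s:s + chunk] = t[idx, best] * np.sqrt(L2[best])
            dists[s:s + chunk] = dd[idx, best]
        return SkeletonPoints(segment=segs, offset=offs, label=label), dists

    def node_points(self, node_ids: Iterable[int], label: str = "") -> "SkeletonPoints":
        """Represent nodes as skeleton points (offset 0 or L on an incident segment)."""
        segs, offs = [], []
        for nid in node_ids:
            e = self._node_edges[int(nid)][0]
            if self.edges[e, 0] == nid:
                segs.append(e); offs.append(0.0)
            else:
                segs.append(e); offs.append(float(self.edge_lengths[e]))
        return SkeletonPoints(segment=np.array(segs, int), offset=np.array(offs), label=label)

    def walk_from(self, segment: int, offset: float, distance: float,
                  rng: np.random.Generator) -> tuple[int, float]:
        """Walk ``|distance|`` µm along the tree from a point, choosing branches
        uniformly at junctions; clamps at leaves.  Sign of ``distance`` picks
        the initial direction (negative: toward the segment's parent node)."""
        seg = int(segment)
        remaining = abs(float(distance))
        # current direction: node we are heading toward
        toward = int(self.edges[seg, 1] if distance >= 0 else self.edges[seg, 0])
        pos = float(offset)
        while remaining > 0:
            L = float(self.edge_lengths[seg])
            if toward == self.edges[seg, 1]:
                room = L - pos
                if remaining <= room:
                    return seg, pos + remaining
            else:
                room = pos
                if remaining <= room:
                    return seg, pos - remaining
            remaining -= room
            # arrived at node `toward`; pick a new incident edge
            options = [e for e in self._node_edges[toward] if e != seg]
            if not options:
                return seg, (L if toward == self.edges[seg, 1] else 0.0)
            seg = int(options[rng.integers(len(options))])
            if self.edges[seg, 0] == toward:
                pos, toward = 0.0, int(self.edges[seg, 1])
            else:
                pos, toward = float(self.edge_lengths[seg]), int(self.edges[seg, 0])
        return seg, pos

    def longest_path(self) -> np.ndarray:
        """Node ids of the longest root-to-leaf path (a natural track substrate)."""
        g = self.to_graph()
        dist = nx.single_source_dijkstra_path_length(g, self.root)
        far = max(dist, key=dist.get)
        return np.array(nx.dijkstra_path(g, self.root, far), dtype=int)

    def path_polyline(self, node_path: Sequence[int]) -> np.ndarray:
        """(n, 3) µm polyline through the given consecutive node ids."""
        return self.positions[np.asarray(node_path, int)]

    def validate_segment_length(self, target: float, tol: float = 0.1) -> bool:
        return bool(np.all(self.edge_lengths <= target * (1.0 + tol) + 1e-9))


@dataclass
class SkeletonPoints:
    """Labelled point set on an :class:`ArborSkeleton`.

    ``segment`` indexes the skeleton's segment list; ``offset`` is the arc
    distance in µm from the segment's parent-side node.  ``weight`` carries a
    per-point amount (e.g. projected voxel counts) and defaults to 1.
    """

    segment: np.ndarray
    offset: np.ndarray
    label: str = ""
    weight: np.ndarray | None = None

    def __post_init__(self):
        self.segment = np.asarray(self.segment, dtype=int)
        self.offset = np.asarray(self.offset, dtype=float)
        if self.weight is not None:
            self.weight = np.asarray(self.weight, dtype=float)

    def __len__(self) -> int:
        return len(self.segment)

    def weights(self) -> np.ndarray:
        return self.weight if self.weight is not None else np.ones(len(self))

    def validate_on(self, skeleton: ArborSkeleton) -> None:
        if np.any(self.segment < 0) or np.any(self.segment >= skeleton.n_segments):
            raise ValueError("segment id out of range")
        L = skeleton.edge_lengths[self.segment]
        if np.any(self.offset < -1e-9) or np.any(self.offset > L + 1e-9):
            raise ValueError("offset outside segment length")


class GeodesicField:
    """Geodesic distance from anywhere on the skeleton to a fixed target set.

    Precomputes, by multi-source Dijkstra, the distance from every node to
    the nearest target; querying a point then costs O(1) plus a same-segment
    correction for targets sharing the query's segment.
    """

    def __init__(self, skeleton: ArborSkeleton, targets: SkeletonPoints):
        if len(targets) == 0:
            raise ValueError("no targets")
        targets.validate_on(skeleton)
        self.skeleton = skeleton
        self.targets = targets
        n = skeleton.n_nodes
        u = skeleton.edges[targets.segment, 0]
        v = skeleton.edges[targets.segment, 1]
        L = skeleton.edge_lengths[targets.segment]
        # virtual source row: source -> u at cost offset, -> v at cost L-offset
        # (weights clamped away from 0: sparse graphs drop explicit zeros)
        cols = np.concatenate([u, v])
        data = np.maximum(np.concatenate([targets.offset, L - targets.offset]), 1e-12)
        best: dict[int, float] = {}
        for c, w in zip(cols.tolist(), data.tolist()):
            if w < best.get(c, np.inf):
                best[c] = w
        adj = skeleton._adjacency.tocoo()
        vc = np.fromiter(best.keys(), dtype=int)
        vw = np.fromiter(best.values(), dtype=float)
        rows = np.concatenate([adj.row, np.full(len(vc), n), vc])
        ccols = np.concatenate([adj.col, vc, np.full(len(vc), n)])
        vals = np.concatenate([adj.data, vw, vw])
        m = csr_matrix((vals, (rows, ccols)), shape=(n + 1, n + 1))
        self.node_dist = dijkstra(m, indices=n)[:n]
        # same-segment targets, grouped and offset-sorted
        order = np.argsort(targets.segment, kind="stable")
        self._tgt_segments, starts = np.unique(targets.segment[order],
                                               return_index=True)
        self._tgt_slices = np.append(starts, len(order))
        self._tgt_offsets = [np.sort(targets.offset[order][s:e2])
                             for s, e2 in zip(self._tgt_slices[:-1],
                                              self._tgt_slices[1:])]

    def distance(self, points: SkeletonPoints) -> np.ndarray:
        sk = self.skeleton
        e = points.segment
        t = points.offset
        u, v = sk.edges[e, 0], sk.edges[e, 1]
        L = sk.edge_lengths[e]
        d = np.minimum(self.node_dist[u] + t, self.node_dist[v] + (L - t))
        # same-segment correction, grouping queries by segment once
        order = np.argsort(e, kind="stable")
        qseg = e[order]
        lo = np.searchsorted(qseg, self._tgt_segments, side="left")
        hi = np.searchsorted(qseg, self._tgt_segments, side="right")
        for k in range(len(self._tgt_segments)):
            if lo[k] == hi[k]:
                continue
            idx = order[lo[k]:hi[k]]
            tt = t[idx]
            offs = self._tgt_offsets[k]
            j = np.clip(np.searchsorted(offs, tt), 0, len(offs) - 1)
            near = np.minimum(np.abs(offs[j] - tt),
                              np.abs(offs[np.maximum(j - 1, 0)] - tt))
            d[idx] = np.minimum(d[idx], near)
        return d


# ------------------------------------------------------------------- SWC I/O
def write_swc(skeleton: ArborSkeleton, path) -> None:
    """Write standard 7-column SWC (ids are 1-based, type 3 = dendrite)."""
    rad = skeleton.radius if skeleton.radius is not None else np.full(skeleton.n_nodes, 0.5)
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(skeleton.n_nodes):
            x, y, z = skeleton.positions[i]
            p = skeleton.parent[i]
            fh.write(f"{i + 1} 3 {x:.4f} {y:.4f} {z:.4f} {rad[i]:.3f} "
                     f"{p + 1 if p >= 0 else -1}\n")


def read_swc(path) -> ArborSkeleton:
    ids, xyz, rad, par = [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split()
            ids.append(int(f[0]))
            xyz.append([float(f[2]), float(f[3]), float(f[4])])
            rad.append(float(f[5]))
            par.append(int(f[6]))
    remap = {old: new for new, old in enumerate(ids)}
    parent = np.array([remap[p] if p != -1 else -1 for p in par], dtype=int)
    return ArborSkeleton(positions=np.array(xyz), parent=parent, radius=np.array(rad))
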