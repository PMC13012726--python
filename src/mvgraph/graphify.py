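"""Centerline skeletonization and vascular graph construction.

A cleaned, unioned vessel mask is thinned to a one-voxel centerline, short
terminal "hair" branches (thinning artifacts) are pruned, and the skeleton
is rendered as a graph: branch points and endpoints become nodes, maximal
degree-2 chains become vessel-segment edges carrying an ordered vertex path
in micrometers.  Vertex positions are then low-pass filtered along each
edge and unit tangents computed for orthogonal-plane extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from skimage.morphology import skeletonize as _sk_skeletonize

from .volume import BinaryMask

_OFFSETS = np.array(
    [(dz, dy, dx)
     for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
     if (dz, dy, dx) != (0, 0, 0)]
)


@dataclass
class Skeleton:
    """One-voxel-thick centerline: a set of voxel indices on a known grid."""

    voxels: np.ndarray  # (n, 3) int indices (z, y, x)
    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.int64).reshape(-1, 3)

    def __len__(self) -> int:
        return self.voxels.shape[0]

    def to_mask(self) -> BinaryMask:
        m = np.zeros(self.shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return BinaryMask(m, self.voxel_size)


@dataclass
class VascularGraph:
    """Junction/endpoint nodes plus vessel-segment edges.

    Wraps a :class:`networkx.MultiGraph`; node attributes: ``position``
    (μm), ``degree``.  Edge attributes: ``path`` (ordered vertex positions,
    μm), ``path_voxels``, ``length`` (polyline arc length, μm), and after
    :func:`smooth_and_tangents` also ``path_smooth`` and ``tangent``.
    """

    graph: nx.MultiGraph
    voxel_size: tuple[float, float, float]

    @property
    def n_junctions(self) -> int:
        return sum(1 for n, d in self.graph.nodes(data=True) if d["degree"] >= 3)

    @property
    def n_endpoints(self) -> int:
        return sum(1 for n, d in self.graph.nodes(data=True) if d["degree"] == 1)

    @property
    def n_segments(self) -> int:
        return self.graph.number_of_edges()

    def edges(self):
        return self.graph.edges(keys=True, data=True)

    def vertex_table(self) -> pd.DataFrame:
        rows = []
        for eid, (u, v, k, data) in enumerate(self.edges()):
            path = data["path_smooth"] if "path_smooth" in data else data["path"]
            tang = data.get("tangent")
            for vi, p in enumerate(path):
                row = {"edge": eid, "vertex": vi,
                       "z": p[0], "y": p[1], "x": p[2]}
                if tang is not None:
                    row.update(tz=tang[vi, 0], ty=tang[vi, 1], tx=tang[vi, 2])
                rows.append(row)
        return pd.DataFrame(rows)


def skeletonize(mask: BinaryMask) -> Skeleton:
    """Thin a cleaned mask to its one-voxel medial centerline.

    Uses homotopy-preserving 3D thinning; the skeleton stays connected
    wherever the mask is connected.
    """
    if not mask.voxels.any():
        raise ValueError("cannot skeletonize an empty mask")
    skel = _sk_skeletonize(mask.voxels)
    if not skel.any():
        # parallel thinning can annihilate perfectly even-width symmetric
        # objects; thin at doubled resolution and map the line back
        up = mask.voxels.repeat(2, 0).repeat(2, 1).repeat(2, 2)
        idx = np.argwhere(_sk_skeletonize(up)) // 2
        mapped = np.zeros(mask.shape, dtype=bool)
        mapped[tuple(idx.T)] = True
        rethinned = _sk_skeletonize(mapped)
        skel = rethinned if rethinned.any() else mapped
    if not skel.any():
        raise RuntimeError("thinning produced an empty skeleton")
    return Skeleton(np.argwhere(skel), mask.shape, mask.voxel_size)


def _index(voxels: np.ndarray) -> dict:
    return {tuple(v): i for i, v in enumerate(voxels)}


def _neighbors(vset: set, v: tuple) -> list:
    out = []
    for off in _OFFSETS:
        w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
        if w in vset:
            out.append(w)
    return out


def _trace(voxels: np.ndarray):
    """Decompose a skeleton voxel set into node clusters and chain edges.

    Returns ``(clusters, edges)`` where ``clusters`` maps cluster id to a
    list of voxels (degree ≠ 2, 26-connected among themselves) and each
    edge is ``(cid_a, cid_b, path)`` with ``path`` an ordered voxel list
    from a voxel of cluster a to a voxel of cluster b.  Pure cycles get an
    anchor cluster at their lexicographically smallest voxel.
    """
    vset = set(map(tuple, voxels))
    nbrs = {v: _neighbors(vset, v) for v in vset}
    node_voxels = {v for v, nb in nbrs.items() if len(nb) != 2}

    clusters, cid_of = {}, {}
    for v in sorted(node_voxels):
        if v in cid_of:
            continue
        cid = len(clusters)
        stack, members = [v], []
        cid_of[v] = cid
        while stack:
            u = stack.pop()
            members.append(u)
            for w in nbrs[u]:
                if w in node_voxels and w not in cid_of:
                    cid_of[w] = cid
                    stack.append(w)
        clusters[cid] = members

    edges = []
    visited_chain: set = set()
    direct = set()
    for v in sorted(node_voxels):
        for m in nbrs[v]:
            if m in node_voxels:
                if cid_of[m] != cid_of[v]:
                    key = tuple(sorted((v, m)))
                    if key not in direct:
                        direct.add(key)
                        edges.append((cid_of[v], cid_of[m], [v, m]))
                continue
            if m in visited_chain:
                continue
            path, prev, cur = [v, m], v, m
            visited_chain.add(m)
            while True:
                nxt = [w for w in nbrs[cur] if w != prev]
                if not nxt:  # dangling chain end (shouldn't happen: deg==2)
                    edges.append((cid_of[v], None, path))
                    break
                nxt = nxt[0]
                if nxt in node_voxels:
                    path.append(nxt)
                    edges.append((cid_of[v], cid_of[nxt], path))
                    break
                if nxt in visited_chain:  # closed back onto the start
                    path.append(nxt)
                    edges.append((cid_of[v], cid_of.get(nxt), path))
                    break
                visited_chain.add(nxt)
                path.append(nxt)
                prev, cur = cur, nxt

    # pure cycles: every voxel degree 2, none visited yet
    remaining = sorted(vset - node_voxels - visited_chain)
    rem = set(remaining)
    while rem:
        anchor = min(rem)
        cid = len(clusters)
        clusters[cid] = [anchor]
        cid_of[anchor] = cid
        path, prev, cur = [anchor], anchor, nbrs[anchor][0]
        while cur != anchor:
            path.append(cur)
            rem.discard(cur)
            nxt = [w for w in nbrs[cur] if w != prev][0]
            prev, cur = cur, nxt
        path.append(anchor)
        rem.discard(anchor)
        edges.append((cid, cid, path))
    return clusters, edges


def _arc_length(path_vox: np.ndarray, voxel_size) -> float:
    p = np.asarray(path_vox, dtype=float) * np.array(voxel_size)
    if p.shape[0] < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


def _collapse_redundant(voxels: np.ndarray) -> np.ndarray:
    """Drop voxels whose neighbors stay mutually connected without them.

    Hair removal can leave a redundant stub voxel glued to a straight chain
    (its three neighbors are consecutive chain voxels); such voxels carry no
    topology and would masquerade as junctions.  A voxel with ≥2 neighbors
    is removable iff the subgraph induced by its neighbors is connected.
    """
    vset = set(map(tuple, voxels))
    changed = True
    while changed:
        changed = False
        for v in sorted(vset):
            nbrs = _neighbors(vset, v)
            if len(nbrs) < 3:
                continue
            nbr_set = set(nbrs)
            seen = {nbrs[0]}
            stack = [nbrs[0]]
            while stack:
                u = stack.pop()
                for w in _neighbors(nbr_set, u):
                    if w not in seen:
                        seen.add(w)
                        stack.append(w)
            if len(seen) == len(nbrs):
                vset.discard(v)
                changed = True
    return np.array(sorted(vset), dtype=np.int64).reshape(-1, 3)


def prune_hairs(skeleton: Skeleton, min_hair_length_um: float = 20.0) -> Skeleton:
    """Iteratively remove short terminal branches ("hairs").

    Terminal segments shorter than ``min_hair_length_um`` are removed
    shortest-first, with junction re-evaluation after every removal: when a
    junction bearing two terminal branches loses the shorter one, its
    degree drops to 2 and the longer branch merges with the continuing
    vessel on the next pass (possibly exceeding the hair threshold and
    surviving).  Self-loops shorter than the threshold are removed the same
    way.  Idempotent; minimizes removed centerline length under this greedy
    order.
    """
    voxels = skeleton.voxels.copy()
    while True:
        if voxels.shape[0] == 0:
            break
        clusters, edges = _trace(voxels)
        degree = {cid: 0 for cid in clusters}
        for a, b, _ in edges:
            if a is not None:
                degree[a] += 1
            if b is not None:
                degree[b] += 1
        candidates = []
        for a, b, path in edges:
            if a is None or b is None:
                continue
            length = _arc_length(path, skeleton.voxel_size)
            if length >= min_hair_length_um:
                continue
            if a == b:  # short loop
                candidates.append((length, min(path), path, "loop", a))
            elif degree[a] == 1 and degree[b] > 1:
                candidates.append((length, path[0], path, "hair_a", a))
            elif degree[b] == 1 and degree[a] > 1:
                candidates.append((length, path[-1], path, "hair_b", b))
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1]))
        length, _, path, kind, term_cid = candidates[0]
        if kind == "loop":
            doomed = set(path[1:-1])  # keep the anchor/junction cluster
            if degree[term_cid] <= 2 and len(clusters[term_cid]) == 1:
                doomed |= set(clusters[term_cid])  # isolated cycle: drop whole
        elif kind == "hair_a":
            doomed = set(path[:-1]) | set(clusters[term_cid])
        else:
            doomed = set(path[1:]) | set(clusters[term_cid])
        keep = np.array([tuple(v) not in doomed for v in voxels])
        voxels = _collapse_redundant(voxels[keep])
    return Skeleton(voxels, skeleton.shape, skeleton.voxel_size)


def build_graph(skeleton: Skeleton) -> VascularGraph:
    """Render a (pruned) skeleton as a vascular graph.

    Nodes sit at skeleton voxels of degree ≠ 2 (branch-point clusters are
    collapsed to one node at their centroid); edges are maximal degree-2
    chains with ordered vertex positions in μm.  Closed loops are
    represented as one self-edge anchored at their lexicographically
    smallest voxel.
    """
    vs = np.array(skeleton.voxel_size)
    clusters, edges = _trace(skeleton.voxels)
    g = nx.MultiGraph()
    for cid, members in clusters.items():
        pos = np.mean(np.array(members, dtype=float), axis=0) * vs
        g.add_node(cid, position=pos, voxels=members)
    for a, b, path in edges:
        if a is None or b is None:
            continue
        path_vox = np.array(path, dtype=np.int64)
        path_um = path_vox * vs
        length = _arc_length(path_vox, skeleton.voxel_size)
        g.add_edge(a, b, path=path_um, path_voxels=path_vox, length=length)
    _dissolve_through_nodes(g, vs)
    for n in list(g.nodes):
        g.nodes[n]["degree"] = g.degree(n)
    return VascularGraph(g, skeleton.voxel_size)


def _dissolve_through_nodes(g: nx.MultiGraph, vs: np.ndarray) -> None:
    """Merge the two edges of any degree-2 node cluster into one segment.

    Thick junction clusters can survive as pass-through nodes once pruning
    removes their side branches; a vascular graph keeps nodes only at
    branch points and endpoints.
    """
    changed = True
    while changed:
        changed = False
        for n in list(g.nodes):
            if g.degree(n) != 2:
                continue
            inc = list(g.edges(n, keys=True, data=True))
            if len(inc) != 2:  # self-loop: a cycle anchor, keep
                continue
            (u1, v1, k1, d1), (u2, v2, k2, d2) = inc
            o1 = v1 if u1 == n else u1
            o2 = v2 if u2 == n else u2
            if o1 == n or o2 == n:
                continue
            p1 = d1["path_voxels"] if u1 == n else d1["path_voxels"][::-1]
            p2 = d2["path_voxels"] if u2 == n else d2["path_voxels"]
            # p1 now runs n -> o1; reorient to o1 -> n, then n -> o2
            p1 = p1[::-1]
            joined = np.vstack([p1, p2[1:]]) if tuple(p1[-1]) == tuple(p2[0]) \
                else np.vstack([p1, p2])
            g.remove_edge(u1, v1, key=k1)
            g.remove_edge(u2, v2, key=k2)
            g.remove_node(n)
            g.add_edge(o1, o2, path=joined * vs, path_voxels=joined,
                       length=_arc_length(joined, vs))
            changed = True
            break


def _smooth_open_path(path: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-smooth vertex coordinates; exact on straight lines.

    The path is extended by linear extrapolation at both ends before
    filtering so colinear inputs (including the endpoints) are fixed points
    of the smoother.
    """
    n = path.shape[0]
    if n < 3 or sigma <= 0:
        return path.copy()
    pad = int(np.ceil(4 * sigma))
    start = path[0] + np.outer(np.arange(-pad, 0), path[1] - path[0])
    end = path[-1] + np.outer(np.arange(1, pad + 1), path[-1] - path[-2])
    ext = np.vstack([start, path, end])
    sm = gaussian_filter1d(ext, sigma=sigma, axis=0, mode="nearest")
    return sm[pad:pad + n]


def smooth_and_tangents(vgraph: VascularGraph, sigma_vertices: float = 3.0) -> VascularGraph:
    """Low-pass filter edge vertex paths and attach unit tangents.

    Coordinates are smoothed per edge with a Gaussian of ``sigma_vertices``
    (in vertex-index units).  The tangent at each vertex is the normalized
    central-difference gradient of the smoothed path (one-sided at
    endpoints).  Raw positions are retained in ``path``.
    """
    for u, v, k, data in vgraph.edges():
        path = data["path"]
        if path.shape[0] < 2:
            raise ValueError("edge with a single vertex cannot be smoothed")
        closed = u == v and np.allclose(path[0], path[-1])
        if closed and path.shape[0] > 4:
            pad = int(np.ceil(4 * sigma_vertices))
            body = path[:-1]
            ext = np.vstack([body[-pad:], body, body[:pad]])
            sm = gaussian_filter1d(ext, sigma=sigma_vertices, axis=0, mode="nearest")
            smooth = np.vstack([sm[pad:pad + body.shape[0]], sm[pad:pad + 1]])
        else:
            smooth = _smooth_open_path(path, sigma_vertices)
        grad = np.gradient(smooth, axis=0)
        norms = np.linalg.norm(grad, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        data["path_smooth"] = smooth
        data["tangent"] = grad / norms
    return vgraph


def extract_graph(mask: BinaryMask, min_hair_length_um: float = 20.0,
                  sigma_vertices: float = 3.0) -> VascularGraph:
    """Mask → skeleton → pruned skeleton → smoothed graph, in one call."""
    skel = prune_hairs(skeletonize(mask), min_hair_length_um)
    return smooth_and_tangents(build_graph(skel), sigma_vertices)
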