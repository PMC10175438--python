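"""Articular surface delineation and fracture-line extraction.

On each fragment mesh the articular patch is either supplied explicitly as
per-vertex annotations (the faithful analogue of manual delineation) or
estimated by a heuristic: upward-facing triangles (normal within a cone
around the proximal axis) whose centroids lie in the top axial band of the
fragment.  The patch boundary is chained into contour polylines, and the
parts of each contour that face a *different* fragment's contour are kept
as fracture lines; the remainder is the plateau rim and is discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .segmentation import FragmentMesh

__all__ = [
    "Polyline3D",
    "ArticularPatch",
    "FractureLineSet",
    "delineate_articular",
    "extract_contours",
    "prune_end_spurs",
    "trim_to_fracture_lines",
]


@dataclass
class Polyline3D:
    """Ordered 3D point sequence in mm; closed loops repeat the first point."""

    points: np.ndarray
    closed: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise ValueError("polyline needs at least 2 points")
        seg = np.diff(self.points, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise ValueError("consecutive points must be distinct")
        if self.closed and not np.allclose(self.points[0], self.points[-1]):
            raise ValueError("closed polyline must end at its first point")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def simplified(self, tol: float) -> "Polyline3D":
        """Douglas–Peucker simplification in 3D with tolerance ``tol`` mm.

        Removes sub-resolution jitter while keeping every retained point at
        its original position; endpoints are always kept.
        """
        pts = self.points[:-1] if self.closed else self.points
        keep = _douglas_peucker(pts, tol)
        if self.closed:
            # anchor a second point (the farthest from the start) so a
            # closed loop cannot collapse to a segment
            far = int(np.argmax(np.linalg.norm(pts - pts[0], axis=1)))
            keep = sorted(set(keep) | {far})
            out = np.vstack([pts[keep], pts[keep[0]]])
            return Polyline3D(out, closed=True)
        return Polyline3D(pts[keep], closed=False)

    def smoothed(self, window: int = 5) -> "Polyline3D":
        """Centred moving-average smoothing of the vertex positions.

        Suppresses voxel-staircase jitter without the endpoint-anchoring
        bias of pure simplification: each vertex moves to the mean of its
        ``window`` neighbours (shrinking symmetric window near open ends,
        circular for closed lines).
        """
        if window < 3:
            return self
        half = window // 2
        pts = self.points[:-1] if self.closed else self.points
        n = len(pts)
        if n <= 2:
            return self
        out = np.empty_like(pts)
        for i in range(n):
            if self.closed:
                idx = (np.arange(i - half, i + half + 1)) % n
            else:
                k = min(half, i, n - 1 - i)
                idx = np.arange(i - k, i + k + 1)
            out[i] = pts[idx].mean(axis=0)
        if self.closed:
            out = np.vstack([out, out[:1]])
        return Polyline3D(out, closed=self.closed)

    def resample(self, step: float) -> np.ndarray:
        """Points sampled densely (spacing <= step) along the polyline."""
        out = [self.points[0]]
        for a, b in zip(self.points[:-1], self.points[1:]):
            d = float(np.linalg.norm(b - a))
            n = max(1, int(np.ceil(d / step)))
            t = np.arange(1, n + 1)[:, None] / n
            out.append(a + t * (b - a))
        return np.vstack(out)


def prune_end_spurs(line: "Polyline3D", max_turn_deg: float = 45.0) -> "Polyline3D":
    """Drop sharply-angled end segments from an open fracture line.

    Where a fracture line meets the plateau rim the trimming may keep one
    or two rim vertices past the true corner; on a simplified line these
    show up as end segments turning by more than ``max_turn_deg`` from the
    adjacent segment.  They are removed iteratively from both ends; the
    line is never shortened below two points.
    """
    if line.closed:
        return line
    pts = line.points
    cos_lim = np.cos(np.deg2rad(max_turn_deg))

    def turn_ok(a, b, c) -> bool:
        u = b - a
        v = c - b
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu == 0 or nv == 0:
            return False
        return float(u @ v) / (nu * nv) >= cos_lim

    changed = True
    while changed and len(pts) >= 3:
        changed = False
        if not turn_ok(pts[0], pts[1], pts[2]):
            pts = pts[1:]
            changed = True
        if len(pts) >= 3 and not turn_ok(pts[-3], pts[-2], pts[-1]):
            pts = pts[:-1]
            changed = True
    return Polyline3D(pts, closed=False)


def _douglas_peucker(pts: np.ndarray, tol: float) -> list[int]:
    """Indices of points kept by recursive farthest-point simplification."""
    n = len(pts)
    if n <= 2:
        return list(range(n))
    keep = np.zeros(n, dtype=bool)
    keep[[0, n - 1]] = True
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        seg = pts[j] - pts[i]
        seg_len2 = float(np.dot(seg, seg))
        rel = pts[i + 1 : j] - pts[i]
        if seg_len2 == 0.0:
            d = np.linalg.norm(rel, axis=1)
        else:
            t = np.clip(rel @ seg / seg_len2, 0.0, 1.0)
            d = np.linalg.norm(rel - t[:, None] * seg, axis=1)
        k = int(np.argmax(d))
        if d[k] > tol:
            mid = i + 1 + k
            keep[mid] = True
            stack.append((i, mid))
            stack.append((mid, j))
    return list(np.flatnonzero(keep))


@dataclass
class ArticularPatch:
    """Subset of a fragment mesh flagged as articular surface."""

    fragment_id: int
    mesh: FragmentMesh
    face_indices: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.face_indices = np.asarray(self.face_indices, dtype=np.int64)
        if self.face_indices.size == 0:
            raise ValueError("no articular surface found")

    @property
    def area(self) -> float:
        tri = self.mesh.vertices[self.mesh.faces[self.face_indices]]
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())


@dataclass
class FractureLineSet:
    """Open fracture polylines at articular level, tagged by fragment."""

    lines: list[Polyline3D] = field(default_factory=list)
    fragment_ids: list[int] = field(default_factory=list)
    d_max: float = 7.5

    def __len__(self) -> int:
        return len(self.lines)


def _largest_face_component(faces: np.ndarray, selected: np.ndarray) -> np.ndarray:
    """Indices (into ``selected``) of the largest edge-connected face group."""
    sel_faces = faces[selected]
    # faces sharing an edge: map sorted edge -> face list
    edges = np.sort(
        np.stack(
            [sel_faces[:, [0, 1]], sel_faces[:, [1, 2]], sel_faces[:, [2, 0]]], axis=1
        ).reshape(-1, 2),
        axis=1,
    )
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    edges_sorted = edges[order]
    face_of_edge = order // 3  # edge row r belongs to face r // 3
    same = np.all(edges_sorted[:-1] == edges_sorted[1:], axis=1)
    a = face_of_edge[:-1][same]
    b = face_of_edge[1:][same]
    n = len(sel_faces)
    graph = coo_matrix((np.ones(len(a)), (a, b)), shape=(n, n))
    _, comp = connected_components(graph, directed=False)
    counts = np.bincount(comp)
    return np.flatnonzero(comp == np.argmax(counts))


def delineate_articular(
    mesh: FragmentMesh,
    annotation: np.ndarray | None = None,
    proximal_axis: np.ndarray = (0.0, 0.0, 1.0),
    max_normal_angle_deg: float = 45.0,
    axial_band_frac: float = 0.15,
) -> ArticularPatch:
    """Mark the articular patch on a fragment mesh.

    With ``annotation`` (boolean per vertex) the patch is exactly the
    triangles whose three vertices are flagged.  Without it, the heuristic
    keeps triangles whose outward normal lies within ``max_normal_angle_deg``
    of the proximal axis and whose centroid falls in the top
    ``axial_band_frac`` of the fragment's proximal extent, then returns the
    largest edge-connected component.
    """
    faces = mesh.faces
    if annotation is not None:
        annotation = np.asarray(annotation, dtype=bool)
        if annotation.shape != (len(mesh.vertices),):
            raise ValueError("annotation length must equal vertex count")
        keep = np.flatnonzero(annotation[faces].all(axis=1))
        if keep.size == 0:
            raise ValueError("no articular surface found")
        return ArticularPatch(mesh.fragment_id, mesh, keep)

    axis = np.asarray(proximal_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    cos_lim = np.cos(np.deg2rad(max_normal_angle_deg))
    facing = mesh.face_normals @ axis >= cos_lim - 1e-12

    proj = mesh.vertices @ axis
    top, bottom = proj.max(), proj.min()
    centroid_proj = proj[faces].mean(axis=1)
    in_band = centroid_proj >= top - axial_band_frac * (top - bottom)

    selected = np.flatnonzero(facing & in_band)
    if selected.size == 0:
        raise ValueError("no articular surface found")
    largest = _largest_face_component(faces, selected)
    return ArticularPatch(mesh.fragment_id, mesh, selected[largest])


def _chain_boundary(
    vertices: np.ndarray, boundary_edges: np.ndarray
) -> list[Polyline3D]:
    """Chain boundary edges into maximal open/closed polylines.

    Deterministic: open chains start at the lexicographically smallest
    endpoint coordinate; remaining loops start at the lexicographically
    smallest vertex; ties resolved toward the smaller vertex index.
    """
    from collections import defaultdict

    adj: dict[int, list[int]] = defaultdict(list)
    edge_used: dict[tuple[int, int], int] = defaultdict(int)
    for i, j in boundary_edges:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
        edge_used[(min(i, j), max(i, j))] += 0
    for v in adj:
        adj[v].sort()

    def lex_key(v: int):
        return tuple(vertices[v]) + (v,)

    remaining = {tuple(sorted((int(i), int(j)))) for i, j in boundary_edges}

    def walk(start: int) -> list[int]:
        path = [start]
        current = start
        while True:
            nxt = None
            for cand in adj[current]:
                e = tuple(sorted((current, cand)))
                if e in remaining:
                    nxt = cand
                    break
            if nxt is None:
                return path
            remaining.discard(tuple(sorted((current, nxt))))
            path.append(nxt)
            current = nxt

    polylines: list[Polyline3D] = []
    degree = {v: len(nb) for v, nb in adj.items()}
    # open chains: endpoints have odd degree
    endpoints = sorted((v for v, d in degree.items() if d % 2 == 1), key=lex_key)
    for v in endpoints:
        if any(tuple(sorted((v, nb))) in remaining for nb in adj[v]):
            path = walk(v)
            if len(path) >= 2:
                polylines.append(Polyline3D(vertices[path], closed=False))
    # closed loops with whatever is left
    while remaining:
        start = min({v for e in remaining for v in e}, key=lex_key)
        path = walk(start)
        if len(path) >= 3 and path[0] == path[-1]:
            polylines.append(Polyline3D(vertices[path], closed=True))
        elif len(path) >= 2:
            polylines.append(Polyline3D(vertices[path], closed=False))
    return polylines


def extract_contours(patch: ArticularPatch) -> list[Polyline3D]:
    """Boundary polylines of an articular patch.

    Boundary edges are those belonging to exactly one member triangle.  A
    closed patch covering the whole mesh has no boundary and yields an
    empty list.  An edge shared by more than two member triangles is a
    non-manifold boundary and raises.
    """
    faces = patch.mesh.faces[patch.face_indices]
    edges = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    bad = uniq[counts > 2]
    if len(bad):
        i, j = bad[0]
        raise ValueError(f"non-manifold boundary edge ({i}, {j})")
    boundary = uniq[counts == 1]
    if len(boundary) == 0:
        return []
    return _chain_boundary(patch.mesh.vertices, boundary)


def trim_to_fracture_lines(
    contours: dict[int, list[Polyline3D]],
    d_max: float = 7.5,
    reciprocal_tol: float = 0.4,
    sample_step: float = 0.25,
    end_prune_tol: float = 0.15,
) -> FractureLineSet:
    """Keep only the contour runs that face another fragment.

    A contour vertex p of fragment f is classified *fracture* when

    * its distance d1 to the nearest point q on a different fragment's
      contour is at most ``d_max``, and
    * q is reciprocally about as close to the opposing contours as p is
      (``dist(q, contours of fragments != owner(q)) >= d1 - reciprocal_tol``).

    The reciprocity condition stops the fracture run from leaking around
    the plateau rim near the fracture-line corners, where rim points are
    close to the opposing *corner* but not to any truly opposing run.
    Maximal runs of fracture vertices become open polylines; everything
    else is rim and is dropped.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    result = FractureLineSet(d_max=d_max)
    frag_ids = [f for f, cs in contours.items() if cs]
    if len(frag_ids) < 2:
        return result

    samples = {
        f: np.vstack([c.resample(sample_step) for c in contours[f]]) for f in frag_ids
    }
    trees = {f: cKDTree(pts) for f, pts in samples.items()}

    # distance from each sample of fragment o back to all fragments != o
    def back_distance(points: np.ndarray, exclude: int) -> np.ndarray:
        dists = [
            trees[f].query(points)[0] for f in frag_ids if f != exclude
        ]
        return np.min(dists, axis=0)

    back = {f: back_distance(samples[f], f) for f in frag_ids}

    for f in frag_ids:
        others = [o for o in frag_ids if o != f]
        # per-vertex nearest opposing sample across all other fragments
        for contour in contours[f]:
            pts = contour.points[:-1] if contour.closed else contour.points
            d1 = np.full(len(pts), np.inf)
            recip = np.zeros(len(pts))
            for o in others:
                d, idx = trees[o].query(pts)
                better = d < d1
                d1[better] = d[better]
                recip[better] = back[o][idx[better]]
            mark = (d1 <= d_max) & (recip >= d1 - reciprocal_tol)
            for run in _marked_runs(mark, circular=contour.closed):
                if len(run) > 2 and not (contour.closed and len(run) == len(pts)):
                    run = _prune_run_ends(run, d1, pts, end_prune_tol)
                if len(run) >= 2:
                    if len(run) == len(pts) and contour.closed:
                        line = contour  # whole contour is fracture: keep closed
                    else:
                        line = Polyline3D(pts[run], closed=False)
                    result.lines.append(line)
                    result.fragment_ids.append(f)
    return result


def _prune_run_ends(
    run: np.ndarray,
    d1: np.ndarray,
    pts: np.ndarray,
    tol: float,
    max_arc: float = 5.0,
) -> np.ndarray:
    """Trim fracture-run ends whose opposing distance exceeds the run floor.

    Near the plateau rim the proximity test admits a short hook of rim
    vertices whose distance to the opposing contour rises above the
    fracture-line level; they are peeled off while ``d1`` at the end
    exceeds ``min(d1 over run) + tol``.  At most ``max_arc`` mm of arc is
    removed per end, so a genuinely widening fracture line cannot be eaten
    beyond the rim-ambiguity scale.
    """
    floor = float(d1[run].min())
    for _ in range(2):  # front pass then back pass (on reversed view)
        removed = 0.0
        while len(run) > 2 and d1[run[0]] > floor + tol:
            removed += float(np.linalg.norm(pts[run[0]] - pts[run[1]]))
            if removed > max_arc:
                break
            run = run[1:]
        run = run[::-1]
    return run


def _marked_runs(mark: np.ndarray, circular: bool) -> list[np.ndarray]:
    """Maximal index runs where ``mark`` is true (wrapping if circular)."""
    n = len(mark)
    if not mark.any():
        return []
    if mark.all():
        return [np.arange(n)]
    idx = np.flatnonzero(mark)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    if circular and len(runs) > 1 and idx[0] == 0 and idx[-1] == n - 1:
        runs[0] = np.concatenate([runs[-1], runs[0]])
        runs.pop()
    return runs
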