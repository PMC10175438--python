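"""Gap-loop closure, spanning-surface construction, and the 3D gap area.

The 3D gap area is the total area (mm²) of the surface spanning all
fracture lines at the articular level: open fracture lines are joined end
to end into closed loops, each loop is triangulated across the interior of
its best-fit-plane projection (keeping the original 3D vertex positions,
so out-of-plane step-offs inflate the area exactly as a ruled surface
would), and per-loop areas are summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import Polygon as ShapelyPolygon

from .articular import (
    FractureLineSet,
    Polyline3D,
    delineate_articular,
    extract_contours,
    prune_end_spurs,
    trim_to_fracture_lines,
)
from .segmentation import FragmentMesh

__all__ = [
    "GapLoop",
    "GapSurface",
    "GapAreaResult",
    "close_loops",
    "build_surface",
    "measure_gap_area",
]


class GapSurfaceError(ValueError):
    """Raised when a loop cannot be turned into a spanning surface."""


@dataclass
class GapLoop:
    """Closed polyline spanning fracture lines plus closure segments.

    ``provenance`` tags every segment (there are ``len(points) - 1``) as
    either ``"fracture"`` or ``"closure"``.
    """

    points: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 4 or not np.allclose(self.points[0], self.points[-1]):
            raise ValueError("loop must be closed with >= 3 distinct points")
        if self.provenance and len(self.provenance) != len(self.points) - 1:
            raise ValueError("provenance must tag every segment")


@dataclass
class GapSurface:
    """Triangulated spanning surface; total area is the 3D gap area."""

    triangles: np.ndarray  # (k, 3, 3) in mm
    loop_areas: list[float]

    @property
    def total_area(self) -> float:
        return float(sum(self.loop_areas))


@dataclass
class GapAreaResult:
    """3D gap area measurement with parameters for provenance."""

    total_area_mm2: float
    loop_areas_mm2: list[float]
    loops: list[GapLoop]
    surface: GapSurface
    params: dict

    @property
    def loop_count(self) -> int:
        return len(self.loop_areas_mm2)

    def to_dict(self) -> dict:
        return {
            "total_area_mm2": self.total_area_mm2,
            "loops": [
                {"area_mm2": a, "n_points": int(len(lp.points))}
                for a, lp in zip(self.loop_areas_mm2, self.loops)
            ],
            "params": self.params,
        }


def close_loops(lines: FractureLineSet | Sequence[Polyline3D]) -> list[GapLoop]:
    """Join open fracture lines into closed loops.

    Free endpoints are paired greedily, closest pair first (ties broken by
    lexicographic order of the joined coordinates); the two ends of the
    same chain may only pair once no cross-chain pairing is available.
    Already-closed input polylines pass through unchanged as loops.
    """
    if isinstance(lines, FractureLineSet):
        polylines = lines.lines
    else:
        polylines = list(lines)

    loops: list[GapLoop] = []
    # chain = (points, segment tags, line id of start point, line id of end)
    chains: list[tuple[np.ndarray, list[str], int, int]] = []
    for k, pl in enumerate(polylines):
        if len(pl.points) < 2:
            raise ValueError("unmatched endpoint: degenerate input line")
        tags = ["fracture"] * (len(pl.points) - 1)
        if pl.closed:
            loops.append(GapLoop(pl.points.copy(), tags))
        else:
            chains.append((pl.points.copy(), tags, k, k))

    def end_point(chain, end: int) -> np.ndarray:
        return chain[0][0] if end == 0 else chain[0][-1]

    def end_line(chain, end: int) -> int:
        return chain[2] if end == 0 else chain[3]

    while chains:
        best = None
        for i in range(len(chains)):
            for ei in (0, 1):
                p = end_point(chains[i], ei)
                for j in range(i, len(chains)):
                    for ej in (0, 1):
                        if j == i and ej <= ei:
                            continue
                        # pairing the two ends of one original polyline is
                        # only legal when it is the only line left
                        same_line = end_line(chains[i], ei) == end_line(
                            chains[j], ej
                        )
                        if j == i and same_line and len(chains) > 1:
                            continue
                        q = end_point(chains[j], ej)
                        d = float(np.linalg.norm(p - q))
                        key = (d, tuple(np.minimum(p, q)), tuple(np.maximum(p, q)))
                        if best is None or key < best[0]:
                            best = (key, i, ei, j, ej)
        if best is None:
            raise ValueError(
                "unmatched endpoint at "
                + ", ".join(str(tuple(end_point(c, e))) for c in chains for e in (0, 1))
            )
        _, i, ei, j, ej = best
        if i == j:
            # close this chain on itself with one straight closure segment
            pts, tags, _, _ = chains.pop(i)
            loops.append(GapLoop(np.vstack([pts, pts[0]]), tags + ["closure"]))
            continue
        pi, ti, si, li = chains[i]
        pj, tj, sj, lj = chains[j]
        # orient so chain i ends at the junction and chain j starts there
        if ei == 0:
            pi, ti, si, li = pi[::-1], ti[::-1], li, si
        if ej == 1:
            pj, tj, sj, lj = pj[::-1], tj[::-1], lj, sj
        merged = (np.vstack([pi, pj]), ti + ["closure"] + tj, si, lj)
        chains = [c for k2, c in enumerate(chains) if k2 not in (i, j)]
        chains.append(merged)
    return loops


def _ear_clip(poly: np.ndarray) -> list[tuple[int, int, int]]:
    """Triangulate a simple CCW 2D polygon by ear clipping.

    Returns index triples into ``poly``.  Collinear (zero-area) ears are
    clipped freely.  Raises GapSurfaceError if no ear can be found, which
    only happens for non-simple input.
    """
    n = len(poly)
    if n < 3:
        return []
    idx = list(range(n))
    tris: list[tuple[int, int, int]] = []
    eps = 1e-12 * max(1.0, float(np.abs(poly).max()) ** 2)

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def point_in_tri(p, a, b, c):
        d1 = cross(a, b, p)
        d2 = cross(b, c, p)
        d3 = cross(c, a, p)
        return d1 >= -eps and d2 >= -eps and d3 >= -eps

    guard = 0
    while len(idx) > 3:
        guard += 1
        if guard > 4 * n * n:
            raise GapSurfaceError("non-simple loop")
        m = len(idx)
        clipped = False
        for k in range(m):
            i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            a, b, c = poly[i0], poly[i1], poly[i2]
            area2 = cross(a, b, c)
            if area2 < -eps:
                continue  # reflex vertex
            if area2 <= eps:
                # collinear ear: drop the middle vertex without a triangle
                tris.append((i0, i1, i2))
                idx.pop(k)
                clipped = True
                break
            ok = True
            for other in idx:
                if other in (i0, i1, i2):
                    continue
                if point_in_tri(poly[other], a, b, c):
                    ok = False
                    break
            if ok:
                tris.append((i0, i1, i2))
                idx.pop(k)
                clipped = True
                break
        if not clipped:
            raise GapSurfaceError("non-simple loop")
    tris.append((idx[0], idx[1], idx[2]))
    return tris


def _crossing_pairs(xy: np.ndarray) -> np.ndarray:
    """Index pairs (i, j) of non-adjacent polygon segments that intersect."""
    n = len(xy)
    p1 = xy
    p2 = np.roll(xy, -1, axis=0)
    i, j = np.triu_indices(n, k=2)
    wrap = (i == 0) & (j == n - 1)
    i, j = i[~wrap], j[~wrap]

    def orient(a, b, c):
        return (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (
            b[:, 1] - a[:, 1]
        ) * (c[:, 0] - a[:, 0])

    a, b = p1[i], p2[i]
    c, d = p1[j], p2[j]
    d1 = orient(a, b, c)
    d2 = orient(a, b, d)
    d3 = orient(c, d, a)
    d4 = orient(c, d, b)
    crossing = (d1 * d2 < 0) & (d3 * d4 < 0)
    return np.column_stack([i[crossing], j[crossing]])


def _untangle(pts: np.ndarray, project, sliver_tol: float = 0.75) -> np.ndarray:
    """Remove sub-resolution sliver vertices that self-cross in projection.

    Fracture-line endpoints next to the plateau rim can carry one or two
    mesh-resolution vertices that fold the projected ring over itself by a
    fraction of a voxel; deleting the vertex nearest the crossing restores
    a simple polygon with negligible area change.  A vertex is only
    deleted when it lies within ``sliver_tol`` mm of the segment it
    crosses, and at most 5% of the vertices (minimum 8) may be removed;
    a macroscopic self-intersection is left for the caller to reject.
    """
    budget = max(8, len(pts) // 20)
    for _ in range(budget):
        xy = project(pts)
        pairs = _crossing_pairs(xy)
        if len(pairs) == 0:
            return pts
        i, j = pairs[0]
        n = len(xy)
        cand = np.array([i, (i + 1) % n, j, (j + 1) % n])
        # delete the endpoint closest to the opposing segment
        def seg_dist(p, a, b):
            ab = b - a
            t = np.clip(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-300), 0, 1)
            return np.linalg.norm(p - (a + t * ab))

        dists = [
            seg_dist(xy[cand[0]], xy[j], xy[(j + 1) % n]),
            seg_dist(xy[cand[1]], xy[j], xy[(j + 1) % n]),
            seg_dist(xy[cand[2]], xy[i], xy[(i + 1) % n]),
            seg_dist(xy[cand[3]], xy[i], xy[(i + 1) % n]),
        ]
        if min(dists) > sliver_tol:
            return pts  # not a sliver: genuine self-intersection
        drop = int(cand[int(np.argmin(dists))])
        pts = np.delete(pts, drop, axis=0)
        if len(pts) < 3:
            return pts
    return pts


def _triangle_areas(tri: np.ndarray) -> np.ndarray:
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def build_surface(
    loop: GapLoop, degeneracy_tol: float = 0.25
) -> tuple[np.ndarray, float]:
    """Triangulate one gap loop and return (triangles (k,3,3), area mm²).

    The loop's points are projected onto their principal (best-fit) plane;
    the projected simple polygon is ear-clipped; triangles are lifted back
    to the original 3D coordinates so non-planarity inflates the area.
    Loops whose points are collinear within ``degeneracy_tol`` mm (RMS)
    contribute zero area.  A self-intersecting projection raises
    GapSurfaceError("non-simple loop").
    """
    pts = loop.points[:-1]
    # drop consecutive (near-)duplicates
    keep = [0]
    for i in range(1, len(pts)):
        if np.linalg.norm(pts[i] - pts[keep[-1]]) > 1e-9:
            keep.append(i)
    if len(keep) > 1 and np.linalg.norm(pts[keep[-1]] - pts[keep[0]]) <= 1e-9:
        keep.pop()
    pts = pts[keep]
    if len(pts) < 3:
        return np.zeros((0, 3, 3)), 0.0

    def project(p: np.ndarray) -> np.ndarray:
        """Best-fit-plane coordinates; axes derived from the geometry
        itself (centroid + farthest point) so the projection is
        rotation-equivariant."""
        centred = p - p.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        normal = vt[2]
        far = int(np.argmax(np.linalg.norm(centred, axis=1)))
        e1 = centred[far] - np.dot(centred[far], normal) * normal
        e1 = e1 / np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        return np.column_stack([centred @ e1, centred @ e2])

    _, svals, _ = np.linalg.svd(pts - pts.mean(axis=0), full_matrices=False)
    # collinear within tolerance: zero-width loop, zero area
    if svals[1] / np.sqrt(len(pts)) <= degeneracy_tol:
        return np.zeros((0, 3, 3)), 0.0

    pts = _untangle(pts, project)
    if len(pts) < 3:
        return np.zeros((0, 3, 3)), 0.0
    xy = project(pts)

    # orient CCW for ear clipping
    signed2 = float(
        np.sum(xy[:, 0] * np.roll(xy[:, 1], -1) - np.roll(xy[:, 0], -1) * xy[:, 1])
    )
    order = np.arange(len(pts)) if signed2 >= 0 else np.arange(len(pts))[::-1]
    xy_ccw = xy[order]

    if not ShapelyPolygon(xy_ccw).is_valid:
        raise GapSurfaceError("non-simple loop")

    tri_idx = _ear_clip(xy_ccw)
    tri_idx = [(order[a], order[b], order[c]) for a, b, c in tri_idx]
    triangles = pts[np.asarray(tri_idx, dtype=int)]
    area = float(_triangle_areas(triangles).sum())
    return triangles, area


def measure_gap_area(
    meshes: Sequence[FragmentMesh],
    annotations: Mapping[int, np.ndarray] | None = None,
    *,
    proximal_axis=(0.0, 0.0, 1.0),
    max_normal_angle_deg: float = 45.0,
    axial_band_frac: float = 0.15,
    d_max: float = 7.5,
    reciprocal_tol: float = 0.4,
    end_prune_tol: float = 0.15,
    degeneracy_tol: float = 0.25,
    simplify_tol: float = 0.25,
    spur_angle_deg: float = 45.0,
    line_smooth_window: int = 5,
) -> GapAreaResult:
    """Measure the total 3D gap area of a set of fragment meshes.

    Pipeline: delineate articular patches (per-vertex ``annotations`` keyed
    by fragment id when given, heuristic otherwise) → extract patch
    contours → trim to fracture lines → close loops → build spanning
    surfaces → sum areas.  A single unfractured fragment yields 0 mm².
    """
    params = {
        "d_max": d_max,
        "reciprocal_tol": reciprocal_tol,
        "end_prune_tol": end_prune_tol,
        "degeneracy_tol": degeneracy_tol,
        "simplify_tol": simplify_tol,
        "spur_angle_deg": spur_angle_deg,
        "line_smooth_window": line_smooth_window,
        "max_normal_angle_deg": max_normal_angle_deg,
        "axial_band_frac": axial_band_frac,
        "closure_rule": "greedy-nearest-endpoint",
    }
    empty = GapAreaResult(
        0.0, [], [], GapSurface(np.zeros((0, 3, 3)), []), params
    )
    if len(meshes) < 2:
        return empty

    contours: dict[int, list[Polyline3D]] = {}
    for mesh in meshes:
        ann = annotations.get(mesh.fragment_id) if annotations else None
        patch = delineate_articular(
            mesh,
            annotation=ann,
            proximal_axis=proximal_axis,
            max_normal_angle_deg=max_normal_angle_deg,
            axial_band_frac=axial_band_frac,
        )
        contours[mesh.fragment_id] = extract_contours(patch)

    lineset = trim_to_fracture_lines(
        contours,
        d_max=d_max,
        reciprocal_tol=reciprocal_tol,
        end_prune_tol=end_prune_tol,
    )
    if len(lineset) == 0:
        return empty
    if simplify_tol > 0:
        cleaned = []
        for ln in lineset.lines:
            if len(ln.points) > 2:
                ln = prune_end_spurs(
                    ln.smoothed(line_smooth_window).simplified(simplify_tol),
                    spur_angle_deg,
                )
            cleaned.append(ln)
        lineset = FractureLineSet(
            lines=cleaned,
            fragment_ids=lineset.fragment_ids,
            d_max=lineset.d_max,
        )

    loops = close_loops(lineset)
    all_triangles = []
    areas = []
    for loop in loops:
        tris, area = build_surface(loop, degeneracy_tol=degeneracy_tol)
        all_triangles.append(tris)
        areas.append(area)
    triangles = (
        np.concatenate(all_triangles) if all_triangles else np.zeros((0, 3, 3))
    )
    surface = GapSurface(triangles, areas)
    return GapAreaResult(surface.total_area, areas, loops, surface, params)
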