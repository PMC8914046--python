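"""3D right-ventricular strain from a tracked endocardial mesh cycle.

The engine mirrors the mesh-based strain definitions used in 3D RV
quantification software: on the end-diastolic (ED) surface it constructs

* 15 *latitudes* — closed circumferential contours obtained by slicing the
  mesh with planes orthogonal to the long axis at equal distances between
  apex and base,
* 45 *longitudes* — apex-to-base contours running through a mid-cavity
  waypoint, realised as shortest paths on the mesh edge graph,

and tracks them *materially* through the cycle: every contour point is stored
as barycentric coordinates on a fixed face, so its position on any other
frame is obtained from the (topology-constant) deformed vertices. Global
strains are fractional length/area reductions from ED to end-systole (ES),
reported as positive percentages for shortening:

    GCS = mean_k (C_k^ED - C_k^ES) / C_k^ED x 100      (15 latitudes)
    GLS = mean_j (L_j^ED - L_j^ES) / L_j^ED x 100      (45 longitudes)
    GAS = (A^ED - A^ES) / A^ED x 100                   (total surface area)
    EF  = (EDV - ESV) / EDV x 100

ED and ES are the global maximum and minimum of the volume curve.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import AxisError, StrainError
from .mesh import FrameSeries, Mesh, surface_area, volume_curve

__all__ = [
    "LongAxis",
    "SurfacePoint",
    "Contour",
    "ContourSet",
    "StrainResult",
    "compute_long_axis",
    "extract_latitudes",
    "extract_longitudes",
    "build_contour_set",
    "propagate_contours",
    "compute_strains",
]


# --------------------------------------------------------------------------
# long axis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LongAxis:
    """RV long axis: apex point, base (annulus) centre, unit base->apex vector."""

    apex_point: np.ndarray
    base_center: np.ndarray
    direction: np.ndarray  # unit, base -> apex
    apex_index: int | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        n = np.linalg.norm(d)
        if n == 0:
            raise AxisError("axis direction has zero length")
        object.__setattr__(self, "direction", d / n)
        object.__setattr__(self, "apex_point", np.asarray(self.apex_point, float))
        object.__setattr__(self, "base_center", np.asarray(self.base_center, float))
        if np.allclose(self.apex_point, self.base_center):
            raise AxisError("apex coincides with base centre")

    @property
    def length(self) -> float:
        """Axial apex-to-base-centre distance (mm)."""
        return float(np.dot(self.base_center - self.apex_point, -self.direction).__abs__())

    def axial_fraction(self, points: np.ndarray) -> np.ndarray:
        """Coordinate along the axis: 0 at apex, 1 at base centre."""
        ab = self.base_center - self.apex_point
        return (np.asarray(points) - self.apex_point) @ ab / float(ab @ ab)


def compute_long_axis(mesh: Mesh, base_ring_hint: np.ndarray | None = None) -> LongAxis:
    """Locate the RV long axis of an (ED) mesh.

    With a ``base_ring_hint`` (points on the tricuspid annulus), the base
    centre is their centroid and the apex is the vertex farthest from it.
    Without a hint the first principal axis of the vertex cloud is used; the
    flatter of the two axial end caps (smaller axial spread of its extreme
    vertices) is taken as the base, since exported RV surfaces are capped by
    the near-planar annulus. Nearly-isotropic vertex clouds are rejected.
    """
    v = mesh.vertices
    if base_ring_hint is not None:
        base_center = np.asarray(base_ring_hint, float).reshape(-1, 3).mean(axis=0)
        d0 = v.mean(axis=0) - base_center
        nrm = np.linalg.norm(d0)
        if nrm < 1e-12:
            raise AxisError("base ring hint centroid coincides with mesh centroid")
        d0 /= nrm
        apex_idx = int(np.argmax((v - base_center) @ d0))
        apex = v[apex_idx]
        return LongAxis(apex, base_center, apex - base_center, apex_idx)

    center = v.mean(axis=0)
    cov = np.cov((v - center).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or (evals[-1] - evals[-2]) / evals[-1] < 0.05:
        raise AxisError(
            "principal axes nearly degenerate (spherical vertex cloud); "
            "supply base_ring_hint"
        )
    u = evecs[:, -1]
    s = (v - center) @ u
    span = s.max() - s.min()

    def cap_flatness(end_sign: int) -> float:
        # axial spread of the end slab relative to its radial extent: a flat
        # basal cap scores ~0, a pointed apex scores high
        if end_sign > 0:
            sel = s >= s.max() - 0.05 * span
        else:
            sel = s <= s.min() + 0.05 * span
        pts = v[sel]
        radial = pts - center - np.outer((pts - center) @ u, u)
        extent = np.linalg.norm(radial, axis=1).max()
        return float(np.std(s[sel]) / (extent + 1e-9))

    flat_hi = cap_flatness(+1)
    flat_lo = cap_flatness(-1)
    base_sign = +1 if flat_hi <= flat_lo else -1
    if base_sign > 0:
        rim = v[s >= s.max() - 0.02 * span]
    else:
        rim = v[s <= s.min() + 0.02 * span]
    base_center = rim.mean(axis=0)
    direction = -base_sign * u
    apex_idx = int(np.argmax((v - base_center) @ direction))
    apex = v[apex_idx]
    return LongAxis(apex, base_center, apex - base_center, apex_idx)


# --------------------------------------------------------------------------
# contours as material surface points
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SurfacePoint:
    """A material point: a face index plus barycentric weights on that face."""

    face_index: int
    barycentric: tuple[float, float, float]

    def __post_init__(self) -> None:
        w = np.asarray(self.barycentric, float)
        if w.min() < -1e-9 or abs(w.sum() - 1.0) > 1e-9:
            raise StrainError(f"invalid barycentric weights {tuple(w)}")
        object.__setattr__(self, "barycentric", tuple(np.clip(w, 0.0, None)))


@dataclass(frozen=True)
class Contour:
    """Polyline of material surface points; closed for latitudes."""

    points: tuple[SurfacePoint, ...]
    closed: bool

    def realize(self, mesh: Mesh) -> np.ndarray:
        """Positions (k, 3) of the material points on a given frame."""
        faces = np.array([p.face_index for p in self.points])
        if faces.size and faces.max() >= mesh.n_faces:
            raise StrainError(
                f"contour face index {faces.max()} out of range for mesh "
                f"with {mesh.n_faces} faces"
            )
        w = np.array([p.barycentric for p in self.points])  # (k, 3)
        tri = mesh.vertices[mesh.faces[faces]]  # (k, 3, 3)
        return np.einsum("kj,kjd->kd", w, tri)

    def length(self, mesh: Mesh) -> float:
        pts = self.realize(mesh)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        if self.closed:
            seg += np.linalg.norm(pts[0] - pts[-1])
        return float(seg)


@dataclass(frozen=True)
class ContourSet:
    """15 closed latitudes + 45 open apex->mid->base longitudes on the ED frame."""

    latitudes: tuple[Contour, ...]
    longitudes: tuple[Contour, ...]


def _slice_loops(mesh: Mesh, axis: LongAxis, level: float) -> list[Contour]:
    """Closed intersection loops of the mesh with the plane at axial fraction ``level``."""
    t = axis.axial_fraction(mesh.vertices)
    # nudge the level off any vertex so every crossing is a clean edge crossing
    lvl = level
    for _ in range(40):
        if np.abs(t - lvl).min() > 1e-12:
            break
        lvl += 1e-9
    d = t - lvl

    f = mesh.faces
    loops: list[Contour] = []
    # for each face, the two crossing edges (if sign change)
    edge_pairs = [(0, 1), (1, 2), (2, 0)]
    # map undirected crossing edge -> interpolation parameter & adjacency
    edge_param: dict[tuple[int, int], float] = {}
    edge_faces: dict[tuple[int, int], list[int]] = {}
    face_edges: dict[int, list[tuple[int, int]]] = {}
    sign = d > 0
    crossing_faces = np.nonzero(
        (sign[f[:, 0]] != sign[f[:, 1]])
        | (sign[f[:, 1]] != sign[f[:, 2]])
    )[0]
    for fi in crossing_faces:
        tri = f[fi]
        edges_here = []
        for a, b in edge_pairs:
            i, j = int(tri[a]), int(tri[b])
            if sign[i] != sign[j]:
                key = (i, j) if i < j else (j, i)
                if key not in edge_param:
                    di, dj = d[key[0]], d[key[1]]
                    edge_param[key] = float(di / (di - dj))
                edge_faces.setdefault(key, []).append(int(fi))
                edges_here.append(key)
        if len(edges_here) == 2:
            face_edges[int(fi)] = edges_here
    if not edge_param:
        raise StrainError(f"slicing plane at fraction {level:.3f} misses the mesh")

    visited: set[tuple[int, int]] = set()
    for start in edge_param:
        if start in visited:
            continue
        loop_pts: list[SurfacePoint] = []
        edge = start
        prev_face = -1
        while True:
            visited.add(edge)
            adj = [fi for fi in edge_faces[edge] if fi != prev_face and fi in face_edges]
            if not adj:
                break  # open chain (non-closed surface); drop
            fi = adj[0]
            tri = f[fi]
            s = edge_param[edge]
            w = np.zeros(3)
            w[np.where(tri == edge[0])[0][0]] = 1.0 - s
            w[np.where(tri == edge[1])[0][0]] = s
            loop_pts.append(SurfacePoint(fi, tuple(w)))
            nxt = [e for e in face_edges[fi] if e != edge]
            if not nxt:
                break
            edge = nxt[0]
            prev_face = fi
            if edge == start:
                break  # loop closed
        if len(loop_pts) >= 3:
            loops.append(Contour(tuple(loop_pts), closed=True))
    if not loops:
        raise StrainError(f"no closed loop at axial fraction {level:.3f}")
    return loops


def extract_latitudes(mesh: Mesh, axis: LongAxis, n: int = 15) -> tuple[Contour, ...]:
    """Slice ``n`` circumferential contours at fractions k/(n+1), apex to base.

    The slicing planes are orthogonal to the long axis, strictly between apex
    and base centre. When a plane intersects the surface in several loops
    (e.g. near trabecular folds) the longest loop is kept.
    """
    out = []
    for k in range(1, n + 1):
        loops = _slice_loops(mesh, axis, k / (n + 1))
        best = max(loops, key=lambda c: c.length(mesh))
        out.append(best)
    return tuple(out)


def _edge_graph(mesh: Mesh):
    f = mesh.faces
    e = np.sort(np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1)
    e = np.unique(e, axis=0)
    i, j = e[:, 0], e[:, 1]
    w = np.linalg.norm(mesh.vertices[i] - mesh.vertices[j], axis=1)
    n = mesh.n_vertices
    g = coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    )
    return g.tocsr()


def _shortest_path_vertices(graph, source: int, target: int) -> list[int]:
    dist, pred = dijkstra(graph, indices=source, return_predecessors=True)
    if not np.isfinite(dist[target]):
        raise StrainError("mesh edge graph is disconnected")
    path = [target]
    while path[-1] != source:
        p = pred[path[-1]]
        if p < 0:
            raise StrainError("mesh edge graph is disconnected")
        path.append(int(p))
    return path[::-1]


def _vertex_surface_point(mesh: Mesh, vertex: int, vertex_face: np.ndarray) -> SurfacePoint:
    fi = int(vertex_face[vertex])
    w = np.zeros(3)
    w[np.where(mesh.faces[fi] == vertex)[0][0]] = 1.0
    return SurfacePoint(fi, tuple(w))


def _azimuth_frame(axis: LongAxis) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane frame: u ~ global x projected off the axis."""
    d = axis.direction
    u = np.array([1.0, 0.0, 0.0]) - d[0] * d
    if np.linalg.norm(u) < 1e-6:
        u = np.array([0.0, 1.0, 0.0]) - d[1] * d
    u /= np.linalg.norm(u)
    w = np.cross(d, u)
    return u, w


def extract_longitudes(
    mesh: Mesh,
    axis: LongAxis,
    n: int = 45,
    latitudes: tuple[Contour, ...] | None = None,
) -> tuple[Contour, ...]:
    """Build ``n`` apex->mid->base longitudinal contours.

    Base seed points sit on the basal rim (vertices within the top 2% of the
    axial extent, away from the cap interior) at equal azimuthal increments
    about the long axis, starting from the lowest-index rim vertex (a
    deterministic, rigid-motion-invariant anchor). Each longitude is the
    mesh-edge-graph shortest path
    apex -> nearest mid-level latitude vertex in the seed's angular sector ->
    base seed, mirroring an apex-to-base geodesic through mid-cavity.
    """
    if latitudes is None:
        latitudes = extract_latitudes(mesh, axis, 15)
    v = mesh.vertices
    t = axis.axial_fraction(v)
    span = t.max() - t.min()
    u, w = _azimuth_frame(axis)
    # basal slab: start at 2% of the axial extent and widen until the rim
    # (cap-interior vertices excluded by a radial cut) can seed n longitudes
    rim = np.empty(0, dtype=int)
    for frac in (0.02, 0.05, 0.10, 0.15, 0.25):
        slab = np.nonzero(t >= t.max() - frac * span)[0]
        rel = v[slab] - axis.base_center
        radial = np.sqrt((rel @ u) ** 2 + (rel @ w) ** 2)
        rim = slab[radial >= 0.8 * radial.max()]
        if rim.size >= max(n, int(1.5 * n)):
            break
    rim_az = np.arctan2((v[rim] - axis.base_center) @ w, (v[rim] - axis.base_center) @ u)

    # first incident face per vertex (for one-hot barycentric representation)
    vertex_face = np.full(mesh.n_vertices, -1, dtype=int)
    for fi, tri in enumerate(mesh.faces):
        for vid in tri:
            if vertex_face[vid] < 0:
                vertex_face[vid] = fi

    # mid-level latitude vertices: each latitude point's dominant edge endpoint
    mid = latitudes[len(latitudes) // 2]
    mid_vertices = []
    for p in mid.points:
        tri = mesh.faces[p.face_index]
        mid_vertices.append(int(tri[int(np.argmax(p.barycentric))]))
    mid_vertices = np.unique(mid_vertices)
    mid_az = np.arctan2(
        (v[mid_vertices] - axis.base_center) @ w, (v[mid_vertices] - axis.base_center) @ u
    )

    if axis.apex_index is None:
        apex_idx = int(np.argmin(np.linalg.norm(v - axis.apex_point, axis=1)))
    else:
        apex_idx = axis.apex_index

    graph = _edge_graph(mesh)
    dist_apex, pred_apex = dijkstra(graph, indices=apex_idx, return_predecessors=True)

    def circdist(a, b):
        return np.abs(np.angle(np.exp(1j * (a - b))))

    # azimuth origin anchored at the lowest-index rim vertex: deterministic
    # and intrinsic to the mesh, so seeding is rigid-motion invariant
    theta0 = rim_az[int(np.argmin(rim))]
    targets = theta0 + 2.0 * np.pi * np.arange(n) / n

    used: set[int] = set()
    seeds = []
    for th in targets:
        order = np.argsort(circdist(rim_az, th))
        pick = next((int(rim[k]) for k in order if int(rim[k]) not in used), None)
        if pick is None:
            raise StrainError(f"basal rim has fewer than {n} distinct vertices")
        used.add(pick)
        seeds.append((pick, th))

    # one multi-source dijkstra per distinct mid waypoint
    waypoint_for_seed = []
    for _, th in seeds:
        k = int(np.argmin(circdist(mid_az, th)))
        waypoint_for_seed.append(int(mid_vertices[k]))
    distinct_wp = sorted(set(waypoint_for_seed))
    wp_dist = {}
    wp_pred = {}
    for wp in distinct_wp:
        dwp, pwp = dijkstra(graph, indices=wp, return_predecessors=True)
        wp_dist[wp], wp_pred[wp] = dwp, pwp

    longitudes = []
    for (base_vid, _), wp in zip(seeds, waypoint_for_seed):
        if not np.isfinite(dist_apex[wp]) or not np.isfinite(wp_dist[wp][base_vid]):
            raise StrainError("mesh edge graph is disconnected")
        # apex -> waypoint (walk back from wp along apex predecessors)
        path1 = [wp]
        while path1[-1] != apex_idx:
            path1.append(int(pred_apex[path1[-1]]))
        path1 = path1[::-1]
        # waypoint -> base (walk back from base along waypoint predecessors)
        path2 = [base_vid]
        while path2[-1] != wp:
            path2.append(int(wp_pred[wp][path2[-1]]))
        path2 = path2[::-1]
        vertices_path = path1 + path2[1:]
        pts = tuple(_vertex_surface_point(mesh, vid, vertex_face) for vid in vertices_path)
        longitudes.append(Contour(pts, closed=False))
    return tuple(longitudes)


def build_contour_set(
    mesh: Mesh,
    axis: LongAxis | None = None,
    n_lat: int = 15,
    n_long: int = 45,
    base_ring_hint: np.ndarray | None = None,
) -> ContourSet:
    """Construct the full latitude/longitude contour set on an ED mesh."""
    if axis is None:
        axis = compute_long_axis(mesh, base_ring_hint)
    lats = extract_latitudes(mesh, axis, n_lat)
    longs = extract_longitudes(mesh, axis, n_long, lats)
    return ContourSet(lats, longs)


# --------------------------------------------------------------------------
# propagation and strains
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PropagatedContours:
    """Per-frame contour lengths (mm): latitudes (F, n_lat), longitudes (F, n_long)."""

    latitude_lengths: np.ndarray
    longitude_lengths: np.ndarray


def propagate_contours(series: FrameSeries, contours: ContourSet) -> PropagatedContours:
    """Realise the material contours on every frame and measure their lengths."""
    lat = np.array(
        [[c.length(m) for c in contours.latitudes] for m in series.frames]
    )
    lon = np.array(
        [[c.length(m) for c in contours.longitudes] for m in series.frames]
    )
    return PropagatedContours(lat, lon)


@dataclass(frozen=True)
class StrainResult:
    """Per-subject volumes, EF and global strains (positive = shortening)."""

    rvedv_mL: float
    rvesv_mL: float
    rvef_pct: float
    gcs_pct: float
    gls_pct: float
    gas_pct: float
    ed_index: int
    es_index: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "rvedv_mL", "rvesv_mL", "rvef_pct", "gcs_pct", "gls_pct", "gas_pct",
            "ed_index", "es_index",
        )}


def compute_strains(
    series: FrameSeries,
    n_lat: int = 15,
    n_long: int = 45,
    base_ring_hint: np.ndarray | None = None,
    return_contours: bool = False,
):
    """Compute RVEDV/RVESV/RVEF and global circumferential/longitudinal/area strain.

    Contours are defined once on the ED frame and tracked materially; strains
    compare ED with ES (volume-curve extrema). Shortening is reported as a
    positive percentage.
    """
    vc = volume_curve(series)
    ed, es = vc.ed_index, vc.es_index
    edv, esv = float(vc.volumes[ed]), float(vc.volumes[es])
    if ed == es:
        warnings.warn("ED and ES coincide (flat volume curve); strains set to 0")
        result = StrainResult(edv, esv, 0.0, 0.0, 0.0, 0.0, ed, es)
        return (result, None, None) if return_contours else result

    ed_mesh = series.frames[ed]
    contours = build_contour_set(ed_mesh, None, n_lat, n_long, base_ring_hint)
    prop = propagate_contours(series, contours)

    c_ed, c_es = prop.latitude_lengths[ed], prop.latitude_lengths[es]
    l_ed, l_es = prop.longitude_lengths[ed], prop.longitude_lengths[es]
    gcs = float(np.mean((c_ed - c_es) / c_ed) * 100.0)
    gls = float(np.mean((l_ed - l_es) / l_ed) * 100.0)
    a_ed = surface_area(series.frames[ed])
    a_es = surface_area(series.frames[es])
    gas = float((a_ed - a_es) / a_ed * 100.0)
    rvef = float((edv - esv) / edv * 100.0)
    result = StrainResult(edv, esv, rvef, gcs, gls, gas, ed, es)
    if return_contours:
        return result, contours, prop
    return result
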