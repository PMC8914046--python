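"""Closed triangular endocardial surface meshes and primitive geometry.

A :class:`Mesh` is one endocardial surface at one cardiac frame: vertices in
millimetres and triangular faces. A :class:`FrameSeries` is a topology-constant
sequence of such meshes over one cardiac cycle (same vertex count and identical
face list in every frame), which is what makes material tracking of contours
across the cycle well defined.

Volumes are reported in mL (mm^3 / 1000) and areas in mm^2, matching clinical
reporting conventions.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import MeshValidationError, SeriesError

__all__ = [
    "Mesh",
    "MeshValidation",
    "FrameSeries",
    "VolumeCurve",
    "validate_mesh",
    "repair_orientation",
    "surface_area",
    "enclosed_volume",
    "volume_curve",
]

#: triangles with area below this (mm^2) count as degenerate
DEGENERATE_AREA_TOL = 1e-9


@dataclass(frozen=True)
class Mesh:
    """A triangular surface mesh. ``vertices`` (n, 3) in mm, ``faces`` (m, 3)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshValidationError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshValidationError(f"faces must be (m, 3) triangles, got {f.shape}")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise MeshValidationError(
                f"face index out of range: max {f.max()} for {len(v)} vertices"
            )
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        """View as a :class:`trimesh.Trimesh` without vertex merging/reordering."""
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def transformed(self, matrix: np.ndarray) -> "Mesh":
        """Apply a 4x4 homogeneous or 3x3 linear transform to the vertices."""
        m = np.asarray(matrix, dtype=float)
        if m.shape == (3, 3):
            v = self.vertices @ m.T
        elif m.shape == (4, 4):
            v = self.vertices @ m[:3, :3].T + m[:3, 3]
        else:
            raise ValueError("matrix must be 3x3 or 4x4")
        return Mesh(v, self.faces)

    def scaled(self, s: float) -> "Mesh":
        return Mesh(self.vertices * float(s), self.faces)


@dataclass(frozen=True)
class MeshValidation:
    """Report of :func:`validate_mesh`; purely informational, never raises."""

    closed: bool
    oriented: bool
    n_degenerate: int
    boundary_edges: tuple[tuple[int, int], ...]

    @property
    def ok(self) -> bool:
        return self.closed and self.oriented and self.n_degenerate == 0


def _triangle_areas(mesh: Mesh) -> np.ndarray:
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def validate_mesh(mesh: Mesh, area_tol: float = DEGENERATE_AREA_TOL) -> MeshValidation:
    """Check closedness, winding consistency, and face degeneracy.

    A surface is *closed* when every undirected edge is shared by exactly two
    faces, and *consistently oriented* when the two faces traverse the shared
    edge in opposite directions. Faces with a repeated vertex index or area
    below ``area_tol`` are counted as degenerate.
    """
    f = mesh.faces
    repeated = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
    n_degenerate = int(repeated.sum() + (_triangle_areas(mesh) < area_tol)[~repeated].sum())

    directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    undirected = np.sort(directed, axis=1)
    uniq, counts = np.unique(undirected, axis=0, return_counts=True)
    boundary = tuple(map(tuple, uniq[counts == 1].tolist()))
    closed = bool((counts == 2).all()) and f.size > 0
    # if any directed edge occurs twice, its two faces wind the same way
    _, dir_counts = np.unique(directed, axis=0, return_counts=True)
    oriented = bool((dir_counts == 1).all()) and bool((counts <= 2).all()) and f.size > 0
    return MeshValidation(closed, oriented, n_degenerate, boundary)


def repair_orientation(mesh: Mesh) -> Mesh:
    """Return a copy with consistent outward winding (flood-fill repair).

    Uses trimesh's winding repair; raises if the result is still inconsistent.
    """
    tm = mesh.to_trimesh()
    trimesh.repair.fix_normals(tm)
    repaired = Mesh(np.asarray(tm.vertices), np.asarray(tm.faces))
    if not validate_mesh(repaired).oriented:
        raise MeshValidationError("winding could not be made consistent")
    return repaired


def surface_area(mesh: Mesh) -> float:
    """Total surface area in mm^2 (sum of triangle areas)."""
    report = validate_mesh(mesh)
    if report.n_degenerate:
        raise MeshValidationError(
            f"mesh has {report.n_degenerate} degenerate faces; area is unreliable"
        )
    return float(_triangle_areas(mesh).sum())


def enclosed_volume(mesh: Mesh) -> float:
    """Volume enclosed by a closed, consistently oriented mesh, in mL.

    Computed as the absolute signed-tetrahedron sum about the origin
    (divergence theorem) divided by 1000 (mm^3 -> mL). Winding is auto-repaired
    when inconsistent but fixable; an open surface is an error.
    """
    report = validate_mesh(mesh)
    if not report.closed:
        shown = ", ".join(map(str, report.boundary_edges[:10]))
        raise MeshValidationError(
            f"volume undefined for open mesh; {len(report.boundary_edges)} "
            f"boundary edges (first: {shown})"
        )
    if not report.oriented:
        mesh = repair_orientation(mesh)
    tri = mesh.vertices[mesh.faces]
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    return abs(float(signed.sum())) / 1000.0


@dataclass(frozen=True)
class FrameSeries:
    """Topology-constant mesh sequence over one cardiac cycle.

    All frames must share the vertex count and the exact face list; frame
    times are in ms from cycle start and strictly increasing.
    """

    frames: tuple[Mesh, ...]
    frame_times: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if len(frames) < 2:
            raise SeriesError(f"need >= 2 frames, got {len(frames)}")
        ref = frames[0]
        for i, fr in enumerate(frames[1:], start=1):
            if fr.n_vertices != ref.n_vertices:
                raise SeriesError(
                    f"frame {i} has {fr.n_vertices} vertices, expected {ref.n_vertices}"
                )
            if not np.array_equal(fr.faces, ref.faces):
                raise SeriesError(f"frame {i} face list differs from frame 0")
        times = np.asarray(self.frame_times, dtype=float)
        if times.shape != (len(frames),):
            raise SeriesError(
                f"frame_times length {times.shape} does not match {len(frames)} frames"
            )
        if not (np.diff(times) > 0).all():
            raise SeriesError("frame_times must be strictly increasing")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "frame_times", times)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def faces(self) -> np.ndarray:
        return self.frames[0].faces


@dataclass(frozen=True)
class VolumeCurve:
    """Per-frame cavity volumes (mL) with end-diastolic/systolic frame indices."""

    volumes: np.ndarray
    ed_index: int
    es_index: int

    def to_frame(self, frame_times: np.ndarray | None = None):
        """As a pandas DataFrame (frame, time_ms, volume_mL, is_ED, is_ES)."""
        import pandas as pd

        n = len(self.volumes)
        times = np.arange(n, dtype=float) if frame_times is None else frame_times
        return pd.DataFrame(
            {
                "frame": np.arange(n),
                "time_ms": times,
                "volume_mL": self.volumes,
                "is_ED": np.arange(n) == self.ed_index,
                "is_ES": np.arange(n) == self.es_index,
            }
        )


def volume_curve(series: FrameSeries) -> VolumeCurve:
    """Compute per-frame volumes; ED = argmax, ES = argmin (earliest on ties)."""
    vols = np.array([enclosed_volume(m) for m in series.frames])
    return VolumeCurve(vols, int(np.argmax(vols)), int(np.argmin(vols)))
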