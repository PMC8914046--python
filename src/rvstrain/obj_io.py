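"""Wavefront OBJ reading/writing for per-frame endocardial meshes.

Deliberately strict subset of the OBJ dialect produced by mesh-export
pipelines: ``v`` and ``f`` records are honoured, ``vn``/``vt``/material and
group records are ignored, polygonal faces are fan-triangulated from their
first vertex, and vertex order is preserved exactly so that vertex
correspondence across a frame series survives a round-trip. Parse failures
name the file and 1-based line number.
"""
from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import MeshValidationError, ObjParseError, SeriesError
from .mesh import FrameSeries, Mesh, validate_mesh

__all__ = [
    "read_obj",
    "write_obj",
    "read_obj_series",
    "read_obj_dir",
    "write_obj_series",
    "natural_sort",
]

_IGNORED = {"vn", "vt", "vp", "g", "o", "s", "usemtl", "mtllib", "l", "p", "#"}


def read_obj(path: str | Path) -> Mesh:
    """Parse a single OBJ file into a :class:`Mesh` (vertex order preserved)."""
    path = Path(path)
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            key = tokens[0]
            if key == "v":
                if len(tokens) < 4:
                    raise ObjParseError(f"{path}:{lineno}: vertex needs 3 coordinates")
                try:
                    vertices.append([float(t) for t in tokens[1:4]])
                except ValueError as exc:
                    raise ObjParseError(f"{path}:{lineno}: bad vertex coordinate: {exc}")
            elif key == "f":
                if len(tokens) < 4:
                    raise ObjParseError(f"{path}:{lineno}: face needs >= 3 vertices")
                idx = []
                for tok in tokens[1:]:
                    head = tok.split("/")[0]
                    try:
                        i = int(head)
                    except ValueError:
                        raise ObjParseError(f"{path}:{lineno}: bad face index {tok!r}")
                    if i == 0:
                        raise ObjParseError(f"{path}:{lineno}: OBJ indices are 1-based")
                    # negative indices count back from the current vertex list
                    idx.append(i - 1 if i > 0 else len(vertices) + i)
                for j in idx:
                    if j < 0 or j >= len(vertices):
                        raise ObjParseError(
                            f"{path}:{lineno}: face index {j + 1} out of range "
                            f"({len(vertices)} vertices so far)"
                        )
                for k in range(1, len(idx) - 1):  # fan from first vertex
                    faces.append([idx[0], idx[k], idx[k + 1]])
            elif key in _IGNORED:
                continue
            else:
                raise ObjParseError(f"{path}:{lineno}: unsupported record {key!r}")
    if not vertices or not faces:
        raise ObjParseError(f"{path}: no vertices or faces found")
    return Mesh(np.array(vertices, dtype=np.float64), np.array(faces, dtype=np.int64))


def write_obj(mesh: Mesh, path: str | Path) -> None:
    """Write a mesh with full float precision (bit-exact round-trip)."""
    path = Path(path)
    with open(path, "w") as fh:
        for x, y, z in mesh.vertices:
            fh.write(f"v {float(x)!r} {float(y)!r} {float(z)!r}\n")
        for a, b, c in mesh.faces + 1:
            fh.write(f"f {a} {b} {c}\n")


def natural_sort(paths: Iterable[str | Path]) -> list[Path]:
    """Sort paths so that frame_2 precedes frame_10."""

    def key(p: Path):
        return [int(t) if t.isdigit() else t for t in re.split(r"(\d+)", p.name)]

    return sorted((Path(p) for p in paths), key=key)


def read_obj_series(
    paths: Sequence[str | Path],
    subject_id: str = "",
    frame_times: Sequence[float] | None = None,
    require_closed: bool = True,
) -> FrameSeries:
    """Load an ordered list of OBJ files as one cardiac-cycle series.

    All frames must share the vertex count and face list (material
    correspondence); the first frame is validated for closedness unless
    ``require_closed`` is False. Default frame times assume a uniformly
    sampled cycle at 1 ms per frame when none are given.
    """
    meshes = [read_obj(p) for p in paths]
    if len(meshes) < 2:
        raise SeriesError(f"series needs >= 2 frames, got {len(meshes)}")
    ref = meshes[0]
    for i, m in enumerate(meshes[1:], start=1):
        if m.n_vertices != ref.n_vertices:
            raise SeriesError(
                f"frame {i} ({Path(paths[i]).name}) has {m.n_vertices} vertices, "
                f"expected {ref.n_vertices}"
            )
        if not np.array_equal(m.faces, ref.faces):
            raise SeriesError(
                f"frame {i} ({Path(paths[i]).name}) face list differs from frame 0"
            )
    if require_closed:
        report = validate_mesh(ref)
        if not report.closed:
            shown = ", ".join(map(str, report.boundary_edges[:10]))
            raise MeshValidationError(
                f"{Path(paths[0]).name}: surface not closed; "
                f"{len(report.boundary_edges)} boundary edges (first: {shown})"
            )
    if frame_times is None:
        frame_times = np.arange(len(meshes), dtype=float)
    return FrameSeries(tuple(meshes), np.asarray(frame_times, float), subject_id)


def read_obj_dir(directory: str | Path, require_closed: bool = True) -> FrameSeries:
    """Load ``*.obj`` files from a directory (naturally sorted).

    An optional ``series.json`` sidecar may carry ``frame_times`` (ms) and
    ``subject_id``.
    """
    directory = Path(directory)
    paths = natural_sort(directory.glob("*.obj"))
    if not paths:
        raise SeriesError(f"no .obj files in {directory}")
    frame_times, subject_id = None, directory.name
    sidecar = directory / "series.json"
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        frame_times = meta.get("frame_times")
        subject_id = meta.get("subject_id", subject_id)
    return read_obj_series(paths, subject_id, frame_times, require_closed)


def write_obj_series(series: FrameSeries, directory: str | Path) -> list[Path]:
    """Write one OBJ per frame plus a ``series.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, mesh in enumerate(series.frames):
        p = directory / f"frame_{i:03d}.obj"
        write_obj(mesh, p)
        paths.append(p)
    (directory / "series.json").write_text(
        json.dumps(
            {
                "subject_id": series.subject_id,
                "frame_times": series.frame_times.tolist(),
            },
            indent=2,
        )
    )
    return paths
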