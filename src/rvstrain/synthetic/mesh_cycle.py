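"""Deforming RV-like mesh cycles with analytic ground-truth strains.

The base shape is a half-ellipsoid (semi-axes ``a, b`` in-plane, ``c`` along
the long axis) closed by a flat basal cap at z = 0, with an optional crescent
("septal bulge") term that pulls the surface inward on one side — a stand-in
for the concave septal wall of a real right ventricle. The cardiac cycle is
emulated by smoothly scaling the in-plane (circumferential) axes by
``s_c(t)`` and the long axis by ``s_l(t)`` with a cosine time profile whose
trough (end-systole) sits at mid-cycle.

Because the deformation is an affine map ``diag(s_c, s_c, s_l)`` of a known
parametric surface, the global strains have closed-form or quadrature ground
truths on the continuous surface:

* every latitude is a planar horizontal curve, so its length scales by
  exactly ``s_c``: GCS = (1 - s_c) x 100,
* meridian lengths and surface areas are integrated numerically at 10x the
  mesh resolution,
* the cavity volume scales by ``det = s_c^2 s_l``: EF = (1 - s_c^2 s_l) x 100.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigError
from ..mesh import FrameSeries, Mesh

__all__ = ["MeshCycleParams", "StrainGroundTruth", "generate_mesh_cycle"]


@dataclass(frozen=True)
class MeshCycleParams:
    """Configuration of one synthetic cardiac cycle.

    Scales are end-systolic multipliers in (0, 1]; ``noise_sd`` is per-vertex
    Gaussian jitter in mm applied independently per frame (tracking noise).
    """

    n_frames: int = 20
    semi_axes: tuple[float, float, float] = (30.0, 25.0, 70.0)  # a, b, c in mm
    septal_bulge: float = 0.0  # inward crescent amplitude, mm
    longitudinal_scale_es: float = 0.85
    circumferential_scale_es: float = 0.90
    noise_sd: float = 0.0
    n_theta: int = 90
    n_phi: int = 45
    cycle_ms: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ConfigError(f"n_frames must be >= 2, got {self.n_frames}")
        for name in ("longitudinal_scale_es", "circumferential_scale_es"):
            s = getattr(self, name)
            if not (0.0 < s <= 1.0):
                raise ConfigError(f"{name} must lie in (0, 1], got {s}")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if min(self.semi_axes) <= 0:
            raise ConfigError("semi-axes must be positive")
        if self.n_theta < 8 or self.n_phi < 4:
            raise ConfigError("mesh resolution too low (n_theta >= 8, n_phi >= 4)")


@dataclass(frozen=True)
class StrainGroundTruth:
    """Analytic/quadrature ground truth of the planted deformation."""

    gcs_pct: float
    gls_pct: float
    gas_pct: float
    ef_pct: float
    apex_point: np.ndarray
    base_center: np.ndarray


def _radial_profile(theta: np.ndarray, phi: np.ndarray, p: MeshCycleParams) -> np.ndarray:
    """In-plane radius multiplier implementing the septal crescent (<= 1)."""
    if p.septal_bulge == 0.0:
        return np.ones(np.broadcast(theta, phi).shape)
    depth = p.septal_bulge / max(p.semi_axes[0], p.semi_axes[1])
    return 1.0 - depth * np.sin(phi) * ((1.0 + np.cos(theta - np.pi)) / 2.0) ** 2


def _lateral_surface(theta: np.ndarray, phi: np.ndarray, p: MeshCycleParams) -> np.ndarray:
    """Parametric lateral wall: phi=0 apex, phi=pi/2 basal rim (z=0)."""
    a, b, c = p.semi_axes
    rho = _radial_profile(theta, phi, p)
    x = a * np.sin(phi) * np.cos(theta) * rho
    y = b * np.sin(phi) * np.sin(theta) * rho
    z = -c * np.cos(phi)
    return np.stack(np.broadcast_arrays(x, y, z), axis=-1)


def _build_ed_mesh(p: MeshCycleParams) -> Mesh:
    nt, np_ = p.n_theta, p.n_phi
    theta = 2.0 * np.pi * np.arange(nt) / nt
    verts = [np.array([0.0, 0.0, -p.semi_axes[2]])]  # apex
    for i in range(1, np_ + 1):
        phi = (np.pi / 2.0) * i / np_
        ring = _lateral_surface(theta, np.full(nt, phi), p)
        verts.extend(ring)
    base_center_idx = 1 + np_ * nt
    verts.append(np.array([0.0, 0.0, 0.0]))  # basal cap centre
    vertices = np.array(verts)

    faces = []
    ring_start = lambda i: 1 + (i - 1) * nt  # noqa: E731
    # apex fan (outward winding: seen from outside, CCW)
    for j in range(nt):
        faces.append([0, ring_start(1) + j, ring_start(1) + (j + 1) % nt])
    # lateral quads
    for i in range(1, np_):
        r0, r1 = ring_start(i), ring_start(i + 1)
        for j in range(nt):
            j2 = (j + 1) % nt
            faces.append([r0 + j, r1 + j, r1 + j2])
            faces.append([r0 + j, r1 + j2, r0 + j2])
    # basal cap fan (normal pointing +z, outward)
    rim = ring_start(np_)
    for j in range(nt):
        faces.append([base_center_idx, rim + (j + 1) % nt, rim + j])
    mesh = Mesh(vertices, np.array(faces))
    # winding fixed by construction; make sure the signed volume is positive
    tri = mesh.vertices[mesh.faces]
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()
    if signed < 0:
        mesh = Mesh(mesh.vertices, mesh.faces[:, [0, 2, 1]])
    return mesh


def _scales_at(t: float, p: MeshCycleParams) -> tuple[float, float]:
    phase = (1.0 - np.cos(2.0 * np.pi * t)) / 2.0  # 0 at ED, 1 at mid-cycle ES
    s_c = 1.0 - (1.0 - p.circumferential_scale_es) * phase
    s_l = 1.0 - (1.0 - p.longitudinal_scale_es) * phase
    return float(s_c), float(s_l)


def _quadrature_ground_truth(p: MeshCycleParams) -> StrainGroundTruth:
    s_c, s_l = p.circumferential_scale_es, p.longitudinal_scale_es
    scale = np.array([s_c, s_c, s_l])
    oversample = 10
    nt, np_ = p.n_theta * oversample, p.n_phi * oversample

    # GCS: latitude curves at axial fractions k/16 between apex and base centre
    c = p.semi_axes[2]
    ratios = []
    theta = np.linspace(0.0, 2.0 * np.pi, nt, endpoint=False)
    for k in range(1, 16):
        z = -c + (k / 16.0) * c
        phi = np.arccos(-z / c)
        curve = _lateral_surface(theta, np.full(nt, phi), p)
        closed = np.vstack([curve, curve[:1]])
        led = np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()
        les = np.linalg.norm(np.diff(closed * scale, axis=0), axis=1).sum()
        ratios.append((led - les) / led)
    gcs = float(np.mean(ratios) * 100.0)

    # GLS: 45 meridians apex -> basal rim
    phi = np.linspace(0.0, np.pi / 2.0, np_)
    mer_ratios = []
    for th in 2.0 * np.pi * np.arange(45) / 45:
        curve = _lateral_surface(np.full(np_, th), phi, p)
        led = np.linalg.norm(np.diff(curve, axis=0), axis=1).sum()
        les = np.linalg.norm(np.diff(curve * scale, axis=0), axis=1).sum()
        mer_ratios.append((led - les) / led)
    gls = float(np.mean(mer_ratios) * 100.0)

    # GAS: lateral area by first-fundamental-form quadrature + planar cap area
    tg, pg = np.meshgrid(theta, np.linspace(0.0, np.pi / 2.0, np_), indexing="ij")
    surf = _lateral_surface(tg, pg, p)

    def lateral_area(points: np.ndarray) -> float:
        dth = np.diff(points, axis=0)  # wrap handled below
        wrap = points[:1] - points[-1:]
        dth = np.concatenate([dth, wrap], axis=0)
        dph = np.diff(points, axis=1)
        # cell area via cross product of the two edge vectors (midpoint rule)
        cell = np.cross(dth[:, :-1], dph)
        return float(np.linalg.norm(cell, axis=-1).sum())

    def cap_area(points_rim: np.ndarray) -> float:
        # planar polygon area (z = const) via shoelace
        x, y = points_rim[:, 0], points_rim[:, 1]
        return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))

    rim = _lateral_surface(theta, np.full(nt, np.pi / 2.0), p)
    a_ed = lateral_area(surf) + cap_area(rim)
    a_es = lateral_area(surf * scale) + cap_area(rim * scale)
    gas = float((a_ed - a_es) / a_ed * 100.0)

    ef = float((1.0 - s_c * s_c * s_l) * 100.0)
    return StrainGroundTruth(
        gcs, gls, gas, ef,
        apex_point=np.array([0.0, 0.0, -c]),
        base_center=np.array([0.0, 0.0, 0.0]),
    )


def generate_mesh_cycle(params: MeshCycleParams) -> tuple[FrameSeries, StrainGroundTruth]:
    """Generate one deforming mesh cycle and its planted ground truth.

    Frame ``k`` (of ``n_frames``, at time ``k/n_frames`` of the cycle) is the
    ED mesh scaled by the cosine-interpolated axis scales; with an even frame
    count the mid-cycle frame carries exactly the end-systolic scales. Noise,
    if any, is added after deformation with a seeded generator.
    """
    ed = _build_ed_mesh(params)
    rng = np.random.default_rng(params.seed)
    frames = []
    for k in range(params.n_frames):
        s_c, s_l = _scales_at(k / params.n_frames, params)
        v = ed.vertices * np.array([s_c, s_c, s_l])
        if params.noise_sd > 0:
            v = v + rng.normal(0.0, params.noise_sd, size=v.shape)
        frames.append(Mesh(v, ed.faces))
    dt = params.cycle_ms / params.n_frames
    series = FrameSeries(tuple(frames), dt * np.arange(params.n_frames), "synthetic")
    return series, _quadrature_ground_truth(params)
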