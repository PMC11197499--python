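"""Parametric vessel lumens, voxel phantoms and synthetic ultrasound panels.

This module supplies the geometric and physiological inputs that a
patient-specific wall-shear-stress study would obtain from HR-MRI
segmentation and duplex ultrasonography: smooth centerlines, swept tube
lumens with optional eccentric wall thickening (plaque), binary voxel
phantoms at vessel-wall-MRI resolution, and per-artery velocity/radius
panels with a brachial pressure.

Everything is deterministic given its seed; seeds are explicit arguments,
never global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh

from .units import MM_PER_M, mmhg_to_pa

# Anatomical reference frame for generated vessels: the tube axis runs
# roughly along +x, anterior (ventral) is +y, superior (head-ward) is +z.
ANTERIOR = np.array([0.0, 1.0, 0.0])
SUPERIOR = np.array([0.0, 0.0, 1.0])

#: wall name -> angle (rad) in the (normal, binormal) tube frame
WALL_ANGLES = {
    "ventral": 0.0,
    "superior": 0.5 * np.pi,
    "dorsal": np.pi,
    "inferior": 1.5 * np.pi,
}


def _normalize(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


def _rotation_minimizing_frame(points: np.ndarray, tangents: np.ndarray, ref: np.ndarray):
    """Propagate a normal along the curve by the double-reflection method.

    Unlike the Frenet frame, the rotation-minimizing frame has no flips at
    inflection points, which keeps wall-quadrant labels stable on s-shaped
    vessels.
    """
    n = len(points)
    e1 = np.zeros_like(points)
    v = ref - np.dot(ref, tangents[0]) * tangents[0]
    if np.linalg.norm(v) < 1e-12:  # reference parallel to the axis
        v = np.cross(tangents[0], [0.0, 0.0, 1.0])
        if np.linalg.norm(v) < 1e-12:
            v = np.cross(tangents[0], [0.0, 1.0, 0.0])
    e1[0] = v / np.linalg.norm(v)
    for i in range(n - 1):
        v1 = points[i + 1] - points[i]
        c1 = np.dot(v1, v1)
        if c1 < 1e-30:
            e1[i + 1] = e1[i]
            continue
        r_l = e1[i] - (2.0 / c1) * np.dot(v1, e1[i]) * v1
        t_l = tangents[i] - (2.0 / c1) * np.dot(v1, tangents[i]) * v1
        v2 = tangents[i + 1] - t_l
        c2 = np.dot(v2, v2)
        if c2 < 1e-30:
            e1[i + 1] = r_l
        else:
            e1[i + 1] = r_l - (2.0 / c2) * np.dot(v2, r_l) * v2
    e1 = _normalize(e1 - np.sum(e1 * tangents, axis=1, keepdims=True) * tangents)
    e2 = np.cross(tangents, e1)
    return e1, e2


@dataclass
class Centerline:
    """Ordered polyline with arclength, tangents and a rotation-minimizing frame.

    ``normals``/``binormals`` span the cross-sectional plane at each point and
    define the angular coordinate used for wall placement (angle 0 = normal
    direction, which for generated vessels points anterior).
    """

    points: np.ndarray          # (n, 3) m
    arclengths: np.ndarray      # (n,) m, cumulative
    tangents: np.ndarray        # (n, 3) unit
    normals: np.ndarray         # (n, 3) unit, frame e1
    binormals: np.ndarray       # (n, 3) unit, frame e2

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.arclengths = np.asarray(self.arclengths, dtype=float)
        if len(self.points) < 2:
            raise ValueError("a centerline needs at least 2 points")
        if not np.all(np.diff(self.arclengths) > 0):
            raise ValueError("arclengths must be strictly increasing")
        norms = np.linalg.norm(self.tangents, axis=1)
        if np.max(np.abs(norms - 1.0)) > 1e-9:
            raise ValueError("tangents must be unit vectors")

    @property
    def length(self) -> float:
        return float(self.arclengths[-1] - self.arclengths[0])

    def curvature_vectors(self) -> np.ndarray:
        """dT/ds per point; points toward the local center of curvature."""
        return np.gradient(self.tangents, self.arclengths, axis=0)

    def curvature(self) -> np.ndarray:
        return np.linalg.norm(self.curvature_vectors(), axis=1)

    def resample(self, n_points: int) -> "Centerline":
        s = np.linspace(self.arclengths[0], self.arclengths[-1], n_points)
        pts = np.column_stack(
            [np.interp(s, self.arclengths, self.points[:, k]) for k in range(3)]
        )
        return _centerline_from_points(pts, ref=self.normals[0])


def _centerline_from_points(points: np.ndarray, ref: np.ndarray = ANTERIOR) -> Centerline:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arclengths = np.concatenate([[0.0], np.cumsum(seg)])
    tangents = _normalize(np.gradient(points, arclengths, axis=0, edge_order=2))
    e1, e2 = _rotation_minimizing_frame(points, tangents, np.asarray(ref, dtype=float))
    return Centerline(points, arclengths, tangents, e1, e2)


def make_centerline(
    shape: str,
    length: float,
    curve_radius: float = 0.012,
    n_points: int = 100,
    seed: int = 0,
    wiggle: float = 0.0,
) -> Centerline:
    """Generate a smooth centerline of the requested arclength.

    shape
        ``straight`` (along +x), ``curved`` (constant-curvature arc bending
        toward anterior, curvature = 1/curve_radius) or ``s_curve`` (two
        arcs of opposite bend).
    wiggle
        optional smooth perturbation amplitude (m); its phases are drawn
        from ``seed`` so identical seeds give bit-identical centerlines.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if n_points < 10:
        raise ValueError("n_points must be at least 10")
    if shape in ("curved", "s_curve") and curve_radius <= 0:
        raise ValueError("curve_radius must be positive for curved shapes")

    # parameterize by arclength exactly
    s = np.linspace(0.0, length, n_points)
    if shape == "straight":
        pts = np.column_stack([s, np.zeros_like(s), np.zeros_like(s)])
    elif shape == "curved":
        phi = s / curve_radius
        pts = np.column_stack(
            [curve_radius * np.sin(phi), curve_radius * (1 - np.cos(phi)), np.zeros_like(s)]
        )
    elif shape == "s_curve":
        phi = s / curve_radius
        half = length / 2.0
        phi_h = half / curve_radius
        first = s <= half
        x = np.where(
            first,
            curve_radius * np.sin(phi),
            curve_radius * np.sin(phi_h)
            + curve_radius * (np.sin(phi_h) - np.sin(2 * phi_h - phi)),
        )
        y = np.where(
            first,
            curve_radius * (1 - np.cos(phi)),
            curve_radius * (1 - np.cos(phi_h))
            + curve_radius * (np.cos(2 * phi_h - phi) - np.cos(phi_h)),
        )
        pts = np.column_stack([x, y, np.zeros_like(s)])
    else:
        raise ValueError(f"unknown centerline shape {shape!r}")

    if wiggle > 0.0:
        rng = np.random.default_rng(seed)
        phases = rng.uniform(0, 2 * np.pi, size=2)
        win = np.sin(np.pi * s / length) ** 2  # pinned at both ends
        pts[:, 1] += wiggle * win * np.sin(2 * np.pi * s / length + phases[0])
        pts[:, 2] += wiggle * win * np.sin(2 * np.pi * s / length + phases[1])

    return _centerline_from_points(pts)


@dataclass
class PlaqueSpec:
    """Eccentric inward wall thickening on one named wall.

    The lumen radius inside the plaque extent is reduced by up to
    ``thickening`` times the base radius at the plaque's angular center; the
    thickening falls smoothly to zero within ``angular_halfwidth`` so the
    opposite wall is untouched (the thinnest wall thickness is 0, i.e. under
    50% of the thickest — the eccentricity rule every generated plaque obeys).
    """

    wall: str                       # ventral | dorsal | superior | inferior
    center_arclength: float         # m
    extent: float                   # axial length of the thickened zone, m
    thickening: float               # peak fractional lumen-radius reduction
    angular_halfwidth: float = 0.5 * np.pi  # rad, < pi keeps it eccentric

    def __post_init__(self):
        if self.wall not in WALL_ANGLES:
            raise ValueError(f"unknown wall {self.wall!r}")
        if not (0.0 < self.thickening < 0.9):
            raise ValueError("thickening fraction must lie in (0, 0.9)")
        if not (0.0 < self.angular_halfwidth < np.pi):
            raise ValueError("angular_halfwidth must lie in (0, pi) for eccentricity")
        if self.extent <= 0:
            raise ValueError("extent must be positive")


@dataclass
class VesselGeometry:
    """A lumen: centerline + radius profile + triangulated surface.

    ``local_radius(s, theta)`` is the authoritative parametric description;
    the triangulated ``surface`` (and any mesh built later) discretize it.
    """

    centerline: Centerline
    radius_profile: np.ndarray           # (n,) m, per centerline point
    surface: trimesh.Trimesh
    plaque: PlaqueSpec | None = None
    n_theta: int = 48
    capped: bool = True                  # False = inlet/outlet caps left open

    def __post_init__(self):
        self.radius_profile = np.asarray(self.radius_profile, dtype=float)
        if np.any(self.radius_profile <= 0):
            raise ValueError("all radii must be positive")

    def base_radius_at(self, s):
        return np.interp(s, self.centerline.arclengths, self.radius_profile)

    def _plaque_factor(self, s, theta):
        pl = self.plaque
        if pl is None:
            return np.zeros_like(np.asarray(s, dtype=float) + np.asarray(theta, dtype=float))
        s = np.asarray(s, dtype=float)
        theta = np.asarray(theta, dtype=float)
        ds = np.abs(s - pl.center_arclength)
        axial = np.where(ds < pl.extent / 2, np.cos(np.pi * ds / pl.extent) ** 2, 0.0)
        dth = np.angle(np.exp(1j * (theta - WALL_ANGLES[pl.wall])))
        ang = np.where(
            np.abs(dth) < pl.angular_halfwidth,
            np.cos(0.5 * np.pi * dth / pl.angular_halfwidth) ** 2,
            0.0,
        )
        return pl.thickening * axial * ang

    def local_radius(self, s, theta):
        """Lumen radius (m) at arclength ``s`` and frame angle ``theta``."""
        return self.base_radius_at(s) * (1.0 - self._plaque_factor(s, theta))

    def wall_thickening(self, s, theta):
        """Inward thickening (m) relative to the plaque-free lumen."""
        return self.base_radius_at(s) * self._plaque_factor(s, theta)

    def enclosed_volume(self) -> float:
        if not self.capped:
            raise ValueError("volume undefined for an uncapped surface")
        return float(abs(self.surface.volume))

    def write_stl(self, path) -> None:
        self.surface.export(path, file_type="stl")

    def write_ply(self, path) -> None:
        self.surface.export(path, file_type="ply")


def make_vessel_surface(
    centerline: Centerline,
    base_radius,
    plaque_spec: PlaqueSpec | None = None,
    n_theta: int = 48,
    capped: bool = True,
) -> VesselGeometry:
    """Sweep a tube surface along the centerline.

    ``base_radius`` may be a scalar or a per-centerline-point profile.  With a
    ``plaque_spec`` the named wall bulges inward per the eccentric-thickening
    model; the plaque extent must fit inside the vessel.
    """
    cl = centerline
    radius_profile = np.broadcast_to(
        np.asarray(base_radius, dtype=float), cl.points.shape[:1]
    ).copy()
    if np.any(radius_profile <= 0):
        raise ValueError("base_radius must be positive")
    if plaque_spec is not None:
        lo = plaque_spec.center_arclength - plaque_spec.extent / 2
        hi = plaque_spec.center_arclength + plaque_spec.extent / 2
        if lo < cl.arclengths[0] or hi > cl.arclengths[-1]:
            raise ValueError("plaque extent does not fit inside the vessel")

    geom = VesselGeometry(cl, radius_profile, trimesh.Trimesh(), plaque_spec, n_theta, capped)

    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    rr = geom.local_radius(cl.arclengths[:, None], theta[None, :])  # (n, n_theta)
    ring = (
        cl.points[:, None, :]
        + rr[:, :, None]
        * (
            np.cos(theta)[None, :, None] * cl.normals[:, None, :]
            + np.sin(theta)[None, :, None] * cl.binormals[:, None, :]
        )
    )
    n_sec = len(cl.points)
    verts = ring.reshape(n_sec * n_theta, 3)

    faces = []
    for i in range(n_sec - 1):
        a = i * n_theta + np.arange(n_theta)
        b = i * n_theta + (np.arange(n_theta) + 1) % n_theta
        c = a + n_theta
        d = b + n_theta
        # outward winding: (a, b, d) then (a, d, c)
        faces.append(np.column_stack([a, b, d]))
        faces.append(np.column_stack([a, d, c]))
    faces = np.concatenate(faces)

    if capped:
        verts = np.vstack([verts, cl.points[0], cl.points[-1]])
        i0, i1 = len(verts) - 2, len(verts) - 1
        first = np.arange(n_theta)
        last = (n_sec - 1) * n_theta + np.arange(n_theta)
        cap0 = np.column_stack([np.full(n_theta, i0), (first + 1) % n_theta, first])
        cap1 = np.column_stack(
            [np.full(n_theta, i1), last, (n_sec - 1) * n_theta + (np.arange(n_theta) + 1) % n_theta]
        )
        faces = np.vstack([faces, cap0, cap1])

    surf = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if capped and surf.volume < 0:
        surf.invert()
    geom.surface = surf

    if plaque_spec is not None:
        th = geom.wall_thickening(plaque_spec.center_arclength, theta)
        if th.min() >= 0.5 * th.max():
            raise ValueError("plaque violates the eccentric-thickening rule")
    return geom


@dataclass
class VoxelGrid:
    """Axis-aligned voxel image with spacing/origin metadata (mm).

    ``origin`` is the world coordinate of the center of voxel (0,0,0);
    world = origin + index * spacing.
    """

    shape: tuple
    spacing: np.ndarray   # (3,) mm: in-plane x, in-plane y, slice z
    origin: np.ndarray    # (3,) mm
    values: np.ndarray

    def __post_init__(self):
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.shape = tuple(int(k) for k in self.shape)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing components must be positive")
        if any(k < 1 for k in self.shape):
            raise ValueError("shape components must be >= 1")
        if tuple(self.values.shape) != self.shape:
            raise ValueError("values shape does not match grid shape")

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[:3, :3] = np.diag(self.spacing)
        a[:3, 3] = self.origin
        return a

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def write_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.values.astype(np.float32), self.affine), str(path))

    @classmethod
    def from_nifti(cls, path) -> "VoxelGrid":
        import nibabel as nib

        img = nib.load(str(path))
        aff = img.affine
        vals = np.asarray(img.dataobj)
        return cls(vals.shape, np.diag(aff)[:3], aff[:3, 3], vals)


# In-plane display resolution and slice thickness of vessel-wall MRI the
# phantom emulates (mm).
HRMRI_SPACING_MM = (0.4, 0.4, 0.8)


def make_image_phantom(
    vessel: VesselGeometry,
    spacing_mm: Sequence[float] = HRMRI_SPACING_MM,
    margin_mm: float = 1.0,
    origin_mm: Sequence[float] | None = None,
    shape: Sequence[int] | None = None,
) -> VoxelGrid:
    """Binary lumen mask on an HR-MRI-like voxel grid.

    A voxel is 1 iff its center lies inside the lumen surface (evaluated
    against the parametric radius function, so plaques are honored).  By
    default the grid is sized to contain the vessel plus ``margin_mm``; if an
    explicit origin/shape is given the vessel must fit inside it.
    """
    spacing = np.asarray(spacing_mm, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    bounds_mm = vessel.surface.bounds * MM_PER_M  # (2, 3)
    if origin_mm is None:
        origin = bounds_mm[0] - margin_mm
    else:
        origin = np.asarray(origin_mm, dtype=float)
    if shape is None:
        shape = tuple(
            int(np.ceil((bounds_mm[1][k] + margin_mm - origin[k]) / spacing[k])) + 1
            for k in range(3)
        )
    else:
        shape = tuple(int(k) for k in shape)
    far = origin + (np.array(shape) - 1) * spacing
    if np.any(bounds_mm[0] < origin - spacing / 2) or np.any(bounds_mm[1] > far + spacing / 2):
        raise ValueError("vessel is not contained in the requested grid extent")

    idx = np.indices(shape).reshape(3, -1).T
    centers_m = (origin + idx * spacing) / MM_PER_M

    cl = vessel.centerline
    n_fine = max(len(cl.points), int(np.ceil(cl.length / (0.5 * spacing.min() / MM_PER_M))) + 1)
    fine = cl.resample(n_fine)
    from scipy.spatial import cKDTree

    _, near = cKDTree(fine.points).query(centers_m)
    d = centers_m - fine.points[near]
    ax = np.sum(d * fine.tangents[near], axis=1)
    s = fine.arclengths[near] + ax
    radial = d - ax[:, None] * fine.tangents[near]
    r = np.linalg.norm(radial, axis=1)
    theta = np.arctan2(
        np.sum(radial * fine.binormals[near], axis=1),
        np.sum(radial * fine.normals[near], axis=1),
    )
    in_span = (s >= fine.arclengths[0]) & (s <= fine.arclengths[-1])
    inside = in_span & (r <= vessel.local_radius(np.clip(s, 0, fine.arclengths[-1]), theta))
    values = inside.reshape(shape).astype(np.uint8)
    return VoxelGrid(shape, spacing, origin, values)


@dataclass
class UltrasoundMeasurement:
    """Per-artery duplex ultrasound reading used to set the inflow."""

    artery_id: str
    v_systole: float   # peak systolic velocity, m/s
    v_diastole: float  # diastolic velocity, m/s
    r: float           # lumen radius, m

    def __post_init__(self):
        if not (self.v_systole >= self.v_diastole >= 0):
            raise ValueError("need v_systole >= v_diastole >= 0")
        if self.r <= 0:
            raise ValueError("radius must be positive")


_ARTERY_NAMES = ["carotid_left", "carotid_right", "vertebral_left", "vertebral_right"]

# physiologically plausible ranges for cervical inflow arteries
V_SYSTOLE_RANGE = (0.6, 1.2)    # m/s
V_DIASTOLE_RANGE = (0.2, 0.6)   # m/s
RADIUS_RANGE = (1.5e-3, 3.5e-3)  # m
PRESSURE_RANGE_MMHG = (80.0, 120.0)


def make_ultrasound_panel(n_arteries: int, seed: int):
    """Draw a synthetic ultrasound panel and brachial pressure (Pa).

    Velocities, radii and pressure are uniform over the documented
    physiological ranges; ``v_systole >= v_diastole`` holds by construction.
    """
    if n_arteries < 1:
        raise ValueError("n_arteries must be >= 1")
    rng = np.random.default_rng(seed)
    panel = []
    for k in range(n_arteries):
        name = _ARTERY_NAMES[k] if k < len(_ARTERY_NAMES) else f"artery_{k}"
        v_dia = rng.uniform(*V_DIASTOLE_RANGE)
        v_sys = rng.uniform(*V_SYSTOLE_RANGE)
        r = rng.uniform(*RADIUS_RANGE)
        panel.append(UltrasoundMeasurement(name, v_sys, v_dia, r))
    p_brachial_pa = mmhg_to_pa(rng.uniform(*PRESSURE_RANGE_MMHG))
    return panel, p_brachial_pa


PANEL_COLUMNS = ["artery_id", "v_systole_m_s", "v_diastole_m_s", "radius_m"]


def write_panel_csv(path, panel: Sequence[UltrasoundMeasurement], p_brachial_pa: float) -> None:
    df = pd.DataFrame(
        [(m.artery_id, m.v_systole, m.v_diastole, m.r) for m in panel],
        columns=PANEL_COLUMNS,
    )
    df.to_csv(path, index=False)
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump({"p_brachial_pa": p_brachial_pa}, fh)


def read_panel_csv(path):
    df = pd.read_csv(path)
    panel = [
        UltrasoundMeasurement(row.artery_id, row.v_systole_m_s, row.v_diastole_m_s, row.radius_m)
        for row in df.itertuples()
    ]
    with open(str(path) + ".json") as fh:
        p = json.load(fh)["p_brachial_pa"]
    return panel, p
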