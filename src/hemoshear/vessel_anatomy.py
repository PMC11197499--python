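"""Anatomical partitions of the vessel wall.

Walls are labeled along three independent axes, mirroring how vessel-wall
imaging studies read the M1 segment of the middle cerebral artery:

* segment — the span between an origin and a branch point is trisected by
  arclength into proximal / middle / distal;
* quadrant — ventral (anterior), dorsal (posterior), superior, inferior,
  assigned from the angular position of each wall face around the local
  centerline using 45° sectors about declared anatomical axes;
* curve side — inner or outer wall of the vessel curve, from the sign of
  the face offset along the local curvature direction; undefined where the
  centerline is locally straight.

Plaque annotations (2–5 image points) are assigned to the wall and segment
of the wall face nearest their centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .meshing import VolumeMesh
from .synthetic_vessels import ANTERIOR, SUPERIOR, Centerline

SEGMENT_NAMES = ("proximal", "middle", "distal")
QUADRANT_NAMES = ("ventral", "dorsal", "superior", "inferior")
CURVE_SIDE_NAMES = ("inner", "outer", "undefined")

SEGMENT_IDS = {name: i for i, name in enumerate(SEGMENT_NAMES)}
QUADRANT_IDS = {name: i for i, name in enumerate(QUADRANT_NAMES)}
CURVE_SIDE_IDS = {name: i for i, name in enumerate(CURVE_SIDE_NAMES)}

#: centerline curvature (1/m) below which inner/outer is undefined
CURVATURE_THRESHOLD = 5.0


@dataclass
class OrientationConvention:
    """Anatomical axes of the dataset (unit vectors in world coordinates)."""

    anterior: np.ndarray = field(default_factory=lambda: ANTERIOR.copy())
    superior: np.ndarray = field(default_factory=lambda: SUPERIOR.copy())

    def __post_init__(self):
        self.anterior = np.asarray(self.anterior, dtype=float)
        self.superior = np.asarray(self.superior, dtype=float)
        for v in (self.anterior, self.superior):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError("orientation axes must be unit vectors")

    def rotated(self, R: np.ndarray) -> "OrientationConvention":
        return OrientationConvention(R @ self.anterior, R @ self.superior)


@dataclass
class WallRegionLabels:
    """Per-wall-face segment / quadrant / curve-side label arrays."""

    face_ids: np.ndarray     # indices into mesh.boundary_faces
    segment: np.ndarray      # ints per SEGMENT_IDS
    quadrant: np.ndarray     # ints per QUADRANT_IDS
    curve_side: np.ndarray   # ints per CURVE_SIDE_IDS

    def __post_init__(self):
        for arr, names in ((self.segment, SEGMENT_NAMES), (self.quadrant, QUADRANT_NAMES),
                           (self.curve_side, CURVE_SIDE_NAMES)):
            if arr.shape != self.face_ids.shape:
                raise ValueError("label arrays must match face_ids")
            if np.any(arr < 0) or np.any(arr >= len(names)):
                raise ValueError("label out of range")

    def segment_mask(self, name: str) -> np.ndarray:
        return self.segment == SEGMENT_IDS[name]

    def quadrant_mask(self, *names: str) -> np.ndarray:
        ids = [QUADRANT_IDS[n] for n in names]
        return np.isin(self.quadrant, ids)

    def curve_side_mask(self, name: str) -> np.ndarray:
        return self.curve_side == CURVE_SIDE_IDS[name]

    def legend(self) -> dict:
        return {"segment_id": SEGMENT_IDS, "quadrant_id": QUADRANT_IDS,
                "curve_side_id": CURVE_SIDE_IDS}


class _CenterlineSampler:
    """Nearest-point queries against a densely resampled centerline."""

    def __init__(self, centerline: Centerline, n: int = 400):
        self.fine = centerline.resample(max(n, len(centerline.points)))
        self.tree = cKDTree(self.fine.points)
        self.kappa = self.fine.curvature_vectors()

    def nearest(self, points: np.ndarray):
        _, idx = self.tree.query(points)
        return idx

    def arclength(self, points: np.ndarray) -> np.ndarray:
        idx = self.nearest(points)
        d = points - self.fine.points[idx]
        return self.fine.arclengths[idx] + np.sum(d * self.fine.tangents[idx], axis=1)

    def radial_offsets(self, points: np.ndarray):
        idx = self.nearest(points)
        d = points - self.fine.points[idx]
        t = self.fine.tangents[idx]
        return idx, d - np.sum(d * t, axis=1)[:, None] * t


def trisect(
    centerline: Centerline,
    origin_arclength: float = 0.0,
    branch_arclength: float | None = None,
    mesh: VolumeMesh | None = None,
):
    """Equal-thirds cuts of the origin→branch span; optionally label faces.

    Returns ``(cut1, cut2)`` or ``(cut1, cut2, segment_labels)`` when a mesh
    is supplied (faces labeled by the arclength of their centroid's nearest
    centerline point; spans before/after the cuts map to proximal/distal).
    """
    if branch_arclength is None:
        branch_arclength = float(centerline.arclengths[-1])
    span = branch_arclength - origin_arclength
    if span <= 0:
        raise ValueError("branch point must lie beyond the origin")
    cut1 = origin_arclength + span / 3.0
    cut2 = origin_arclength + 2.0 * span / 3.0
    if mesh is None:
        return cut1, cut2
    sampler = _CenterlineSampler(centerline)
    s = sampler.arclength(mesh.face_centroids()[mesh.wall_faces])
    labels = np.where(s < cut1, SEGMENT_IDS["proximal"],
                      np.where(s < cut2, SEGMENT_IDS["middle"], SEGMENT_IDS["distal"]))
    return cut1, cut2, labels


def classify_quadrant(
    mesh: VolumeMesh,
    centerline: Centerline,
    convention: OrientationConvention | None = None,
) -> np.ndarray:
    """Quadrant id per wall face by dominant angular component.

    The anatomical axes are projected into the plane normal to the local
    centerline tangent; a face goes to ventral/dorsal when its radial offset
    aligns more with ±anterior than ±superior (45° sectors), else to
    superior/inferior.
    """
    if convention is None:
        raise ValueError("an orientation convention must be declared")
    sampler = _CenterlineSampler(centerline)
    cent = mesh.face_centroids()[mesh.wall_faces]
    idx, radial = sampler.radial_offsets(cent)
    t = sampler.fine.tangents[idx]

    def proj(axis):
        ax = np.broadcast_to(axis, t.shape) - np.sum(axis * t, axis=1)[:, None] * t
        n = np.linalg.norm(ax, axis=1)
        if np.any(n < 1e-9):
            raise ValueError("anatomical axis parallel to the vessel tangent")
        return ax / n[:, None]

    ca = np.sum(radial * proj(convention.anterior), axis=1)
    cs = np.sum(radial * proj(convention.superior), axis=1)
    vd = np.where(ca > 0, QUADRANT_IDS["ventral"], QUADRANT_IDS["dorsal"])
    si = np.where(cs > 0, QUADRANT_IDS["superior"], QUADRANT_IDS["inferior"])
    return np.where(np.abs(ca) >= np.abs(cs), vd, si)


def classify_curve_side(
    mesh: VolumeMesh,
    centerline: Centerline,
    curvature_threshold: float = CURVATURE_THRESHOLD,
) -> np.ndarray:
    """Inner/outer-curve id per wall face (undefined on straight spans).

    A face is *inner* when its radial offset points toward the local center
    of curvature, i.e. along the curvature vector dT/ds.
    """
    sampler = _CenterlineSampler(centerline)
    cent = mesh.face_centroids()[mesh.wall_faces]
    idx, radial = sampler.radial_offsets(cent)
    kappa = sampler.kappa[idx]
    kmag = np.linalg.norm(kappa, axis=1)
    side = np.where(np.sum(radial * kappa, axis=1) > 0,
                    CURVE_SIDE_IDS["inner"], CURVE_SIDE_IDS["outer"])
    return np.where(kmag < curvature_threshold, CURVE_SIDE_IDS["undefined"], side)


def label_walls(
    mesh: VolumeMesh,
    centerline: Centerline,
    convention: OrientationConvention | None = None,
    origin_arclength: float = 0.0,
    branch_arclength: float | None = None,
    curvature_threshold: float = CURVATURE_THRESHOLD,
) -> WallRegionLabels:
    """All three label axes for every wall face of the mesh."""
    convention = convention or OrientationConvention()
    _, _, segment = trisect(centerline, origin_arclength, branch_arclength, mesh)
    quadrant = classify_quadrant(mesh, centerline, convention)
    curve_side = classify_curve_side(mesh, centerline, curvature_threshold)
    return WallRegionLabels(mesh.wall_faces.copy(), segment, quadrant, curve_side)


@dataclass
class PlaqueAnnotation:
    """2–5 world-coordinate points (m) marking one plaque on the images."""

    points: np.ndarray
    plaque_id: str = "plaque"

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if not (2 <= len(self.points) <= 5):
            raise ValueError("a plaque is determined by 2-5 points")

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def assign_plaque(
    annotation: PlaqueAnnotation,
    labels: WallRegionLabels,
    mesh: VolumeMesh,
    max_distance: float | None = None,
):
    """Snap the annotation centroid to the nearest wall face; return labels.

    Returns ``(wall_name, segment_name)``.  The centroid must lie within
    ``max_distance`` of the wall (default: one local vessel diameter,
    estimated from the wall geometry).
    """
    cent = annotation.centroid()
    wall_centroids = mesh.face_centroids()[labels.face_ids]
    d, i = cKDTree(wall_centroids).query(cent)
    if max_distance is None:
        # local diameter estimate: twice the median offset of wall faces
        # from their mutual centroid within the nearest cross-section
        near = np.linalg.norm(wall_centroids - wall_centroids[i], axis=1)
        ring = wall_centroids[near < np.percentile(near, 5)]
        max_distance = 2.0 * np.median(np.linalg.norm(ring - ring.mean(axis=0), axis=1)) + 1e-12
    if d > max_distance:
        raise ValueError(
            f"annotation centroid is {d:.3g} m from the wall (limit {max_distance:.3g} m)"
        )
    return QUADRANT_NAMES[labels.quadrant[i]], SEGMENT_NAMES[labels.segment[i]]


def read_plaque_annotations_csv(path):
    """CSV columns plaque_id,x_mm,y_mm,z_mm → list of annotations (m)."""
    import pandas as pd

    from .units import mm_to_m

    df = pd.read_csv(path)
    out = []
    for pid, grp in df.groupby("plaque_id", sort=False):
        pts = mm_to_m(grp[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float))
        out.append(PlaqueAnnotation(pts, str(pid)))
    return out
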