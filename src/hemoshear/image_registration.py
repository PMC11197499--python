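"""Mapping between model coordinates and image voxel indices.

The flow model and the voxel images share one world coordinate frame; the
projection between them is purely metric — voxel indices follow from the
in-plane resolution and slice thickness.  Conventions fixed here (and
stored with every transform): 0-based indices, voxel-center alignment,
nearest-neighbor rounding, axis order (in-plane x, in-plane y, slice z).
Transforms work in mm; mesh coordinates are SI meters and converted at the
call boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .meshing import VolumeMesh
from .synthetic_vessels import VoxelGrid
from .units import MM_PER_M
from .wall_shear import WSSField


@dataclass
class GridTransform:
    """Voxel-grid geometry: spacing (mm), world origin of voxel (0,0,0) (mm)."""

    spacing: np.ndarray
    origin: np.ndarray
    axis_signs: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self):
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.axis_signs = np.asarray(self.axis_signs, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")
        if not np.all(np.isin(self.axis_signs, (-1.0, 1.0))):
            raise ValueError("axis signs must be ±1")

    @property
    def step(self) -> np.ndarray:
        return self.spacing * self.axis_signs

    @classmethod
    def from_grid(cls, grid: VoxelGrid) -> "GridTransform":
        return cls(grid.spacing, grid.origin)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"spacing_mm": self.spacing.tolist(),
                       "origin_mm": self.origin.tolist(),
                       "axis_signs": self.axis_signs.tolist(),
                       "convention": "0-based, voxel-center, nearest-neighbor"}, fh)

    @classmethod
    def from_json(cls, path) -> "GridTransform":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["spacing_mm"], d["origin_mm"], d["axis_signs"])


def world_to_voxel(coords_mm, t: GridTransform, shape=None):
    """Nearest-voxel indices for world points (mm).

    index = floor((coord − origin)/step + 1/2).  With ``shape`` given, a
    boolean in-bounds flag per point is returned alongside the indices
    (out-of-range points are flagged, not raised).
    """
    coords = np.atleast_2d(np.asarray(coords_mm, dtype=float))
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    idx = np.floor((coords - t.origin) / t.step + 0.5).astype(int)
    single = np.asarray(coords_mm).ndim == 1
    if shape is None:
        return idx[0] if single else idx
    inb = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    return (idx[0], bool(inb[0])) if single else (idx, inb)


def voxel_to_world(indices, t: GridTransform):
    """World coordinate (mm) of the voxel center(s)."""
    idx = np.atleast_2d(np.asarray(indices))
    out = t.origin + idx * t.step
    return out[0] if np.asarray(indices).ndim == 1 else out


def locate_point_on_model(voxel_idx, t: GridTransform, mesh: VolumeMesh,
                          face_ids: np.ndarray | None = None):
    """Nearest wall face to a voxel center; returns (face index, distance m).

    Distance ties resolve to the lowest face index.
    """
    if face_ids is None:
        face_ids = mesh.wall_faces
    world_m = voxel_to_world(np.asarray(voxel_idx), t) / MM_PER_M
    centroids = mesh.face_centroids()[face_ids]
    tree = cKDTree(centroids)
    k = min(4, len(face_ids))
    d, i = tree.query(world_m, k=k)
    d, i = np.atleast_1d(d), np.atleast_1d(i)
    tied = np.flatnonzero(d <= d[0] * (1 + 1e-12))
    best = int(np.min(i[tied]))
    return int(face_ids[best]), float(d[0])


def project_wss_to_image(field: WSSField, t: GridTransform, shape):
    """Deposit WSS magnitudes onto the voxel grid.

    Each wall face lands in the voxel containing its centroid; voxels hit by
    several faces take the area-weighted mean.  Returns (wss grid, validity
    mask grid) — empty voxels are 0 with mask 0.
    """
    shape = tuple(int(k) for k in shape)
    cent_mm = field.face_centroids * MM_PER_M
    idx, inb = world_to_voxel(cent_mm, t, shape)
    idx = idx[inb]
    w = field.wss_magnitude[inb]
    a = field.face_areas[inb]
    flat = np.ravel_multi_index(tuple(idx.T), shape)
    num = np.bincount(flat, weights=a * w, minlength=int(np.prod(shape)))
    den = np.bincount(flat, weights=a, minlength=int(np.prod(shape)))
    vals = np.zeros_like(num)
    hit = den > 0
    vals[hit] = num[hit] / den[hit]
    grid = VoxelGrid(shape, t.spacing, t.origin, vals.reshape(shape))
    mask = VoxelGrid(shape, t.spacing, t.origin, hit.reshape(shape).astype(np.uint8))
    return grid, mask
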