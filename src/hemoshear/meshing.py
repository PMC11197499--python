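"""Labeled tetrahedral volume meshes for tube lumens.

The mesher sweeps a graded polar disk template along the vessel centerline
and splits the resulting triangular prisms into tetrahedra with the
minimum-global-index diagonal rule, which keeps shared quad faces conforming.
This structured approach is deterministic and dependency-light and is
adequate for tube topologies; it replaces general-purpose unstructured
tetrahedral meshing of arbitrary segmented surfaces, with the same near-wall
size reduction (thin first cell layer at the wall, where shear must be
resolved).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import vtkio
from .synthetic_vessels import VesselGeometry

#: boundary label legend; outlets number upward from 2
BOUNDARY_WALL = 0
BOUNDARY_INLET = 1
BOUNDARY_OUTLET = 2

#: cells smaller than this (m^3) are flagged by mesh_quality; 1.0e-8 cm^3
MIN_CELL_VOLUME_M3 = 1.0e-14


class MeshingError(RuntimeError):
    pass


@dataclass
class VolumeMesh:
    """Tetrahedral mesh with labeled boundary triangles and outward normals."""

    nodes: np.ndarray            # (n, 3) m
    tets: np.ndarray             # (m, 4) int, positively oriented
    boundary_faces: np.ndarray   # (f, 3) int
    boundary_labels: np.ndarray  # (f,) int, see legend
    face_normals: np.ndarray = field(default=None)  # (f, 3) outward unit
    face_areas: np.ndarray = field(default=None)    # (f,)
    face_owner_tets: np.ndarray = field(default=None)  # (f,) int

    def __post_init__(self):
        if self.face_normals is None:
            self._compute_face_geometry()

    # -- derived geometry -------------------------------------------------

    def tet_volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        e = x[:, 1:] - x[:, :1]
        return np.linalg.det(e) / 6.0

    def total_volume(self) -> float:
        return float(np.sum(self.tet_volumes()))

    def face_centroids(self) -> np.ndarray:
        return self.nodes[self.boundary_faces].mean(axis=1)

    def _compute_face_geometry(self):
        tri = self.nodes[self.boundary_faces]
        cr = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        areas = 0.5 * np.linalg.norm(cr, axis=1)
        normals = cr / (2.0 * areas[:, None])
        if self.face_owner_tets is None:
            self.face_owner_tets = _find_owner_tets(self.tets, self.boundary_faces)
        # orient outward: away from the owning tet's centroid
        tet_cent = self.nodes[self.tets[self.face_owner_tets]].mean(axis=1)
        face_cent = tri.mean(axis=1)
        flip = np.sum(normals * (face_cent - tet_cent), axis=1) < 0
        normals[flip] *= -1.0
        self.face_normals = normals
        self.face_areas = areas

    def divergence_identity_residual(self) -> float:
        """|∮ x·n dA − 3V| / 3V — closure + outward-normal validation."""
        cent = self.face_centroids()
        flux = np.sum(self.face_areas * np.sum(cent * self.face_normals, axis=1))
        vol3 = 3.0 * self.total_volume()
        return abs(flux - vol3) / vol3

    def faces_with_label(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.boundary_labels == label)

    @property
    def wall_faces(self) -> np.ndarray:
        return self.faces_with_label(BOUNDARY_WALL)

    # -- I/O ---------------------------------------------------------------

    def write_vtu(self, path) -> None:
        vtkio.write_vtu(path, self.nodes, self.tets, vtkio.VTK_TETRA)
        # boundary surface as a sidecar with the label array and legend
        bpath = str(path).replace(".vtu", "") + "_boundary.vtu"
        vtkio.write_vtu(
            bpath,
            self.nodes,
            self.boundary_faces,
            vtkio.VTK_TRIANGLE,
            cell_data={"boundary_id": self.boundary_labels.astype(np.int64)},
        )
        with open(str(path) + ".legend.json", "w") as fh:
            json.dump({"wall": BOUNDARY_WALL, "inlet": BOUNDARY_INLET,
                       "outlet_0": BOUNDARY_OUTLET}, fh)

    @classmethod
    def read_vtu(cls, path) -> "VolumeMesh":
        nodes, tets, ctype, _, _ = vtkio.read_vtu(path)
        if ctype != vtkio.VTK_TETRA:
            raise MeshingError("expected a tetrahedral VTU")
        bpath = str(path).replace(".vtu", "") + "_boundary.vtu"
        _, faces, _, _, cdata = vtkio.read_vtu(bpath)
        labels = cdata["boundary_id"].astype(int).ravel()
        return cls(nodes, tets.astype(int), faces.astype(int), labels)


def _face_codes(faces: np.ndarray, n_nodes: int) -> np.ndarray:
    """Order-independent int64 code per triangle (valid for n_nodes < 2^21)."""
    key = np.sort(faces.astype(np.int64), axis=1)
    n = np.int64(n_nodes)
    return (key[:, 0] * n + key[:, 1]) * n + key[:, 2]


def _tet_face_table(tets: np.ndarray):
    faces = np.concatenate(
        [tets[:, [1, 2, 3]], tets[:, [0, 3, 2]], tets[:, [0, 1, 3]], tets[:, [0, 2, 1]]]
    )
    owner = np.tile(np.arange(len(tets)), 4)
    return faces, owner


def _find_owner_tets(tets: np.ndarray, faces: np.ndarray) -> np.ndarray:
    n_nodes = int(max(tets.max(), faces.max())) + 1
    tet_faces, owner = _tet_face_table(tets)
    codes = _face_codes(tet_faces, n_nodes)
    order = np.argsort(codes)
    idx = np.searchsorted(codes[order], _face_codes(faces, n_nodes))
    return owner[order[idx]]


def _extract_boundary_faces(tets: np.ndarray):
    n_nodes = int(tets.max()) + 1
    faces, _ = _tet_face_table(tets)
    codes = _face_codes(faces, n_nodes)
    _, first, counts = np.unique(codes, return_index=True, return_counts=True)
    if counts.max() > 2:
        raise MeshingError("non-manifold mesh: a face is shared by >2 cells")
    return faces[first[counts == 1]]


# rotations of a prism (bottom 0,1,2 / top 3,4,5) that preserve orientation
_PRISM_ROTATIONS = np.array(
    [
        [0, 1, 2, 3, 4, 5],
        [1, 2, 0, 4, 5, 3],
        [2, 0, 1, 5, 3, 4],
        [3, 5, 4, 0, 2, 1],
        [4, 3, 5, 1, 0, 2],
        [5, 4, 3, 2, 1, 0],
    ]
)


def split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split each 6-node prism into 3 tets with the min-index diagonal rule.

    Adjacent prisms sharing a quad face pick the same diagonal (the one
    through the smallest global node index), so the result is conforming.
    """
    prisms = np.asarray(prisms)
    rot = np.argmin(prisms, axis=1)
    p = np.take_along_axis(prisms, _PRISM_ROTATIONS[rot], axis=1)
    case_a = np.minimum(p[:, 1], p[:, 5]) < np.minimum(p[:, 2], p[:, 4])
    tets = np.empty((len(p), 3, 4), dtype=prisms.dtype)
    a = p[case_a]
    tets[case_a, 0] = a[:, [0, 1, 2, 5]]
    tets[case_a, 1] = a[:, [0, 1, 5, 4]]
    tets[case_a, 2] = a[:, [0, 4, 5, 3]]
    b = p[~case_a]
    tets[~case_a, 0] = b[:, [0, 1, 2, 4]]
    tets[~case_a, 1] = b[:, [0, 4, 2, 5]]
    tets[~case_a, 2] = b[:, [0, 4, 5, 3]]
    return tets.reshape(-1, 4)


def _radial_fractions(radius: float, target_edge: float, near_wall_factor: float):
    """Ring radii fractions in (0, 1], graded so the wall layer is thin."""
    t = near_wall_factor * target_edge
    thick = [min(t, 0.8 * radius)]
    while sum(thick) < radius:
        t = min(target_edge, 1.5 * t)
        thick.append(t)
    # absorb the overshoot into the innermost layer
    thick[-1] -= sum(thick) - radius
    if thick[-1] < 0.25 * target_edge and len(thick) > 1:
        thick[-2] += thick[-1]
        thick.pop()
    radii = radius - np.cumsum(thick)  # wall inward
    fractions = np.sort(np.clip(radii[radii > 1e-12], 0, None)) / radius
    return np.concatenate([fractions, [1.0]])


def _disk_template(n_theta: int, fractions: np.ndarray):
    """Triangulate the unit disk: center node + rings at the given fractions."""
    n_r = len(fractions)
    tris = []
    ring0 = 1 + np.arange(n_theta)
    nxt = (np.arange(n_theta) + 1) % n_theta
    tris.append(np.column_stack([np.zeros(n_theta, dtype=int), ring0, 1 + nxt]))
    for k in range(n_r - 1):
        a = 1 + k * n_theta + np.arange(n_theta)
        b = 1 + k * n_theta + nxt
        c = a + n_theta
        d = b + n_theta
        tris.append(np.column_stack([a, b, d]))
        tris.append(np.column_stack([a, d, c]))
    return np.concatenate(tris), 1 + n_r * n_theta  # (triangles, nodes per section)


def tetrahedralize(
    vessel: VesselGeometry,
    target_edge: float,
    near_wall_factor: float = 0.3,
    n_theta: int | None = None,
) -> VolumeMesh:
    """Fill the lumen with tetrahedra, refined toward the wall.

    target_edge
        nominal cell edge (m) in the interior; the angular and axial node
        spacings track it and the wall-adjacent radial layer is
        ``near_wall_factor`` times thinner.
    """
    if target_edge <= 0:
        raise MeshingError("target_edge must be positive")
    if not (0 < near_wall_factor <= 1):
        raise MeshingError("near_wall_factor must lie in (0, 1]")
    cl = vessel.centerline
    r_mean = float(np.mean(vessel.radius_profile))
    if n_theta is None:
        n_theta = int(4 * max(2, round(2 * np.pi * r_mean / target_edge / 4)))
    n_z = max(4, int(round(cl.length / target_edge)))
    fine = cl.resample(n_z + 1)
    fractions = _radial_fractions(r_mean, target_edge, near_wall_factor)
    tris, m = _disk_template(n_theta, fractions)

    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    rr = vessel.local_radius(fine.arclengths[:, None], theta[None, :])  # (n_z+1, n_theta)
    if np.any(~np.isfinite(rr)) or np.any(rr <= 0):
        raise MeshingError("degenerate geometry: non-positive local radius")
    sections = np.empty((n_z + 1, m, 3))
    sections[:, 0, :] = fine.points
    dirs = (
        np.cos(theta)[None, :, None] * fine.normals[:, None, :]
        + np.sin(theta)[None, :, None] * fine.binormals[:, None, :]
    )  # (n_z+1, n_theta, 3)
    for k, f in enumerate(fractions):
        sections[:, 1 + k * n_theta : 1 + (k + 1) * n_theta, :] = (
            fine.points[:, None, :] + f * rr[:, :, None] * dirs
        )
    nodes = sections.reshape(-1, 3)

    slabs = np.arange(n_z)[:, None, None] * m
    prisms = np.concatenate(
        [tris[None, :, :] + slabs, tris[None, :, :] + slabs + m], axis=2
    ).reshape(-1, 6)
    tets = split_prisms(prisms)

    vols = np.linalg.det(nodes[tets][:, 1:] - nodes[tets][:, :1]) / 6.0
    neg = vols < 0
    tets[neg] = tets[neg][:, [0, 2, 1, 3]]
    vols = np.abs(vols)
    if vols.min() <= 0:
        raise MeshingError("meshing produced a degenerate (zero-volume) cell")

    faces = _extract_boundary_faces(tets)
    mesh = VolumeMesh(nodes, tets, faces, np.full(len(faces), BOUNDARY_WALL))
    return tag_boundaries(mesh, vessel)


def tag_boundaries(mesh: VolumeMesh, vessel: VesselGeometry) -> VolumeMesh:
    """Label planar end caps as inlet/outlet (flow enters at arclength 0)."""
    cl = vessel.centerline
    cent = mesh.face_centroids()
    labels = np.full(len(mesh.boundary_faces), BOUNDARY_WALL)
    scale = max(np.mean(vessel.radius_profile), 1e-9)
    for plane_pt, plane_n, lab in (
        (cl.points[0], cl.tangents[0], BOUNDARY_INLET),
        (cl.points[-1], cl.tangents[-1], BOUNDARY_OUTLET),
    ):
        verts = mesh.nodes[mesh.boundary_faces]  # (f, 3, 3)
        dist = np.abs((verts - plane_pt) @ plane_n)
        # the cap lies in the end plane up to the endpoint-tangent estimate;
        # wall faces are rejected by the normal-alignment test regardless
        on_plane = np.all(dist < 2e-2 * scale, axis=1)
        aligned = np.abs(mesh.face_normals @ plane_n) > 0.9
        labels[on_plane & aligned] = lab
    if not (np.any(labels == BOUNDARY_INLET) and np.any(labels == BOUNDARY_OUTLET)):
        raise MeshingError("cap detection failed: no inlet/outlet faces found")
    mesh.boundary_labels = labels
    return mesh


@dataclass
class MeshQualityReport:
    min_volume: float      # m^3
    max_aspect: float      # longest/shortest edge over cells
    n_cells: int
    n_below_min: int       # cells under the configured minimum volume
    mean_edge: float       # m

    def as_dict(self):
        return {
            "min_volume_m3": self.min_volume,
            "max_aspect": self.max_aspect,
            "n_cells": self.n_cells,
            "n_below_min_volume": self.n_below_min,
            "mean_edge_m": self.mean_edge,
        }


def mesh_quality(mesh: VolumeMesh, min_volume: float = MIN_CELL_VOLUME_M3) -> MeshQualityReport:
    if len(mesh.tets) == 0:
        raise MeshingError("no cells")
    vols = np.abs(mesh.tet_volumes())
    x = mesh.nodes[mesh.tets]
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    edges = np.stack([np.linalg.norm(x[:, i] - x[:, j], axis=1) for i, j in pairs], axis=1)
    aspect = edges.max(axis=1) / edges.min(axis=1)
    return MeshQualityReport(
        min_volume=float(vols.min()),
        max_aspect=float(aspect.max()),
        n_cells=len(mesh.tets),
        n_below_min=int(np.sum(vols < min_volume)),
        mean_edge=float(edges.mean()),
    )


def wall_adjacent_edge_ratio(mesh: VolumeMesh) -> float:
    """Local mesh size at the wall relative to the interior.

    For every wall node, take the shortest edge incident to it (the
    wall-normal layer thickness); its median over wall nodes, divided by the
    median edge length of the whole mesh, measures how much thinner the
    wall-adjacent layer is than the bulk resolution.  Medians keep the polar
    crowding at the tube axis (where circumferential edges shrink toward the
    centerline) from skewing the measure.
    """
    wall_nodes = np.zeros(len(mesh.nodes), dtype=bool)
    wall_nodes[np.unique(mesh.boundary_faces[mesh.wall_faces])] = True
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    shortest = np.full(len(mesh.nodes), np.inf)
    x = mesh.nodes[mesh.tets]
    all_lengths = []
    for i, j in pairs:
        ln = np.linalg.norm(x[:, i] - x[:, j], axis=1)
        all_lengths.append(ln)
        np.minimum.at(shortest, mesh.tets[:, i], ln)
        np.minimum.at(shortest, mesh.tets[:, j], ln)
    used = np.isfinite(shortest) & wall_nodes
    return float(np.median(shortest[used]) / np.median(np.concatenate(all_lengths)))
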