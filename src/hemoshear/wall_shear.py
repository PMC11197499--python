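"""Wall shear stress from the Cauchy stress at the vessel wall.

For incompressible Newtonian flow the Cauchy stress is
σ = −p·I + μ(∇v + ∇vᵀ).  On each wall boundary face the traction σ·n is
formed with the outward unit normal n, and the WSS is its tangential part

    WSS = σn − (σn·n)n,

whose magnitude (Pa) is the quantity averaged over wall regions.  Velocity
gradients are recovered per wall-adjacent element from the finite-element
basis (constant per P1 tet) and attributed to the owned face; face pressure
is the mean of the face's nodal values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hemodynamics import FlowSolution
from .meshing import BOUNDARY_WALL, VolumeMesh


@dataclass
class WSSField:
    """Per-wall-face stress state and tangential traction."""

    face_ids: np.ndarray        # indices into mesh.boundary_faces
    sigma: np.ndarray           # (f, 3, 3) Pa
    normals: np.ndarray         # (f, 3) outward unit
    wss_vectors: np.ndarray     # (f, 3) Pa, tangential
    wss_magnitude: np.ndarray   # (f,) Pa
    face_areas: np.ndarray      # (f,) m²
    face_centroids: np.ndarray  # (f, 3) m

    def __post_init__(self):
        tang = np.abs(np.sum(self.wss_vectors * self.normals, axis=1))
        scale = np.maximum(self.wss_magnitude, 1e-300)
        if np.any(tang > 1e-9 * scale + 1e-15):
            raise ValueError("WSS vectors must be tangential to the wall")

    def write_vtu(self, path, mesh: VolumeMesh) -> None:
        from . import vtkio

        faces = mesh.boundary_faces[self.face_ids]
        vtkio.write_vtu(
            path, mesh.nodes, faces, vtkio.VTK_TRIANGLE,
            cell_data={"wss_vector": self.wss_vectors,
                       "wss_magnitude": self.wss_magnitude},
        )


def cauchy_stress_at_wall(
    sol: FlowSolution, mesh: VolumeMesh, mu: float, face_ids: np.ndarray | None = None
) -> np.ndarray:
    """σ = −p̄I + μ(∇v + ∇vᵀ) per wall face, from the owning element."""
    if face_ids is None:
        face_ids = mesh.wall_faces
    u = sol.final_velocity
    p = sol.final_pressure
    owners = mesh.face_owner_tets[face_ids]
    tets = mesh.tets[owners]
    X = mesh.nodes[tets]
    E = X[:, 1:] - X[:, :1]
    Ginv = np.linalg.inv(np.transpose(E, (0, 2, 1)))
    G = np.empty((len(tets), 4, 3))
    G[:, 1:, :] = Ginv
    G[:, 0, :] = -Ginv.sum(axis=1)
    grad_v = np.einsum("mic,mid->mcd", u[tets], G)       # ∂v_c/∂x_d
    p_face = p[mesh.boundary_faces[face_ids]].mean(axis=1)
    sigma = mu * (grad_v + np.transpose(grad_v, (0, 2, 1)))
    sigma -= p_face[:, None, None] * np.eye(3)
    return sigma


def wss_vector(sigma: np.ndarray, n: np.ndarray):
    """Tangential part of the traction σn; returns (vectors, magnitudes).

    Accepts a single (3,3)/(3,) pair or stacked arrays.  Non-unit normals
    are normalized with a warning.
    """
    sigma = np.asarray(sigma, dtype=float)
    n = np.asarray(n, dtype=float)
    single = sigma.ndim == 2
    if single:
        sigma, n = sigma[None], n[None]
    norms = np.linalg.norm(n, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-12):
        warnings.warn("non-unit wall normal; normalizing", stacklevel=2)
        n = n / norms[:, None]
    traction = np.einsum("mcd,md->mc", sigma, n)
    tang = traction - np.sum(traction * n, axis=1)[:, None] * n
    mag = np.linalg.norm(tang, axis=1)
    if single:
        return tang[0], float(mag[0])
    return tang, mag


def compute_wss(
    sol: FlowSolution,
    mesh: VolumeMesh,
    mu: float,
    exclude_cap_band: float | None = None,
) -> WSSField:
    """Full WSS field on the wall, optionally trimming faces near the caps.

    exclude_cap_band
        wall faces whose centroid lies within this distance (m) of an
        inlet/outlet face centroid are dropped — the cap boundary condition
        contaminates the local stress.  ``None`` picks twice the median
        wall edge length; pass 0 to keep everything.
    """
    face_ids = mesh.wall_faces
    centroids = mesh.face_centroids()
    if exclude_cap_band is None:
        tri = mesh.nodes[mesh.boundary_faces[face_ids]]
        edges = np.linalg.norm(tri - np.roll(tri, 1, axis=1), axis=2)
        exclude_cap_band = 2.0 * float(np.median(edges))
    if exclude_cap_band > 0:
        from scipy.spatial import cKDTree

        cap_ids = np.flatnonzero(mesh.boundary_labels != BOUNDARY_WALL)
        d, _ = cKDTree(centroids[cap_ids]).query(centroids[face_ids])
        face_ids = face_ids[d > exclude_cap_band]

    sigma = cauchy_stress_at_wall(sol, mesh, mu, face_ids)
    n = mesh.face_normals[face_ids]
    vec, mag = wss_vector(sigma, n)
    return WSSField(
        face_ids=face_ids,
        sigma=sigma,
        normals=n,
        wss_vectors=vec,
        wss_magnitude=mag,
        face_areas=mesh.face_areas[face_ids],
        face_centroids=centroids[face_ids],
    )


def regional_mean_wss(field: WSSField, region: np.ndarray, weighting: str = "area") -> float:
    """Mean WSS magnitude (Pa) over a boolean face mask of the field."""
    region = np.asarray(region, dtype=bool)
    if region.shape != field.wss_magnitude.shape:
        raise ValueError("region mask must match the field's face count")
    if not np.any(region):
        raise ValueError("empty region")
    if weighting == "area":
        return float(np.average(field.wss_magnitude[region], weights=field.face_areas[region]))
    if weighting == "uniform":
        return float(np.mean(field.wss_magnitude[region]))
    raise ValueError(f"unknown weighting {weighting!r}")


def poiseuille_wall_shear(mu: float, q: float, r: float) -> float:
    """Analytic wall shear 4μQ/(πr³) of fully developed tube flow."""
    return 4.0 * mu * q / (np.pi * r**3)
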