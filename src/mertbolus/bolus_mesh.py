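"""Convert the final thickness map into a watertight printable solid.

The inner surface samples the patient (BODY) entry point along every grid
ray; the outer surface is displaced from it toward the source along the same
diverging ray by the local thickness, consistent with the ray-line definition
of bolus thickness used by the design. A vertical skirt around the grid
boundary closes the solid. The mesh resolution equals the SBT grid resolution
(optional 2x supersampling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh
import yaml
from scipy.ndimage import map_coordinates

from .beam_geometry import BeamSpec, SBTPlane, project_to_plane, ray_directions
from .errors import GeometryError, SpecError
from .io_formats import CTVolume
from .surface_model import entry_distance_map

log = logging.getLogger(__name__)

#: Thickness floor (mm) applied over the meshed domain so the closed solid has
#: no degenerate (zero-volume) sheets; far below any printable layer height.
MIN_THICKNESS_MM = 0.05

#: CT number assigned to the voxelized bolus for dose recomputation.
BOLUS_HU_OVERRIDE = 160

PRINT_PROFILES = {"low": 0.3, "standard": 0.2, "high": 0.1}  # layer height mm


@dataclass
class BolusSolid:
    """Watertight triangulated bolus between patient surface and outer shell.

    Keeps the generating maps (per-ray source distance of the inner surface
    and the effective thickness) so voxelization can reuse the exact ray
    geometry of the design.
    """

    mesh: trimesh.Trimesh
    beam: BeamSpec
    plane: SBTPlane
    entry_map: np.ndarray
    thickness_map: np.ndarray
    footprint: tuple[int, int, int, int] = (0, 0, 0, 0)  # i0, i1, j0, j1

    @property
    def is_watertight(self) -> bool:
        return bool(self.mesh.is_watertight)

    @property
    def volume_mm3(self) -> float:
        return float(abs(self.mesh.volume))

    def measure_thickness(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """Ray-cast the mesh along grid rays (i, j): distance between the
        first and last hit, i.e. the as-built thickness along each ray."""
        dirs = ray_directions(self.beam, self.plane)
        i = np.atleast_1d(i)
        j = np.atleast_1d(j)
        out = np.full(len(i), np.nan)
        tri = self.mesh.triangles
        for k in range(len(i)):
            hits = _ray_triangle_hits(self.beam.source, dirs[i[k], j[k]], tri)
            if len(hits) >= 2:
                out[k] = hits.max() - hits.min()
        return out


def _ray_triangle_hits(origin: np.ndarray, direction: np.ndarray,
                       triangles: np.ndarray) -> np.ndarray:
    """Distances of all ray-triangle intersections (Moller-Trumbore,
    vectorized over triangles)."""
    v0, v1, v2 = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(direction, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-12
    f = np.where(ok, 1.0 / np.where(ok, a, 1.0), 0.0)
    s = origin - v0
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * (q @ direction)
    t = f * np.einsum("ij,ij->i", q, e2)
    eps = 1e-9
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t > eps)
    return t[hit]


def _grid_faces(n: int, m: int, offset: int = 0, flip: bool = False
                ) -> np.ndarray:
    ii, jj = np.meshgrid(np.arange(n - 1), np.arange(m - 1), indexing="ij")
    v00 = (ii * m + jj).ravel() + offset
    v10 = ((ii + 1) * m + jj).ravel() + offset
    v01 = (ii * m + jj + 1).ravel() + offset
    v11 = ((ii + 1) * m + jj + 1).ravel() + offset
    f1 = np.column_stack([v00, v10, v11])
    f2 = np.column_stack([v00, v11, v01])
    faces = np.vstack([f1, f2])
    return faces[:, ::-1] if flip else faces


def _skirt_faces(n: int, m: int) -> np.ndarray:
    """Quads joining the inner grid (vertex ids [0, n*m)) to the outer grid
    (ids [n*m, 2*n*m)) around the boundary ring."""
    ring = []
    ring += [(0, j) for j in range(m - 1)]
    ring += [(i, m - 1) for i in range(n - 1)]
    ring += [(n - 1, j) for j in range(m - 1, 0, -1)]
    ring += [(i, 0) for i in range(n - 1, 0, -1)]
    faces = []
    nm = n * m
    for k in range(len(ring)):
        i0, j0 = ring[k]
        i1, j1 = ring[(k + 1) % len(ring)]
        a, b = i0 * m + j0, i1 * m + j1
        faces.append([a, b, b + nm])
        faces.append([a, b + nm, a + nm])
    return np.asarray(faces)


def build_solid(thickness: np.ndarray, body_mask: np.ndarray, ct: CTVolume,
                plane: SBTPlane, beam: BeamSpec,
                supersample: int = 1) -> BolusSolid | None:
    """Triangulated bolus solid from a thickness map on the SBT plane.

    Inner vertices sit at the ray-BODY entry points; outer vertices are
    displaced toward the source along each ray by the local thickness (with a
    0.05 mm floor so the closed surface is non-degenerate). Returns ``None``
    with a warning when the map is everywhere zero. Rays without a BODY entry
    inside the meshed bounding box raise a hole error.
    """
    thickness = np.asarray(thickness, float)
    if thickness.shape != plane.shape:
        raise SpecError("thickness map does not match the SBT plane")
    if np.any(thickness < 0):
        raise SpecError("thickness must be non-negative")
    if thickness.max() <= MIN_THICKNESS_MM:
        log.warning("zero thickness everywhere: no solid built")
        return None
    entry = entry_distance_map(ct, body_mask, beam, plane)

    nz = np.argwhere(thickness > MIN_THICKNESS_MM)
    i0, j0 = nz.min(axis=0)
    i1, j1 = nz.max(axis=0) + 1
    i0, j0 = max(i0 - 1, 0), max(j0 - 1, 0)
    i1, j1 = min(i1 + 1, plane.n), min(j1 + 1, plane.n)
    sub_entry = entry[i0:i1, j0:j1]
    sub_thick = thickness[i0:i1, j0:j1]
    if np.any(~np.isfinite(sub_entry)):
        raise GeometryError("hole: ray without BODY entry inside the bolus "
                            "footprint")
    dirs = ray_directions(beam, plane)[i0:i1, j0:j1]

    if supersample > 1:
        f = supersample
        def up(a):
            n, m = a.shape
            gi = np.linspace(0, n - 1, (n - 1) * f + 1)
            gj = np.linspace(0, m - 1, (m - 1) * f + 1)
            I, J = np.meshgrid(gi, gj, indexing="ij")
            return map_coordinates(a, [I, J], order=1)
        sub_entry = up(sub_entry)
        sub_thick = up(sub_thick)
        dirs = np.stack([up(dirs[..., k]) for k in range(3)], axis=-1)
        dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)

    t_eff = np.maximum(sub_thick, MIN_THICKNESS_MM)
    inner = beam.source + sub_entry[..., None] * dirs
    outer = beam.source + (sub_entry - t_eff)[..., None] * dirs
    n, m = sub_entry.shape
    vertices = np.vstack([inner.reshape(-1, 3), outer.reshape(-1, 3)])
    faces = np.vstack([
        _grid_faces(n, m, offset=0, flip=False),         # inner sheet
        _grid_faces(n, m, offset=n * m, flip=True),      # outer sheet
        _skirt_faces(n, m),
    ])
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    trimesh.repair.fix_normals(mesh)
    if mesh.volume < 0:
        mesh.invert()
    return BolusSolid(mesh=mesh, beam=beam, plane=plane, entry_map=entry,
                      thickness_map=np.maximum(thickness, 0.0),
                      footprint=(int(i0), int(i1), int(j0), int(j1)))


def solid_to_structure(solid: BolusSolid, ct: CTVolume
                       ) -> tuple[np.ndarray, int]:
    """Voxelize the bolus solid onto the CT grid.

    A voxel belongs to the bolus iff its centre projects into the thickness
    map's footprint and its source distance lies between the outer and inner
    surfaces along its ray — the same fan geometry that built the mesh.
    Returns the mask and the HU override (160, printed PLA) for dose
    recomputation; warns when the solid is clipped by the CT extent.
    """
    plane, beam = solid.plane, solid.beam
    lo, hi = solid.mesh.bounds
    if np.any(lo < ct.origin - 1e-6) or np.any(hi > ct.extent_max + 1e-6):
        log.warning("bolus solid extends outside the CT volume; clipping")
    pts = ct.voxel_centers()
    a, b, t = project_to_plane(pts, beam)
    fi = a / plane.spacing + plane.n_half
    fj = b / plane.spacing + plane.n_half
    i0, i1, j0, j1 = solid.footprint
    ok = (fi >= i0) & (fi <= i1 - 1) & (fj >= j0) & (fj <= j1 - 1)
    # bilinear maps match the mesh's bilinear sheets
    entry = np.where(np.isfinite(solid.entry_map), solid.entry_map, 1e9)
    coords = np.stack([np.clip(fi, i0, i1 - 1), np.clip(fj, j0, j1 - 1)])
    ent = map_coordinates(entry, coords, order=1)
    thk = map_coordinates(np.maximum(solid.thickness_map, MIN_THICKNESS_MM),
                          coords, order=1)
    cov = map_coordinates((solid.thickness_map > MIN_THICKNESS_MM
                           ).astype(float), coords, order=1)
    inside = ok & (cov > 0.5) & (ent < 1e8) & (t >= ent - thk) & (t <= ent)
    return inside.reshape(ct.shape), BOLUS_HU_OVERRIDE


def override_ct(ct: CTVolume, mask: np.ndarray, hu: int = BOLUS_HU_OVERRIDE
                ) -> CTVolume:
    """New CT with the mask voxels set to the bolus HU (for recalculation)."""
    voxels = ct.voxels.copy()
    voxels[mask] = hu
    return CTVolume(voxels=voxels, spacing=ct.spacing.copy(),
                    origin=ct.origin.copy(), orientation=ct.orientation.copy())


def write_sidecar(path, cet: float, print_profile: str = "standard",
                  material: str = "PLA") -> None:
    """Record fabrication metadata next to the STL (not acted upon)."""
    meta = {
        "material": material,
        "cet": float(cet),
        "hu_override": BOLUS_HU_OVERRIDE,
        "print_profile": {
            "name": print_profile,
            "layer_height_mm": PRINT_PROFILES[print_profile],
            "infill_percent": 100,
            "infill_pattern": "linear",
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh)
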