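"""Beam coordinate system, virtual point source and divergent ray construction.

The beam frame is defined by the gantry angle (rotation about the patient +y
axis): at gantry 0 the central axis points along -z (source above the patient).
The virtual point source sits on the central axis at SAD (default 1000 mm)
upstream of the isocenter. The shift-of-bolus-thickness (SBT) grid lives on the
plane through the isocenter perpendicular to the central axis, spanned by the
rotated lateral axis ``u`` and the patient ``y`` axis ``v``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError
from .io_formats import CTVolume

STANDARD_ENERGIES = (6.0, 9.0, 12.0, 16.0)


@dataclass
class BeamSpec:
    """Electron beam: energy (MeV), square applicator side (cm), SSD (cm),
    gantry angle (degrees), isocenter (mm, patient frame), SAD (mm)."""

    energy: float
    applicator_cm: float
    ssd_cm: float = 100.0
    gantry_deg: float = 0.0
    isocenter: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sad_mm: float = 1000.0

    def __post_init__(self) -> None:
        self.isocenter = np.asarray(self.isocenter, dtype=float)
        if self.applicator_cm <= 0:
            raise GeometryError("applicator side must be positive")
        if self.ssd_cm <= 0 or self.sad_mm <= 0:
            raise GeometryError("SSD and SAD must be positive")

    @property
    def axis(self) -> np.ndarray:
        """Unit central-axis direction, source toward isocenter."""
        g = np.deg2rad(self.gantry_deg)
        return np.array([-np.sin(g), 0.0, -np.cos(g)])

    @property
    def lateral_u(self) -> np.ndarray:
        """First lateral unit vector of the SBT plane (gantry-rotated x)."""
        g = np.deg2rad(self.gantry_deg)
        return np.array([np.cos(g), 0.0, -np.sin(g)])

    @property
    def lateral_v(self) -> np.ndarray:
        """Second lateral unit vector (patient y)."""
        return np.array([0.0, 1.0, 0.0])

    @property
    def source(self) -> np.ndarray:
        """Virtual point source position (mm)."""
        return self.isocenter - self.sad_mm * self.axis

    @property
    def field_mm(self) -> float:
        """Square field side at the isocenter plane (mm)."""
        return self.applicator_cm * 10.0


@dataclass
class Ray:
    """Divergent ray from the virtual source through one SBT grid point.

    ``t_entry`` (mm from the source) marks the BODY entry point once attached;
    depths reported by surface extraction are measured from it.
    """

    origin: np.ndarray
    direction: np.ndarray
    t_entry: float | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        d = np.asarray(self.direction, float)
        self.direction = d / np.linalg.norm(d)

    def point(self, t: np.ndarray) -> np.ndarray:
        """World position(s) at source distance ``t`` (mm)."""
        t = np.asarray(t, float)
        return self.origin + t[..., None] * self.direction


@dataclass
class SBTPlane:
    """Square 2D grid on the isocenter plane perpendicular to the beam axis.

    Indices are 0-based, row-major, with the central axis at ``(center,
    center)``; +i runs along the gantry-rotated lateral axis, +j along patient y.
    """

    beam: BeamSpec
    spacing: float = 2.5
    half_extent_mm: float = 60.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise GeometryError("SBT plane spacing must be positive")
        self.n_half = int(np.ceil(self.half_extent_mm / self.spacing - 1e-9))
        self.n = 2 * self.n_half + 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n, self.n)

    @property
    def center(self) -> int:
        return self.n_half

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Lateral (a, b) mm coordinates of every grid point, shape (n, n)."""
        ax = (np.arange(self.n) - self.n_half) * self.spacing
        return np.meshgrid(ax, ax, indexing="ij")

    def point_mm(self, i: int | np.ndarray, j: int | np.ndarray) -> np.ndarray:
        """World position(s) of grid point(s) (i, j)."""
        a = (np.asarray(i, float) - self.n_half) * self.spacing
        b = (np.asarray(j, float) - self.n_half) * self.spacing
        return (self.beam.isocenter
                + a[..., None] * self.beam.lateral_u
                + b[..., None] * self.beam.lateral_v)

    def index_of(self, a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray,
                                                              np.ndarray]:
        """Nearest grid indices for lateral mm coordinates (may be out of range)."""
        i = np.rint(np.asarray(a) / self.spacing).astype(int) + self.n_half
        j = np.rint(np.asarray(b) / self.spacing).astype(int) + self.n_half
        return i, j


def build_sbt_plane(beam: BeamSpec, margin_mm: float = 10.0,
                    spacing: float = 2.5) -> SBTPlane:
    """SBT grid covering the projected applicator plus a margin on each side.

    The default 10 mm margin matches the beyond-aperture band acted on by the
    outside-PTV extrusion operator.
    """
    if margin_mm < 0:
        raise GeometryError("margin must be non-negative")
    half = beam.field_mm / 2.0 + margin_mm
    return SBTPlane(beam=beam, spacing=spacing, half_extent_mm=half)


def ray_through(beam: BeamSpec, plane: SBTPlane, i: int, j: int) -> Ray:
    """Ray from the virtual source through grid point (i, j), extended beyond
    the isocenter plane. The central ray (i = j = center) is axis-collinear."""
    p = plane.point_mm(i, j)
    return Ray(origin=beam.source, direction=p - beam.source)


def ray_directions(beam: BeamSpec, plane: SBTPlane) -> np.ndarray:
    """(n, n, 3) unit directions of all grid rays (vectorized ray_through)."""
    ii, jj = np.meshgrid(np.arange(plane.n), np.arange(plane.n), indexing="ij")
    pts = plane.point_mm(ii, jj)
    d = pts - beam.source
    return d / np.linalg.norm(d, axis=-1, keepdims=True)


def aperture_region(beam: BeamSpec, plane: SBTPlane,
                    beyond_mm: float = 10.0) -> np.ndarray:
    """Mask of grid points inside the applicator projection at the isocenter
    plane, expanded by ``beyond_mm`` on each side (the 1.0 cm default is the
    band handled by the outside-PTV operator)."""
    a, b = plane.coords_mm()
    half = beam.field_mm / 2.0 + beyond_mm
    return (np.abs(a) <= half + 1e-9) & (np.abs(b) <= half + 1e-9)


def project_to_plane(points: np.ndarray, beam: BeamSpec
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Central-project world points onto the isocenter plane along source rays.

    Returns lateral coordinates ``(a, b)`` in mm on the SBT plane and the
    distance ``t`` of each point from the source.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    w = pts - beam.source
    t = np.linalg.norm(w, axis=-1)
    along = w @ beam.axis
    if np.any(along <= 0):
        raise GeometryError("point at or behind the virtual source")
    scale = beam.sad_mm / along
    proj = beam.source + scale[:, None] * w
    rel = proj - beam.isocenter
    return rel @ beam.lateral_u, rel @ beam.lateral_v, t


def ray_volume_range(ray: Ray, ct: CTVolume) -> tuple[float, float] | None:
    """Parametric interval [t0, t1] where the ray is inside the CT extent
    (slab method); None if the ray misses the volume."""
    lo, hi = ct.origin, ct.extent_max
    t0, t1 = 0.0, np.inf
    for k in range(3):
        d, o = ray.direction[k], ray.origin[k]
        if abs(d) < 1e-12:
            if not (lo[k] <= o <= hi[k]):
                return None
            continue
        ta, tb = (lo[k] - o) / d, (hi[k] - o) / d
        t0, t1 = max(t0, min(ta, tb)), min(t1, max(ta, tb))
    if t1 <= t0:
        return None
    return t0, t1
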