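"""Shift-of-bolus-thickness (SBT) computation.

For each ray intersecting the PTV, the geometric gap between the distal 90%
isodose depth and the distal PTV depth is converted to millimetres of bolus
material through the coefficient-of-equivalent-thickness (CET) line integral

    SBT_p = (1 / CET_bolus) * ∫ CET(z) dz

taken along the diverging ray between the two distal depths, where CET(z) is
the density of the tissue at z relative to water (HU lookup). The sign is
positive (thicken the bolus) when the 90% surface lies deeper than the PTV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt

from .beam_geometry import Ray
from .errors import GeometryError, SpecError
from .io_formats import CTVolume

#: Relative density of printed PLA bolus derived from its measured CT number
#: (160 HU -> 1.119 g/cm3); the slab-shift measurement gives 1.13.
DEFAULT_BOLUS_CET = 1.119

_DEFAULT_TABLE = (
    (-1024.0, 0.001),
    (-1000.0, 0.001),
    (0.0, 1.000),
    (160.0, 1.119),
    (800.0, 1.500),
    (4000.0, 3.100),
)


@dataclass
class CETTable:
    """Piecewise-linear HU → relative-density lookup plus the bolus CET scalar.

    Mirrors a planning-system CT calibration curve. Must be monotone
    non-decreasing with CET(0 HU) = 1.
    """

    hu: np.ndarray = field(
        default_factory=lambda: np.array([r[0] for r in _DEFAULT_TABLE]))
    density: np.ndarray = field(
        default_factory=lambda: np.array([r[1] for r in _DEFAULT_TABLE]))
    bolus_cet: float = DEFAULT_BOLUS_CET

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, float)
        self.density = np.asarray(self.density, float)
        if np.any(np.diff(self.hu) <= 0):
            raise SpecError("CET table HU breakpoints must increase")
        if np.any(np.diff(self.density) < 0):
            raise SpecError("CET table must be monotone non-decreasing")
        if abs(float(np.interp(0.0, self.hu, self.density)) - 1.0) > 1e-9:
            raise SpecError("CET(0 HU) must equal 1.000")
        if self.bolus_cet <= 0:
            raise SpecError("bolus CET must be positive")

    def __call__(self, hu: np.ndarray) -> np.ndarray:
        return np.interp(hu, self.hu, self.density)

    @classmethod
    def from_yaml_dict(cls, d: dict) -> "CETTable":
        pairs = sorted((float(k), float(v)) for k, v in d["table"].items())
        return cls(hu=np.array([p[0] for p in pairs]),
                   density=np.array([p[1] for p in pairs]),
                   bolus_cet=float(d.get("bolus_cet", DEFAULT_BOLUS_CET)))


@dataclass
class SBTGrid:
    """Signed bolus-thickness shift (mm of bolus material) on the SBT plane.

    ``valid`` marks rays that intersect the PTV; ``flagged`` marks PTV rays
    whose isodose crossing was missing and whose value was filled from the
    nearest valid neighbour.
    """

    values: np.ndarray
    valid: np.ndarray
    flagged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.valid = np.asarray(self.valid, bool)
        if self.flagged is None:
            self.flagged = np.zeros_like(self.valid)
        if not np.all(np.isfinite(self.values)):
            raise SpecError("SBT values must be finite")


def cet_line_integral(ray: Ray, ct: CTVolume, cet_table: CETTable,
                      z_from: float, z_to: float) -> float:
    """Water-equivalent length (mm) of the ray segment [z_from, z_to].

    The CET profile along a ray is piecewise constant (one value per voxel),
    so the integral is evaluated exactly by resolving every voxel-boundary
    crossing (Siddon-style traversal) and summing CET x segment length, with
    the CET sampled at each segment midpoint. This makes the integral exactly
    additive over subintervals. Depths use the ray's own depth origin. Raises
    :class:`GeometryError` when the segment leaves the CT extent.
    """
    if z_from > z_to:
        raise SpecError("z_from must not exceed z_to")
    if z_from == z_to:
        return 0.0
    off = ray.t_entry if ray.t_entry is not None else 0.0
    t0, t1 = z_from + off, z_to + off
    ends = ray.point(np.array([t0, t1]))
    if np.any(ends < ct.origin - 1e-6) or np.any(ends > ct.extent_max + 1e-6):
        raise GeometryError("CET integration range extends outside the CT")
    cuts = [t0, t1]
    for k in range(3):
        d = ray.direction[k]
        if abs(d) < 1e-12:
            continue
        planes = ct.origin[k] + np.arange(ct.shape[k] + 1) * ct.spacing[k]
        tc = (planes - ray.origin[k]) / d
        cuts.append(tc[(tc > t0) & (tc < t1)])
    ts = np.unique(np.concatenate([np.atleast_1d(np.asarray(c, float))
                                   for c in cuts]))
    ts = ts[(ts >= t0 - 1e-12) & (ts <= t1 + 1e-12)]
    mids = 0.5 * (ts[:-1] + ts[1:])
    lengths = np.diff(ts)
    hu = ct.sample_hu(ray.point(mids))
    return float(np.sum(cet_table(hu) * lengths))


def compute_sbt(plane, rays: np.ndarray, ptv_depths: np.ndarray,
                isodose_depths: np.ndarray, ct: CTVolume,
                cet_table: CETTable) -> SBTGrid:
    """Thickness-shift matrix from per-ray distal depths.

    ``rays`` is an (n, n) object array of :class:`Ray` (or None);
    ``ptv_depths`` / ``isodose_depths`` hold the distal PTV / distal 90% depths
    per ray, NaN where unavailable. Rays missing the PTV are left invalid for
    the outside-PTV operator; PTV rays missing an isodose crossing are flagged
    and filled from the nearest valid neighbour.
    """
    valid = np.isfinite(ptv_depths)
    flagged = valid & ~np.isfinite(isodose_depths)
    values = np.zeros(plane.shape, dtype=float)
    for i, j in np.argwhere(valid & ~flagged):
        t2 = ptv_depths[i, j]       # distal PTV
        t1 = isodose_depths[i, j]   # distal 90% isodose
        lo, hi = (t2, t1) if t1 >= t2 else (t1, t2)
        weq = cet_line_integral(rays[i, j], ct, cet_table, lo, hi)
        values[i, j] = np.sign(t1 - t2) * weq / cet_table.bolus_cet
    if flagged.any():
        ok = valid & ~flagged
        if ok.any():
            _, (fi, fj) = distance_transform_edt(~ok, return_indices=True)
            values[flagged] = values[fi[flagged], fj[flagged]]
    return SBTGrid(values=values, valid=valid, flagged=flagged)


def apply_sbt(thickness: np.ndarray, sbt: SBTGrid
              ) -> tuple[np.ndarray, int]:
    """Adjust the running thickness map by the (modulated) SBT matrix.

    Physical bolus cannot be negative: the result is clamped at zero and the
    number of clamped points is returned alongside the new map.
    """
    thickness = np.asarray(thickness, float)
    if thickness.shape != sbt.values.shape:
        raise SpecError("thickness and SBT shapes differ")
    raw = thickness + sbt.values
    clamped = int(np.count_nonzero(raw < 0))
    return np.maximum(raw, 0.0), clamped
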