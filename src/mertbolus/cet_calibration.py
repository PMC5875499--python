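"""Estimate the bolus material's CET from depth-dose curves and from density.

Replacing the superficial t mm of water with bolus material of coefficient of
equivalent thickness CET shifts the depth-dose falloff shallower by

    z_eff - z_real = (CET - 1) * t

The shift between a reference (open water) curve and a slab curve is found by
chi-square matching of the falloff location; the CET follows as 1 plus the
least-squares slope of shift versus slab thickness through the origin.

Sign convention: a positive shift means the slab curve is shallower than the
reference, as expected for CET > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, SpecError
from .io_formats import PDDCurve


@dataclass
class CalibrationSlab:
    """One slab measurement: thickness, fitted shift, chi-square profile."""

    thickness_mm: float
    shift_mm: float
    shift_grid: np.ndarray
    chi2: np.ndarray

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise SpecError("slab thickness must be positive")


def _falloff_window(curve: PDDCurve, lo: float = 20.0, hi: float = 80.0
                    ) -> np.ndarray:
    """Depths in the 20-80% falloff region beyond the depth of maximum."""
    z_of_max = curve.depth_mm[int(np.argmax(curve.dose_percent))]
    sel = (curve.depth_mm > z_of_max) & (curve.dose_percent >= lo) \
        & (curve.dose_percent <= hi)
    z = curve.depth_mm[sel]
    if z.size < 3:
        raise SpecError("curves do not overlap over the falloff region")
    return z


def chi2_shift(pdd_ref: PDDCurve, pdd_slab: PDDCurve,
               search_mm: float = 10.0, step: float = 0.05,
               full: bool = False):
    """Shift s (mm) minimizing sum over the 20-80% falloff window of
    [pdd_slab(z) - pdd_ref(z + s)]^2, with parabolic refinement of the
    discrete minimum. Positive s = slab curve shallower.

    Raises :class:`ConvergenceError` when the minimum sits at the search
    boundary. ``full=True`` additionally returns the shift grid and the
    chi-square profile.
    """
    z = _falloff_window(pdd_slab)
    shifts = np.arange(-search_mm, search_mm + step / 2, step)
    target = pdd_slab(z)
    chi2 = np.array([np.sum((target - pdd_ref(z + s)) ** 2) for s in shifts])
    k = int(np.argmin(chi2))
    if k == 0 or k == len(shifts) - 1:
        raise ConvergenceError("chi-square minimum at the search boundary")
    # parabolic interpolation through the three points around the minimum
    y0, y1, y2 = chi2[k - 1], chi2[k], chi2[k + 1]
    denom = y0 - 2.0 * y1 + y2
    frac = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-30 else 0.0
    s = float(shifts[k] + frac * step)
    if full:
        return s, shifts, chi2
    return s


def cet_from_shifts(shifts: np.ndarray, thicknesses: np.ndarray
                    ) -> tuple[float, float | None]:
    """CET estimate (and residual-based 1-sigma uncertainty) from measured
    shifts at several slab thicknesses.

    Least-squares slope of shift vs thickness through the origin; CET = 1 +
    slope. A single slab gives the direct ratio with no uncertainty.
    """
    s = np.asarray(shifts, float)
    t = np.asarray(thicknesses, float)
    if s.shape != t.shape or s.size == 0:
        raise SpecError("shifts and thicknesses must match and be non-empty")
    if np.any(t <= 0):
        raise SpecError("slab thicknesses must be positive")
    if s.size == 1:
        return 1.0 + float(s[0] / t[0]), None
    slope = float(np.sum(s * t) / np.sum(t ** 2))
    resid = s - slope * t
    var = float(np.sum(resid ** 2) / ((s.size - 1) * np.sum(t ** 2)))
    return 1.0 + slope, float(np.sqrt(var))


def cet_from_density(density_g_cm3: float) -> float:
    """CET as density relative to water (1.000 g/cm^3)."""
    if density_g_cm3 <= 0:
        raise SpecError("density must be positive")
    return density_g_cm3 / 1.000


def calibrate_slab(pdd_ref: PDDCurve, pdd_slab: PDDCurve,
                   thickness_mm: float, **kwargs) -> CalibrationSlab:
    """Convenience: fit one slab and keep the chi-square profile."""
    s, grid, chi2 = chi2_shift(pdd_ref, pdd_slab, full=True, **kwargs)
    return CalibrationSlab(thickness_mm=thickness_mm, shift_mm=s,
                           shift_grid=grid, chi2=chi2)
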