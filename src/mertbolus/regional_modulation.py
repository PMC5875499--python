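"""The five regional modulation operators applied to the SBT matrix after the
ray-line thickness estimate: hot-spot smoothing, coverage smoothing,
irregular-surface smoothing, PTV-margin adjustment, and outside-PTV extrusion.

The three smoothing operators share one Gaussian regional kernel. The matrix
is segmented into points p to be adjusted, neighbouring points q used for the
smoothing (never themselves adjusted), and untouched points. With
w_q = exp(-r_pq^2 / (2 SF^2)) over neighbours at distance r_pq < SF:

    mode 1:  SBT_p <- (sum_q w_q SBT_q) / (1 + sum_q w_q)
    mode 2:  SBT_p <- (SBT_p + sum_q w_q SBT_q) / (1 + sum_q w_q)

Mode 2 is a proper weighted average (preserves constants); mode 1 drops the
self term and shrinks toward zero, suited to regions whose original values are
unreliable (hot spots). SF is the smoothing factor in mm: 5 / 10 / 20 for
low / medium / high.

All updates within one operator application are simultaneous (computed from
the input field). Operator order in the pipeline is fixed: hotspot ->
coverage -> irregularity -> margin -> extrusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree

from .errors import SpecError
from .sbt_core import SBTGrid
from .surface_model import RegionMask2D

log = logging.getLogger(__name__)

SF_LEVELS = {"low": 5.0, "medium": 10.0, "high": 20.0}


@dataclass
class SmoothingSpec:
    """Smoothing factor (mm) and kernel mode for the regional operators."""

    sf: float = 10.0
    mode: int = 2

    def __post_init__(self) -> None:
        if self.sf <= 0:
            raise SpecError("smoothing factor must be positive")
        if self.mode not in (1, 2):
            raise SpecError("mode must be 1 or 2")

    @classmethod
    def from_level(cls, level: str, mode: int = 2) -> "SmoothingSpec":
        return cls(sf=SF_LEVELS[level], mode=mode)


@dataclass
class MarginKernel:
    """Gaussian kernel of the PTV-margin adjustment.

    ``K1 = sigma * sqrt(-2 ln 0.01)`` is the radial distance over which the
    kernel rises from 0.01 to 1, so Ker(0) = 1 and Ker(K1) = 0.01 exactly.
    The default sigma grows with both beam energy and applicator size:
    sigma = sqrt(E[MeV] * A[cm]) mm.
    """

    sigma: float
    border_width: float = 10.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.border_width <= 0:
            raise SpecError("sigma and border width must be positive")

    @property
    def k1(self) -> float:
        return self.sigma * np.sqrt(-2.0 * np.log(0.01))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return np.exp(-(x ** 2) / (2.0 * self.sigma ** 2))

    @staticmethod
    def default_sigma(energy_mev: float, applicator_cm: float) -> float:
        return float(np.sqrt(energy_mev * applicator_cm))


def _as_mask(region) -> np.ndarray:
    if isinstance(region, RegionMask2D):
        return region.mask
    return np.asarray(region, bool)


def _as_values(sbt) -> np.ndarray:
    return sbt.values if isinstance(sbt, SBTGrid) else np.asarray(sbt, float)


def _wrap(sbt, values: np.ndarray):
    if isinstance(sbt, SBTGrid):
        return SBTGrid(values=values, valid=sbt.valid.copy(),
                       flagged=sbt.flagged.copy())
    return values


def _rm_kernel(values: np.ndarray, p_mask: np.ndarray, q_mask: np.ndarray,
               sf: float, mode: int, spacing: float) -> np.ndarray:
    """Apply the regional smoothing kernel; q candidates from q_mask minus the
    evaluation point itself, restricted to r_pq < SF (strict)."""
    out = values.copy()
    p_idx = np.argwhere(p_mask)
    if len(p_idx) == 0:
        return out
    q_idx = np.argwhere(q_mask)
    tree = cKDTree(q_idx * spacing) if len(q_idx) else None
    for i, j in p_idx:
        num, den = 0.0, 1.0
        if tree is not None:
            pos = np.array([i, j], float) * spacing
            nb = tree.query_ball_point(pos, sf)
            if nb:
                qn = q_idx[nb]
                d = np.linalg.norm(qn * spacing - pos, axis=1)
                keep = (d < sf - 1e-9) & ~((qn[:, 0] == i) & (qn[:, 1] == j))
                if keep.any():
                    w = np.exp(-d[keep] ** 2 / (2.0 * sf ** 2))
                    num = float(np.sum(w * values[qn[keep, 0], qn[keep, 1]]))
                    den = 1.0 + float(np.sum(w))
        out[i, j] = (num / den) if mode == 1 else ((values[i, j] + num) / den)
    return out


def smooth(sbt, region_p, sf: float = 10.0, mode: int = 2,
           spacing: float = 2.5):
    """Regional smoothing of points in ``region_p`` using neighbours within
    SF (mm) that lie outside the region. No-op on an empty region."""
    p_mask = _as_mask(region_p)
    values = _as_values(sbt)
    if p_mask.shape != values.shape:
        raise SpecError("region and SBT grid shapes differ")
    new = _rm_kernel(values, p_mask, ~p_mask, sf, mode, spacing)
    return _wrap(sbt, new)


def hotspot_smoothing(sbt, hotspot, sf: float = 10.0, spacing: float = 2.5):
    """Mode-1 smoothing over the projected hot-spot region (dose > 110%).

    Mode 1 is used because the original SBT values inside the region may
    differ appreciably from their surroundings. Identity when no hot spot.
    """
    mask = _as_mask(hotspot)
    if not mask.any():
        return _wrap(sbt, _as_values(sbt).copy())
    out = smooth(sbt, mask, sf=sf, mode=1, spacing=spacing)
    _log_change("hotspot", _as_values(sbt), _as_values(out), mask)
    return out


def coverage_smoothing(sbt, under, sf: float = 10.0, spacing: float = 2.5):
    """Extend bolus thinning beyond the projected under-dosed region.

    Negative SBT values inside the region are retained; an annulus of width SF
    around it is smoothed with mode 2, drawing neighbours from the region and
    the annulus, so thinning bleeds outward and coverage can only improve.
    """
    mask = _as_mask(under)
    values = _as_values(sbt)
    if not mask.any():
        return _wrap(sbt, values.copy())
    dist = distance_transform_edt(~mask) * spacing
    annulus = (dist > 0) & (dist <= sf + 1e-9)
    new = _rm_kernel(values, annulus, mask | annulus, sf, 2, spacing)
    _log_change("coverage", values, new, annulus)
    return _wrap(sbt, new)


def irregularity_smoothing(sbt, sf: float = 10.0, spacing: float = 2.5,
                           max_passes: int = 3, domain=None):
    """Smooth cells whose SBT gradient magnitude exceeds twice the mean.

    The central-difference gradient is evaluated on the grid; flagged cells are
    mode-2 smoothed; the pass repeats (at most ``max_passes``) until no cell is
    flagged. When ``domain`` is given (the PTV projection), both the flagged
    region and the statistics are restricted to it, because outside-PTV values
    are only defined after the extrusion operator and would otherwise dominate
    the gradient statistic with an artificial cliff.
    """
    values = _as_values(sbt).copy()
    dom = _as_mask(domain) if domain is not None else np.ones_like(values,
                                                                   dtype=bool)
    for _ in range(max_passes):
        gx, gy = np.gradient(values, spacing)
        mag = np.hypot(gx, gy)
        mean = mag[dom].mean() if dom.any() else 0.0
        region = dom & (mag > 2.0 * mean)
        if mean <= 0 or not region.any():
            break
        before = values
        values = _rm_kernel(values, region, dom & ~region, sf, 2, spacing)
        _log_change("irregularity", before, values, region)
    return _wrap(sbt, values)


def margin_adjustment(sbt, ptv_projection, kernel: MarginKernel,
                      spacing: float = 2.5, center: tuple[int, int] | None = None):
    """Taper bolus thickness in a border inside the PTV projection.

    The border is the band of ``kernel.border_width`` mm inside the projection
    boundary. For each border point p, m is the nearest inner-boundary point
    along the radial line from the central axis through p, r_pm their distance,
    and with x = max(K1 - r_pm, 0):

        SBT_p > 0 -> SBT_p * (1 - Ker(x))     (thin: boost dose at the edge)
        SBT_p < 0 -> SBT_p * (1 + Ker(x))     (extra thinning)

    If the central axis lies outside the PTV projection, m falls back to the
    nearest inner-boundary point (with a warning).
    """
    ptv = _as_mask(ptv_projection)
    values = _as_values(sbt).copy()
    if not ptv.any():
        return _wrap(sbt, values)
    dist_in = distance_transform_edt(ptv) * spacing
    border = ptv & (dist_in <= kernel.border_width + 1e-9)
    inner = ptv & ~border
    if center is None:
        center = (values.shape[0] // 2, values.shape[1] // 2)
    c = np.asarray(center, float)
    radial_ok = ptv[center] and inner.any()
    if not radial_ok:
        log.warning("margin adjustment: central axis outside PTV projection or "
                    "no interior; using nearest-boundary-point fallback")
        if inner.any():
            _, near = distance_transform_edt(~inner, return_indices=True)
    before = values.copy()
    for i, j in np.argwhere(border):
        p = np.array([i, j], float)
        if radial_ok:
            r_pm = _radial_inner_distance(p, c, inner, spacing)
        elif inner.any():
            m = np.array([near[0][i, j], near[1][i, j]], float)
            r_pm = np.linalg.norm(p - m) * spacing
        else:
            r_pm = np.linalg.norm(p - c) * spacing
        ker = kernel(max(kernel.k1 - r_pm, 0.0))
        v = values[i, j]
        values[i, j] = v * (1.0 - ker) if v > 0 else v * (1.0 + ker)
    _log_change("margin", before, values, border)
    return _wrap(sbt, values)


def _radial_inner_distance(p: np.ndarray, c: np.ndarray, inner: np.ndarray,
                           spacing: float) -> float:
    """Distance (mm) from p to the first inner-region cell walking toward the
    central axis; falls back to the full distance to the axis when the walk
    never enters the interior (degenerate projections)."""
    length = np.linalg.norm(p - c)
    if length < 1e-9:
        return 0.0
    n_steps = max(2, int(np.ceil(length / 0.25)))
    ts = np.linspace(0.0, 1.0, n_steps)
    pts = p[None, :] + ts[:, None] * (c - p)[None, :]
    idx = np.rint(pts).astype(int)
    idx = np.clip(idx, 0, np.array(inner.shape) - 1)
    hit = inner[idx[:, 0], idx[:, 1]]
    if not hit.any():
        return float(length * spacing)
    k = int(np.argmax(hit))
    return float(ts[k] * length * spacing)


def extrude_outside(sbt, ptv_projection, aperture,
                    spacing: float = 2.5, center: tuple[int, int] | None = None):
    """Extrude boundary SBT values from the PTV projection outward.

    Every point p between the PTV projection and the expanded aperture takes
    the value at n, the first PTV-projection point met on the segment from p
    toward the central-axis projection. Points beyond the expanded aperture are
    zeroed. If the segment misses the projection (concavity / off-axis), the
    nearest projection point is used instead (with a warning). Idempotent.
    """
    ptv = _as_mask(ptv_projection)
    ap = _as_mask(aperture)
    values = _as_values(sbt).copy()
    if not ptv.any():
        values[~ap] = 0.0
        return _wrap(sbt, values)
    if center is None:
        center = (values.shape[0] // 2, values.shape[1] // 2)
    c = np.asarray(center, float)
    _, near = distance_transform_edt(~ptv, return_indices=True)
    warned = False
    outside = ap & ~ptv
    before = values.copy()
    for i, j in np.argwhere(outside):
        p = np.array([i, j], float)
        n_cell = _segment_first_hit(p, c, ptv)
        if n_cell is None:
            if not warned:
                log.warning("extrusion: segment to central axis missed the PTV "
                            "projection; using nearest-boundary fallback")
                warned = True
            n_cell = (near[0][i, j], near[1][i, j])
        values[i, j] = before[n_cell]
    values[~ap] = 0.0
    _log_change("extrusion", before, values, outside | ~ap)
    return _wrap(sbt, values)


def _segment_first_hit(p: np.ndarray, c: np.ndarray,
                       mask: np.ndarray) -> tuple[int, int] | None:
    length = np.linalg.norm(c - p)
    if length < 1e-9:
        return None
    n_steps = max(2, int(np.ceil(length / 0.25)))
    ts = np.linspace(0.0, 1.0, n_steps)
    pts = p[None, :] + ts[:, None] * (c - p)[None, :]
    idx = np.rint(pts).astype(int)
    idx = np.clip(idx, 0, np.array(mask.shape) - 1)
    hit = mask[idx[:, 0], idx[:, 1]]
    if not hit.any():
        return None
    k = int(np.argmax(hit))
    return int(idx[k, 0]), int(idx[k, 1])


def _log_change(name: str, before: np.ndarray, after: np.ndarray,
                region: np.ndarray) -> None:
    delta = after - before
    if region.any():
        log.info("%s operator: region %d points, change min %.3f max %.3f mm",
                 name, int(region.sum()), float(delta[region].min()),
                 float(delta[region].max()))
    else:
        log.info("%s operator: empty region, identity", name)
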