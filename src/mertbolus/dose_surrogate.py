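"""Simplified electron broad-beam dose engine and 2D gamma comparison.

The engine stands in for a treatment-planning-system dose calculation during
desk-scale design and testing. It is a central-axis percentage-depth-dose
(PDD) model evaluated at water-equivalent depth along each diverging ray,
multiplied by error-function field edges with a depth-dependent penumbra. It
is heterogeneity-aware through the CET line integral but makes no claim of
matching a Monte Carlo engine; its parameters are frozen constants below.

PDD model per energy E (MeV), depths in mm of water:

    R50  = E / 2.33 cm      (half-value depth)
    Rp   = E / 2 cm         (practical range)
    zmax = 0.6 * R50        (depth of maximum)

85% surface dose rising parabolically to 100 at zmax; beyond zmax a logistic
falloff, rescaled to 100 at zmax and calibrated so dose(R50) = 50, on top of a
2% bremsstrahlung tail.

An adapter for externally computed dose (DICOM RTDOSE per iteration) lets a
clinic drop a planning-system calculation into the same iteration loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import erf

from .beam_geometry import BeamSpec, SBTPlane, build_sbt_plane, \
    project_to_plane, ray_directions
from .errors import FormatError, SpecError
from .io_formats import CTVolume, DoseGrid, PDDCurve, StructureSet, read_dose
from .sbt_core import CETTable

_SURFACE_DOSE = 85.0     # % at z = 0
_TAIL = 2.0              # % bremsstrahlung tail
_PENUMBRA_MM = 2.0       # lateral sigma at the surface
_PENUMBRA_GROWTH = 0.05  # sigma growth per mm depth
_STEP = 0.5              # mm, ray sampling for dose and CET accumulation
_SCATTER_SIGMA = 5.0     # mm, thickness-gradient scatter kernel width
_SCATTER_COEFF = 0.01    # fractional dose boost per mm of neighbour excess


@dataclass(frozen=True)
class PDDModel:
    """Frozen per-energy depth-dose parameterization."""

    energy: float
    r50: float = field(init=False)
    rp: float = field(init=False)
    zmax: float = field(init=False)
    _w: float = field(init=False)
    _c: float = field(init=False)

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise SpecError("energy must be positive")
        r50 = self.energy / 2.33 * 10.0
        rp = self.energy / 2.0 * 10.0
        zmax = 0.6 * r50
        w = (rp - r50) / 4.0
        object.__setattr__(self, "r50", r50)
        object.__setattr__(self, "rp", rp)
        object.__setattr__(self, "zmax", zmax)
        object.__setattr__(self, "_w", w)

        def ratio(c: float) -> float:
            f = lambda z: 1.0 / (1.0 + np.exp((z - c) / w))
            return _TAIL + (100.0 - _TAIL) * f(r50) / f(zmax) - 50.0

        c = brentq(ratio, zmax - 5.0 * w, rp + 20.0 * w, xtol=1e-10)
        object.__setattr__(self, "_c", c)

    def __call__(self, z: np.ndarray) -> np.ndarray:
        """Dose (% of maximum) at water-equivalent depth z (mm)."""
        z = np.asarray(z, float)
        build = 100.0 - (100.0 - _SURFACE_DOSE) * ((self.zmax - z) /
                                                   self.zmax) ** 2
        f = lambda zz: 1.0 / (1.0 + np.exp((zz - self._c) / self._w))
        fall = _TAIL + (100.0 - _TAIL) * f(z) / f(self.zmax)
        return np.where(z < self.zmax, build, fall)


@lru_cache(maxsize=None)
def _model(energy: float) -> PDDModel:
    return PDDModel(energy=energy)


def pdd(energy: float, z_eff: np.ndarray) -> np.ndarray:
    """Central-axis PDD (%) at water-equivalent depth(s) ``z_eff`` (mm)."""
    return _model(float(energy))(z_eff)


def pdd_curve(energy: float, z_max_mm: float | None = None,
              step: float = 0.5) -> PDDCurve:
    """Tabulated open-water PDD for an energy, as a :class:`PDDCurve`."""
    m = _model(float(energy))
    if z_max_mm is None:
        z_max_mm = 1.5 * m.rp
    z = np.arange(0.0, z_max_mm + step, step)
    return PDDCurve(depth_mm=z, dose_percent=m(z))


def _field_factor(a: np.ndarray, b: np.ndarray, depth: np.ndarray,
                  field_mm: float) -> np.ndarray:
    """Product of error-function field edges at isocenter-scaled lateral
    coordinates (a, b) and geometric depth (mm)."""
    sig = _PENUMBRA_MM + _PENUMBRA_GROWTH * np.maximum(depth, 0.0)
    half = field_mm / 2.0
    s2 = sig * np.sqrt(2.0)
    fa = 0.5 * (erf((half - a) / s2) + erf((half + a) / s2))
    fb = 0.5 * (erf((half - b) / s2) + erf((half + b) / s2))
    return fa * fb


def compute_dose(ct: CTVolume, structures: StructureSet,
                 bolus_thickness: np.ndarray | None, beam: BeamSpec,
                 cet_table: CETTable | None = None,
                 plane: SBTPlane | None = None,
                 scatter_hotspot: bool = False) -> DoseGrid:
    """Broad-beam surrogate dose on the CT grid, in % of prescription.

    Every voxel is assigned to its nearest grid ray; along each ray the
    water-equivalent depth accumulates the bolus path (thickness x bolus CET)
    plus the tissue CET path from the BODY entry point. Voxels outside the ray
    fan receive zero dose. ``scatter_hotspot`` enables a thickness-gradient
    scatter kernel that boosts dose under local valleys of the bolus, the
    mechanism that creates midline hot spots under strongly modulated bolus.
    """
    cet_table = cet_table or CETTable()
    plane = plane or build_sbt_plane(beam)
    n = plane.n
    if bolus_thickness is None:
        bolus_thickness = np.zeros(plane.shape)
    if bolus_thickness.shape != plane.shape:
        raise SpecError("bolus thickness map does not match the SBT plane")
    body = structures["BODY"]
    dirs = ray_directions(beam, plane).reshape(-1, 3)
    src = beam.source

    from .surface_model import entry_distance_map
    t_entry = entry_distance_map(ct, body, beam, plane, step=_STEP).reshape(-1)
    has_entry = np.isfinite(t_entry)

    # cumulative tissue CET from the entry point, midpoint rule
    t_hi = beam.sad_mm + float(np.linalg.norm(ct.extent_max - ct.origin))
    depth_max = t_hi - np.nanmin(t_entry) if has_entry.any() else 100.0
    n_samp = int(np.ceil(depth_max / _STEP)) + 2
    s_mid = (np.arange(n_samp) + 0.5) * _STEP
    pos = (src + dirs[:, None, :]
           * (np.nan_to_num(t_entry)[:, None] + s_mid[None, :])[..., None])
    hu = ct.sample_hu(pos)
    z_eff = np.cumsum(cet_table(hu), axis=1) * _STEP  # depth at s=(k+1)*STEP

    bolus_weq = bolus_thickness.reshape(-1) * cet_table.bolus_cet
    z_tot = z_eff + bolus_weq[:, None]

    a, b = plane.coords_mm()
    a = a.reshape(-1)
    b = b.reshape(-1)
    s_grid = (np.arange(n_samp) + 1) * _STEP
    model = _model(float(beam.energy))
    dose_samp = model(z_tot) * _field_factor(a[:, None], b[:, None],
                                             s_grid[None, :], beam.field_mm)
    dose_samp /= _field_factor(np.zeros(1), np.zeros(1),
                               np.array([model.zmax]), beam.field_mm)[0]
    if scatter_hotspot:
        blurred = gaussian_filter(bolus_thickness,
                                  _SCATTER_SIGMA / plane.spacing,
                                  mode="nearest")
        excess = (blurred - bolus_thickness).reshape(-1)
        factor = np.clip(1.0 + _SCATTER_COEFF * excess, 0.8, 1.3)
        dose_samp *= factor[:, None]
    dose_samp[~has_entry] = 0.0

    # gather: voxel -> (ray id, depth) -> linear interpolation along the ray
    pts = ct.voxel_centers()
    av, bv, tv = project_to_plane(pts, beam)
    iv = np.rint(av / plane.spacing).astype(int) + plane.n_half
    jv = np.rint(bv / plane.spacing).astype(int) + plane.n_half
    in_fan = (iv >= 0) & (iv < n) & (jv >= 0) & (jv < n)
    rid = np.clip(iv, 0, n - 1) * n + np.clip(jv, 0, n - 1)
    depth = tv - np.nan_to_num(t_entry)[rid]
    kf = depth / _STEP - 1.0
    k0 = np.clip(np.floor(kf).astype(int), 0, n_samp - 1)
    k1 = np.clip(k0 + 1, 0, n_samp - 1)
    frac = np.clip(kf - k0, 0.0, 1.0)
    d0 = dose_samp[rid, k0]
    d1 = dose_samp[rid, k1]
    vox = d0 * (1.0 - frac) + d1 * frac
    vox[(depth < 0) | ~in_fan | np.isnan(t_entry)[rid]] = 0.0
    return DoseGrid(values=vox.reshape(ct.shape), ct=ct)


@dataclass
class SurrogateEngine:
    """Dose-engine contract implementation backed by :func:`compute_dose`."""

    cet_table: CETTable = field(default_factory=CETTable)
    scatter_hotspot: bool = False

    def __call__(self, ct: CTVolume, structures: StructureSet,
                 bolus_thickness: np.ndarray | None, beam: BeamSpec,
                 plane: SBTPlane | None = None) -> DoseGrid:
        return compute_dose(ct, structures, bolus_thickness, beam,
                            cet_table=self.cet_table, plane=plane,
                            scatter_hotspot=self.scatter_hotspot)


@dataclass
class ExternalDoseEngine:
    """Adapter for externally computed dose (one RTDOSE file per iteration).

    Mirrors the clinical workflow where each design iteration is recalculated
    in the planning system and re-exported.
    """

    dose_paths: list[str | Path]
    prescription_cgy: float | None = None
    _cursor: int = 0

    def __call__(self, ct: CTVolume, structures: StructureSet,
                 bolus_thickness: np.ndarray | None, beam: BeamSpec,
                 plane: SBTPlane | None = None) -> DoseGrid:
        if self._cursor >= len(self.dose_paths):
            raise FormatError("no external dose file left for this iteration")
        path = self.dose_paths[self._cursor]
        self._cursor += 1
        return read_dose(path, ct, prescription_cgy=self.prescription_cgy)


def gamma_2d(eval_plane: np.ndarray, ref_plane: np.ndarray,
             dose_crit: float = 3.0, dist_crit: float = 5.0,
             spacing: float = 1.0) -> tuple[np.ndarray, float]:
    """Global-normalization 2D gamma of an evaluated dose plane against a
    reference plane on a common grid.

    For each reference point the minimum over evaluation points within a
    search disk (radius 3 x ``dist_crit``) of

        sqrt( (D_eval - D_ref)^2 / (dose_crit% of max ref)^2 + r^2 / dist_crit^2 )

    Returns the gamma map and the pass rate (% of points with gamma <= 1).
    """
    ev = np.asarray(eval_plane, float)
    ref = np.asarray(ref_plane, float)
    if ev.shape != ref.shape:
        raise SpecError("gamma planes must share a grid")
    ref_max = ref.max()
    if ref_max <= 0:
        raise FormatError("all-zero reference plane cannot be normalized")
    dd = dose_crit / 100.0 * ref_max
    r_cells = int(np.floor(3.0 * dist_crit / spacing))
    best = np.full(ref.shape, np.inf)
    for di in range(-r_cells, r_cells + 1):
        for dj in range(-r_cells, r_cells + 1):
            r2 = (di * spacing) ** 2 + (dj * spacing) ** 2
            if r2 > (3.0 * dist_crit) ** 2:
                continue
            shifted = np.full(ref.shape, np.nan)
            src = shifted[max(0, -di):shifted.shape[0] - max(0, di),
                          max(0, -dj):shifted.shape[1] - max(0, dj)]
            src[...] = ev[max(0, di):ev.shape[0] - max(0, -di),
                          max(0, dj):ev.shape[1] - max(0, -dj)]
            g2 = (shifted - ref) ** 2 / dd ** 2 + r2 / dist_crit ** 2
            best = np.fmin(best, g2)
    gamma = np.sqrt(best)
    pass_rate = 100.0 * float(np.count_nonzero(gamma <= 1.0)) / gamma.size
    return gamma, pass_rate
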