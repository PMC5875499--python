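"""Synthetic phantom generator.

Produces CT volumes, structure sets and depth-dose fixtures that replicate the
desk-scale test geometries every stage of the design pipeline is exercised on:
a water cube with a wedge-shaped PTV and optional bone/air slabs distal to it,
and curved-surface phantoms (sinusoidal or spherical-cap entrance) with an
embedded PTV at fixed depth below the skin — stand-ins for foot/head-like
anatomy. Generation is deterministic given the phantom parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .beam_geometry import BeamSpec
from .dose_surrogate import pdd
from .errors import SpecError
from .io_formats import CTVolume, PDDCurve, StructureSet

MATERIAL_HU = {"water": 0, "bone": 800, "air": -1000, "pla": 160}


@dataclass
class Insert:
    """Axis-aligned inhomogeneity box, corners in mm, material by name."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]
    material: str

    def __post_init__(self) -> None:
        if self.material not in MATERIAL_HU:
            raise SpecError(f"unknown material {self.material!r}")
        if not all(h > l for l, h in zip(self.lo, self.hi)):
            raise SpecError("insert box must have positive extent")


@dataclass
class PhantomSpec:
    """Geometry of a synthetic phantom.

    The phantom occupies x, y in [-size/2, size/2] and z in [0, size_z] with
    the entrance surface on top (+z); the beam enters along -z at gantry 0.
    PTV depths are measured from the (local) entrance surface.
    """

    size_mm: tuple[float, float, float] = (200.0, 200.0, 200.0)
    spacing_mm: float = 1.0
    surface: str = "flat"          # flat | wedge | sinusoidal | spherical-cap
    surface_amplitude_mm: float = 0.0
    surface_period_mm: float = 100.0
    cap_radius_mm: float = 150.0
    ptv_half_x_mm: float = 30.0
    ptv_half_y_mm: float = 30.0
    ptv_proximal_mm: float = 5.0
    ptv_distal_min_mm: float = 20.0
    ptv_distal_max_mm: float = 40.0
    inserts: list[Insert] = field(default_factory=list)
    air_above_mm: float = 0.0   # air gap above the entrance surface in the CT
    hu_noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise SpecError("voxel spacing must be positive")
        if self.ptv_proximal_mm >= self.ptv_distal_min_mm:
            raise SpecError("PTV proximal depth must be above the distal range")
        for ins in self.inserts:
            for k in range(3):
                lo_ok = ins.lo[k] >= (-self.size_mm[k] / 2 if k < 2 else 0.0)
                hi_ok = ins.hi[k] <= (self.size_mm[k] / 2 if k < 2
                                      else self.size_mm[k])
                if not (lo_ok and hi_ok):
                    raise SpecError("insert outside the phantom")

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        inserts = [Insert(lo=tuple(i["lo"]), hi=tuple(i["hi"]),
                          material=i["material"]) for i in d.pop("inserts", [])]
        return cls(**{k: tuple(v) if k == "size_mm" else v
                      for k, v in d.items()}, inserts=inserts)


def _grids(spec: PhantomSpec):
    s = spec.spacing_mm
    nx = int(round(spec.size_mm[0] / s))
    ny = int(round(spec.size_mm[1] / s))
    nz = int(round(spec.size_mm[2] / s))
    origin = np.array([-spec.size_mm[0] / 2, -spec.size_mm[1] / 2, 0.0])
    cx = origin[0] + (np.arange(nx) + 0.5) * s
    cy = origin[1] + (np.arange(ny) + 0.5) * s
    cz = origin[2] + (np.arange(nz) + 0.5) * s
    return origin, cx, cy, cz


def _apply_noise_and_pack(hu: np.ndarray, spec: PhantomSpec,
                          origin: np.ndarray) -> CTVolume:
    if spec.hu_noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.hu_noise_sigma, hu.shape)
    hu = np.clip(np.round(hu), -1024, 4000).astype(np.int16)
    return CTVolume(voxels=hu, spacing=np.full(3, spec.spacing_mm),
                    origin=origin)


def _insert_masks(spec: PhantomSpec, X, Y, Z) -> dict[str, np.ndarray]:
    out = {}
    for k, ins in enumerate(spec.inserts):
        m = ((X >= ins.lo[0]) & (X < ins.hi[0]) & (Y >= ins.lo[1])
             & (Y < ins.hi[1]) & (Z >= ins.lo[2]) & (Z < ins.hi[2]))
        out[f"INSERT_{ins.material.upper()}_{k}"] = m
    return out


def make_wedge_phantom(spec: PhantomSpec
                       ) -> tuple[CTVolume, StructureSet]:
    """Water cube with a wedge PTV whose distal surface is a planar ramp.

    The distal depth ramps linearly from ``ptv_distal_min_mm`` to
    ``ptv_distal_max_mm`` across the PTV's x extent; equal values give a flat
    (degenerate) wedge. Optional bone/air inserts sit distal to the PTV; an
    insert overlapping the PTV is a spec error.
    """
    origin, cx, cy, cz = _grids(spec)
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    z_top = spec.size_mm[2] - spec.air_above_mm
    body = Z < z_top
    frac = np.clip((X + spec.ptv_half_x_mm) / (2 * spec.ptv_half_x_mm), 0, 1)
    distal_depth = spec.ptv_distal_min_mm + frac * (
        spec.ptv_distal_max_mm - spec.ptv_distal_min_mm)
    depth = z_top - Z
    ptv = ((np.abs(X) <= spec.ptv_half_x_mm)
           & (np.abs(Y) <= spec.ptv_half_y_mm)
           & (depth >= spec.ptv_proximal_mm) & (depth <= distal_depth))
    hu = np.where(body, 0.0, -1000.0)
    masks = {"BODY": body, "PTV": ptv}
    for name, m in _insert_masks(spec, X, Y, Z).items():
        if np.any(m & ptv):
            raise SpecError(f"{name} overlaps the PTV")
        hu[m] = MATERIAL_HU[name.split("_")[1].lower()]
        masks[name] = m
    ct = _apply_noise_and_pack(hu, spec, origin)
    ss = StructureSet(masks=masks)
    ss.validate_for_design()
    return ct, ss


def make_curved_phantom(spec: PhantomSpec
                        ) -> tuple[CTVolume, StructureSet]:
    """Phantom with a curved entrance surface and a surface-following PTV.

    Surface profiles: ``sinusoidal`` (height base + A sin(2 pi x / period)) or
    ``spherical-cap`` (cap of the given radius on a flat base); amplitude 0
    reduces to a flat slab. The PTV spans depths
    [``ptv_proximal_mm``, ``ptv_distal_min_mm``] below the local surface; a
    PTV breaking through the surface is a spec error.
    """
    origin, cx, cy, cz = _grids(spec)
    X, Y, Z = np.meshgrid(cx, cy, cz, indexing="ij")
    base = spec.size_mm[2] - spec.air_above_mm - spec.surface_amplitude_mm
    if spec.surface == "sinusoidal":
        z_surf = base + spec.surface_amplitude_mm * (
            1.0 + np.sin(2 * np.pi * X[:, :, 0] / spec.surface_period_mm)) / 2
    elif spec.surface == "spherical-cap":
        z_surf = surface_height_spherical_cap(
            X[:, :, 0], Y[:, :, 0], base, spec.cap_radius_mm,
            spec.surface_amplitude_mm)
    elif spec.surface == "flat":
        z_surf = np.full(X.shape[:2], float(spec.size_mm[2]
                                            - spec.air_above_mm))
    else:
        raise SpecError(f"unknown surface profile {spec.surface!r}")
    if spec.ptv_proximal_mm <= 0:
        raise SpecError("PTV breaks through the surface")
    body = Z <= z_surf[:, :, None]
    depth = z_surf[:, :, None] - Z
    ptv = ((np.abs(X) <= spec.ptv_half_x_mm)
           & (np.abs(Y) <= spec.ptv_half_y_mm)
           & (depth >= spec.ptv_proximal_mm)
           & (depth <= spec.ptv_distal_min_mm))
    hu = np.where(body, 0.0, -1000.0)
    masks = {"BODY": body, "PTV": ptv}
    for name, m in _insert_masks(spec, X, Y, Z).items():
        m = m & body
        hu[m] = MATERIAL_HU[name.split("_")[1].lower()]
        masks[name] = m
    ct = _apply_noise_and_pack(hu, spec, origin)
    ss = StructureSet(masks=masks)
    ss.validate_for_design()
    return ct, ss


def surface_height_spherical_cap(x, y, base: float, radius: float,
                                 cap_height: float) -> np.ndarray:
    """Analytic height field of a spherical cap of ``cap_height`` on a flat
    base: the sphere of the given radius is centred on the axis so its top
    sits ``cap_height`` above the base."""
    if not 0 <= cap_height <= radius:
        raise SpecError("cap height must lie in [0, radius]")
    zc = base + cap_height - radius
    r2 = np.asarray(x) ** 2 + np.asarray(y) ** 2
    dome = zc + np.sqrt(np.maximum(radius ** 2 - r2, 0.0))
    return np.maximum(base, np.where(r2 <= radius ** 2, dome, base))


def make_pdd_fixture(energy: float,
                     material_stack: list[tuple[float, float]],
                     z_max_mm: float | None = None,
                     step: float = 0.5) -> PDDCurve:
    """Depth-dose curve with the superficial layers replaced by slabs.

    ``material_stack`` is an ordered list of (thickness mm, CET) from the
    surface down; the curve is the surrogate PDD evaluated at the effective
    (water-equivalent) depth through the stack, renormalized to max 100.
    """
    if float(energy) not in (6.0, 9.0, 12.0, 16.0):
        raise SpecError("energy must be one of 6, 9, 12, 16 MeV")
    for t, _cet in material_stack:
        if t < 0:
            raise SpecError("negative slab thickness")
    if z_max_mm is None:
        z_max_mm = 1.5 * energy / 2.0 * 10.0
    z = np.arange(0.0, z_max_mm + step, step)
    z_eff = np.zeros_like(z)
    remaining = z.copy()
    consumed = np.zeros_like(z)
    for t, cet in material_stack:
        seg = np.clip(remaining, 0.0, t)
        z_eff += seg * cet
        remaining -= seg
        consumed += seg
    z_eff += np.maximum(z - consumed, 0.0)  # water below the stack
    dose = pdd(energy, z_eff)
    dose = dose * 100.0 / dose.max()
    return PDDCurve(depth_mm=z, dose_percent=dose)


def beam_for_phantom(ct: CTVolume, body_mask: np.ndarray, energy: float,
                     applicator_cm: float, ssd_cm: float = 100.0,
                     sad_mm: float = 1000.0) -> BeamSpec:
    """Vertical beam (gantry 0) on the phantom's central axis with the given
    SSD: the isocenter is placed SAD - 10*SSD mm below the entry point."""
    nx, ny, _ = ct.shape
    col = body_mask[nx // 2, ny // 2, :]
    if not col.any():
        raise SpecError("no BODY on the central axis")
    k_top = int(np.max(np.nonzero(col)))
    z_surf = ct.origin[2] + (k_top + 1) * ct.spacing[2]
    center_xy = ct.origin[:2] + np.array(ct.shape[:2]) * ct.spacing[:2] / 2.0
    entry = np.array([center_xy[0], center_xy[1], z_surf])
    iso = entry + (sad_mm - ssd_cm * 10.0) * np.array([0.0, 0.0, -1.0])
    return BeamSpec(energy=energy, applicator_cm=applicator_cm,
                    ssd_cm=ssd_cm, gantry_deg=0.0, isocenter=iso,
                    sad_mm=sad_mm)
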