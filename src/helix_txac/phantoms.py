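"""Voxelized 511 keV attenuation phantoms and emission-activity volumes.

Phantoms are defined parametrically (cylinders, nested ellipsoids, inserts)
and voxelized with a center-inclusion rule: a voxel takes a material's
linear attenuation coefficient iff its center lies inside the shape.  This
rule is simple, deterministic, and converges to the analytic volume as the
voxel size shrinks, and it matches the grid model assumed by the exact
(Siddon) ray tracer used in the forward simulation.

Units: lengths in mm, attenuation in cm^-1, activity concentration Bq/mL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "GridSpec",
    "MaterialTable",
    "AttenuationVolume",
    "ActivityVolume",
    "make_cylinder_phantom",
    "make_insert_phantom",
    "make_head_phantom",
    "make_uniform_activity",
    "WATER_BOTTLE_1L",
]

#: Linear attenuation coefficients at 511 keV (cm^-1).  Water is the
#: standard literature reference; cortical bone and PTFE come from photon
#: cross-section tabulations (NIST XCOM mass coefficients times nominal
#: densities 1.92 and 2.2 g/cm^3).  Override any entry via MaterialTable.
DEFAULT_MU_511 = {
    "air": 0.0,
    "water": 0.096,
    "soft_tissue": 0.0975,
    "bone": 0.172,
    "teflon": 0.191,
}

#: Preset dimensions (mm) for a 1 L water bottle test object.  The preset
#: encloses 1.0 L: pi * 4.5^2 * 15.7 = 998.8 mL.
WATER_BOTTLE_1L = {"diameter_mm": 90.0, "height_mm": 157.0}


@dataclass(frozen=True)
class GridSpec:
    """Regular voxel grid: ``shape`` voxels of ``voxel_size`` mm; ``origin``
    is the mm offset of the grid *corner* from the scanner isocenter.
    Axis order is (x, y, z) with z along the bore."""

    shape: tuple
    voxel_size: tuple
    origin: tuple

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError("shape must be three integers >= 1")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")

    @classmethod
    def default(cls, size_mm: float = 200.0, voxel_mm: float = 2.0) -> "GridSpec":
        n = int(round(size_mm / voxel_mm))
        return cls(shape=(n, n, n), voxel_size=(voxel_mm,) * 3,
                   origin=(-size_mm / 2,) * 3)

    @property
    def extent(self):
        """(min, max) mm per axis."""
        lo = np.asarray(self.origin, float)
        hi = lo + np.asarray(self.shape) * np.asarray(self.voxel_size)
        return lo, hi

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def centers(self):
        """Voxel-center coordinate arrays (1D per axis, mm)."""
        return tuple(
            self.origin[i] + (np.arange(self.shape[i]) + 0.5) * self.voxel_size[i]
            for i in range(3)
        )

    def center_mesh(self):
        cx, cy, cz = self.centers()
        return np.meshgrid(cx, cy, cz, indexing="ij")


class MaterialTable:
    """Material name -> linear attenuation coefficient at 511 keV (cm^-1)."""

    def __init__(self, overrides: Mapping[str, float] | None = None):
        self._mu = dict(DEFAULT_MU_511)
        if overrides:
            self._mu.update(overrides)
        if self._mu.get("air", 0.0) > 1e-6:
            raise ValueError("air attenuation must be ~0 at 511 keV")
        for k, v in self._mu.items():
            if v < 0 or not np.isfinite(v):
                raise ValueError(f"invalid mu for {k!r}: {v}")

    def mu(self, name: str) -> float:
        try:
            return self._mu[name]
        except KeyError:
            raise KeyError(f"unknown material {name!r}; known: {sorted(self._mu)}")

    def __contains__(self, name: str) -> bool:
        return name in self._mu


@dataclass
class _Volume:
    values: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError("values shape does not match grid")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("values must be finite and non-negative")

    @property
    def voxel_size(self):
        return self.grid.voxel_size

    @property
    def origin(self):
        return self.grid.origin

    def to_nifti(self, path) -> None:
        from .io import save_nifti
        save_nifti(path, self.values, self.grid)

    @classmethod
    def from_nifti(cls, path):
        from .io import load_nifti
        values, grid = load_nifti(path)
        return cls(values=values, grid=grid)


class AttenuationVolume(_Volume):
    """Voxel grid of linear attenuation coefficients mu at 511 keV (cm^-1)."""


class ActivityVolume(_Volume):
    """Voxel grid of activity concentration (Bq/mL)."""

    @property
    def total_activity_bq(self) -> float:
        return float(self.values.sum() * self.grid.voxel_volume_ml)


def _cylinder_mask(grid: GridSpec, diameter_mm: float, height_mm: float,
                   center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Boolean mask of voxels whose centers lie inside an axis-aligned
    (z-axis) cylinder."""
    cx, cy, cz = grid.centers()
    r2 = (cx[:, None] - center[0]) ** 2 + (cy[None, :] - center[1]) ** 2
    in_disc = r2 <= (diameter_mm / 2.0) ** 2
    in_z = np.abs(cz - center[2]) <= height_mm / 2.0
    return in_disc[:, :, None] & in_z[None, None, :]


def _check_cylinder_fits(grid: GridSpec, diameter_mm, height_mm, center) -> None:
    lo, hi = grid.extent
    need_lo = np.array([center[0] - diameter_mm / 2, center[1] - diameter_mm / 2,
                        center[2] - height_mm / 2])
    need_hi = np.array([center[0] + diameter_mm / 2, center[1] + diameter_mm / 2,
                        center[2] + height_mm / 2])
    if np.any(need_lo < lo) or np.any(need_hi > hi):
        raise ValueError(
            f"cylinder (d={diameter_mm} mm, h={height_mm} mm at {center}) "
            f"exceeds grid extent {lo}..{hi}; enlarge the grid")


def make_cylinder_phantom(diameter_mm: float, height_mm: float, material: str,
                          grid: GridSpec | None = None,
                          materials: MaterialTable | None = None,
                          center=(0.0, 0.0, 0.0)) -> AttenuationVolume:
    """Homogeneous cylinder phantom (axis along z).

    Voxels whose centers fall inside the cylinder take the material's mu;
    all others are 0 (air).  Raises if the cylinder does not fit in the
    grid — silent clipping would bias every downstream volume check.
    """
    if diameter_mm <= 0 or height_mm <= 0:
        raise ValueError("diameter and height must be positive")
    grid = grid or GridSpec.default()
    materials = materials or MaterialTable()
    _check_cylinder_fits(grid, diameter_mm, height_mm, center)
    values = np.zeros(grid.shape, dtype=np.float64)
    values[_cylinder_mask(grid, diameter_mm, height_mm, center)] = materials.mu(material)
    return AttenuationVolume(values=values, grid=grid)


@dataclass(frozen=True)
class CylinderSpec:
    """Axis-aligned cylindrical insert: diameter/height in mm, center in mm."""
    diameter_mm: float
    height_mm: float
    center: tuple = (0.0, 0.0, 0.0)
    material: str = "teflon"


def default_cavity_layout(diameters_mm, ring_radius_mm: float = 36.0,
                          height_mm: float = 120.0):
    """Place air-cavity cylinders on a circle around the phantom axis,
    equally spaced in azimuth, all spanning ``height_mm`` axially."""
    specs = []
    n = len(diameters_mm)
    for k, d in enumerate(diameters_mm):
        phi = 2.0 * np.pi * k / max(n, 1)
        specs.append(CylinderSpec(
            diameter_mm=d, height_mm=height_mm,
            center=(ring_radius_mm * np.cos(phi), ring_radius_mm * np.sin(phi), 0.0),
            material="air"))
    return specs


def make_insert_phantom(base_cylinder: AttenuationVolume,
                        teflon_cylinder_spec: CylinderSpec | None,
                        air_cavity_diameters_mm,
                        cavity_layout=None,
                        materials: MaterialTable | None = None):
    """Water phantom with a Teflon cylinder and graded cylindrical air
    cavities, emulating a resolution/contrast test object.

    Returns ``(volume, masks)`` where ``masks`` maps label -> boolean voxel
    mask (``"cavity_<d>mm"`` per cavity, ``"teflon"``, and ``"base"`` for
    the remaining water), so that recovery can be scored later against
    ground truth.  Inserts must be pairwise disjoint and inside the base.
    """
    materials = materials or MaterialTable()
    grid = base_cylinder.grid
    values = base_cylinder.values.copy()
    base_mask = values > 0

    specs = []
    if teflon_cylinder_spec is not None:
        specs.append(("teflon", teflon_cylinder_spec))
    cavities = (cavity_layout if cavity_layout is not None
                else default_cavity_layout(air_cavity_diameters_mm))
    if len(cavities) != len(air_cavity_diameters_mm):
        raise ValueError("cavity layout length must match diameters")
    for d, spec in zip(air_cavity_diameters_mm, cavities):
        specs.append((f"cavity_{d:g}mm", spec))

    masks = {}
    occupied = np.zeros(grid.shape, dtype=bool)
    for label, spec in specs:
        m = _cylinder_mask(grid, spec.diameter_mm, spec.height_mm, spec.center)
        if not np.all(base_mask[m]):
            raise ValueError(f"insert {label!r} extends outside the base cylinder")
        if np.any(occupied & m):
            raise ValueError(f"insert {label!r} overlaps another insert")
        occupied |= m
        values[m] = materials.mu(spec.material)
        masks[label] = m
    masks["base"] = base_mask & ~occupied
    return AttenuationVolume(values=values, grid=grid), masks


def _ellipsoid_mask(grid: GridSpec, semi_axes, center=(0.0, 0.0, 0.0)):
    cx, cy, cz = grid.centers()
    a, b, c = semi_axes
    u = ((cx - center[0]) / a) ** 2
    v = ((cy - center[1]) / b) ** 2
    w = ((cz - center[2]) / c) ** 2
    return (u[:, None, None] + v[None, :, None] + w[None, None, :]) <= 1.0


def make_head_phantom(grid: GridSpec | None = None,
                      materials: MaterialTable | None = None):
    """Simplified three-material head: soft-tissue interior inside a bone
    shell, with an air sinus cavity.  Exactly three distinct mu levels
    (air = 0 included).

    Returns ``(volume, info)`` with ``info`` holding the analytic component
    volumes (mL) of the nested ellipsoids for convergence checks.
    """
    grid = grid or GridSpec.default()
    materials = materials or MaterialTable()
    outer = (75.0, 88.0, 95.0)      # skull outer semi-axes, mm
    shell = 7.0                     # bone shell thickness, mm
    inner = tuple(s - shell for s in outer)
    sinus_c = (0.0, 55.0, -25.0)    # frontal air cavity
    sinus_ax = (14.0, 16.0, 12.0)

    m_outer = _ellipsoid_mask(grid, outer)
    m_inner = _ellipsoid_mask(grid, inner)
    m_sinus = _ellipsoid_mask(grid, sinus_ax, sinus_c)

    values = np.zeros(grid.shape, dtype=np.float64)
    values[m_outer] = materials.mu("bone")
    values[m_inner] = materials.mu("soft_tissue")
    values[m_sinus & m_inner] = materials.mu("air")

    def ell_vol(ax):
        return 4.0 / 3.0 * np.pi * ax[0] * ax[1] * ax[2] / 1000.0

    info = {
        "bone_shell_ml": ell_vol(outer) - ell_vol(inner),
        "soft_tissue_ml": ell_vol(inner) - ell_vol(sinus_ax),
        "sinus_ml": ell_vol(sinus_ax),
        "total_nonzero_ml": ell_vol(outer) - ell_vol(sinus_ax),
    }
    return AttenuationVolume(values=values, grid=grid), info


def make_uniform_activity(total_activity_bq: float, diameter_mm: float,
                          height_mm: float, grid: GridSpec | None = None,
                          center=(0.0, 0.0, 0.0)) -> ActivityVolume:
    """Uniform cylindrical emission source with the requested total
    activity; the concentration is scaled so the voxelized total matches
    the request exactly (well within the 0.5% bookkeeping tolerance)."""
    if total_activity_bq < 0:
        raise ValueError("activity must be >= 0")
    grid = grid or GridSpec.default()
    _check_cylinder_fits(grid, diameter_mm, height_mm, center)
    mask = _cylinder_mask(grid, diameter_mm, height_mm, center)
    values = np.zeros(grid.shape, dtype=np.float64)
    n = int(mask.sum())
    if total_activity_bq > 0:
        if n == 0:
            raise ValueError("no voxel centers fall inside the requested "
                             "cylinder; refine the grid")
        values[mask] = total_activity_bq / (n * grid.voxel_volume_ml)
    return ActivityVolume(values=values, grid=grid)
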