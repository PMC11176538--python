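"""Tumor size geometry and drug dose/unit arithmetic.

Tumor "size" (a clinical diameter in mm) is translated to a cell count by
treating the tumor as a disc three cell layers deep (cell length ~10 um,
so depth 3e-2 mm) at a packing density of 1e6 cells per mm^3:

    cells = pi * radius^2 * depth * density

Dose arithmetic follows the standard intravesical protocol (40 mg
mitomycin-C in 50 ml, molecular weight 334 g/mol), converting a course
dose in mg to a molar concentration in uM and then to a continuous
instillation rate in uM/day by spreading it over ``tau`` days.
"""

from __future__ import annotations

import dataclasses
import math

__all__ = [
    "CELL_DEPTH_MM",
    "CELL_DENSITY_PER_MM3",
    "MMC_MOLECULAR_WEIGHT",
    "TumorGeometry",
    "DoseSpec",
    "cells_from_diameter",
    "cells_from_radius",
    "diameter_from_cells",
    "dose_to_molar",
    "molar_to_rate",
    "rate_to_course_mg",
    "half_life",
]

#: Default tumor thickness: 3 cell layers of ~10 um [mm].
CELL_DEPTH_MM = 3e-2
#: Default packing density [cells / mm^3].
CELL_DENSITY_PER_MM3 = 1e6
#: Molecular weight of mitomycin-C [g/mol].
MMC_MOLECULAR_WEIGHT = 334.0
#: Standard single-session protocol.
PROTOCOL_DOSE_MG = 40.0
PROTOCOL_VOLUME_ML = 50.0
DEFAULT_TAU_DAYS = 365.0


def cells_from_radius(
    radius_mm: float,
    depth_mm: float = CELL_DEPTH_MM,
    density: float = CELL_DENSITY_PER_MM3,
) -> float:
    """Cell count of a disc-shaped tumor of the given radius [mm]."""
    if radius_mm < 0:
        raise ValueError(f"radius must be nonnegative, got {radius_mm}")
    return math.pi * radius_mm**2 * depth_mm * density


def cells_from_diameter(
    diameter_mm: float,
    depth_mm: float = CELL_DEPTH_MM,
    density: float = CELL_DENSITY_PER_MM3,
) -> float:
    """Cell count of a disc-shaped tumor of the given diameter [mm]."""
    if diameter_mm < 0:
        raise ValueError(f"diameter must be nonnegative, got {diameter_mm}")
    return cells_from_radius(diameter_mm / 2.0, depth_mm, density)


def diameter_from_cells(
    cells: float,
    depth_mm: float = CELL_DEPTH_MM,
    density: float = CELL_DENSITY_PER_MM3,
) -> float:
    """Tumor diameter [mm] corresponding to a cell count (inverse of the disc model)."""
    if cells < 0:
        raise ValueError(f"cell count must be nonnegative, got {cells}")
    return 2.0 * math.sqrt(cells / (math.pi * depth_mm * density))


def dose_to_molar(
    dose_mg: float,
    volume_ml: float = PROTOCOL_VOLUME_ML,
    mw: float = MMC_MOLECULAR_WEIGHT,
) -> float:
    """Molar concentration [uM] of ``dose_mg`` dissolved in ``volume_ml``.

    mg/ml equals g/L, so concentration = (dose/volume)/mw mol/L = 1e6 *
    (dose/volume)/mw uM.
    """
    if volume_ml <= 0 or mw <= 0:
        raise ValueError("volume and molecular weight must be positive")
    if dose_mg < 0:
        raise ValueError(f"dose must be nonnegative, got {dose_mg}")
    return dose_mg / volume_ml / mw * 1e6


def molar_to_rate(m0_uM: float, tau_days: float = DEFAULT_TAU_DAYS) -> float:
    """Continuous instillation rate [uM/day] spreading ``m0_uM`` over ``tau_days``."""
    if tau_days <= 0:
        raise ValueError(f"tau must be positive, got {tau_days}")
    return m0_uM / tau_days


def rate_to_course_mg(
    m_uM_per_day: float,
    tau_days: float = DEFAULT_TAU_DAYS,
    volume_ml: float = PROTOCOL_VOLUME_ML,
    mw: float = MMC_MOLECULAR_WEIGHT,
) -> float:
    """Course dose [mg] equivalent to an instillation rate, inverting the full chain."""
    if tau_days <= 0:
        raise ValueError(f"tau must be positive, got {tau_days}")
    return m_uM_per_day * tau_days * mw * volume_ml / 1e6


def half_life(mu1: float) -> float:
    """Drug half-life [minutes] implied by a first-order washout rate [1/day]."""
    if mu1 <= 0:
        raise ValueError(f"washout rate must be positive, got {mu1}")
    return math.log(2.0) / mu1 * 1440.0


@dataclasses.dataclass(frozen=True)
class TumorGeometry:
    """Disc-model tumor geometry linking a clinical size to a cell count."""

    diameter_mm: float
    depth_mm: float = CELL_DEPTH_MM
    density: float = CELL_DENSITY_PER_MM3

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    @property
    def cells(self) -> float:
        return cells_from_diameter(self.diameter_mm, self.depth_mm, self.density)

    @classmethod
    def from_cells(cls, cells: float, depth_mm: float = CELL_DEPTH_MM,
                   density: float = CELL_DENSITY_PER_MM3) -> "TumorGeometry":
        return cls(diameter_from_cells(cells, depth_mm, density), depth_mm, density)

    @classmethod
    def from_radius(cls, radius_mm: float, depth_mm: float = CELL_DEPTH_MM,
                    density: float = CELL_DENSITY_PER_MM3) -> "TumorGeometry":
        return cls(2.0 * radius_mm, depth_mm, density)


@dataclasses.dataclass(frozen=True)
class DoseSpec:
    """A course dose and the derived molar concentration / instillation rate."""

    dose_mg: float = PROTOCOL_DOSE_MG
    volume_ml: float = PROTOCOL_VOLUME_ML
    mw: float = MMC_MOLECULAR_WEIGHT
    tau_days: float = DEFAULT_TAU_DAYS

    @property
    def m0_uM(self) -> float:
        """Dissolved concentration [uM]."""
        return dose_to_molar(self.dose_mg, self.volume_ml, self.mw)

    @property
    def m_uM_per_day(self) -> float:
        """Continuous instillation rate [uM/day]."""
        return molar_to_rate(self.m0_uM, self.tau_days)

    @classmethod
    def from_rate(cls, m_uM_per_day: float, tau_days: float = DEFAULT_TAU_DAYS,
                  volume_ml: float = PROTOCOL_VOLUME_ML,
                  mw: float = MMC_MOLECULAR_WEIGHT) -> "DoseSpec":
        return cls(rate_to_course_mg(m_uM_per_day, tau_days, volume_ml, mw),
                   volume_ml, mw, tau_days)
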