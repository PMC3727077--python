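"""Tumor-compartment geometry derived from primitive measurements.

The tumor compartment is characterized by a small set of measured primitives
(tumor-cell diameter, capillary lumen diameter and wall thickness, a
perimeter-correction factor for non-circular microvessels, the extracellular
fluid fraction and the intravascular fraction). Everything else — cell volume
and surface area, capillary density, endothelial wall fraction, vessel and
cell surface densities per unit tissue volume, basement-membrane volume
fractions, and the fluid volumes available to VEGF in each interstitial
sub-region — is derived here. Intermediates are carried unrounded through the
whole chain; rounding happens only in display/export.

Two conventions worth noting:

* The dodecahedral cell area (not the spherical one) enters the parenchymal
  surface density S_PC: tumor cells are not spherical, and a regular
  dodecahedron of equal volume has ~10% more area.
* Basement-membrane volume fractions are computed from the *smooth* areas
  (circular outer perimeter for the endothelial basement membrane, spherical
  cell area for the parenchymal one). The perimeter/shape corrections apply
  to the exchange areas, not to the thin BM shells wrapped around them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CellGeometry",
    "CapillaryGeometry",
    "TissueComposition",
    "InterstitialRegion",
    "InterstitialPartition",
    "TumorGeometry",
    "sphere_geometry",
    "dodecahedron_surface_from_volume",
    "capillary_geometry",
    "capillary_density",
    "surface_densities",
    "ec_wall_fraction",
    "basement_membrane_fractions",
    "interstitial_partition",
    "derive_tumor_geometry",
]

UM2_PER_MM2 = 1e6
CM2_PER_CM3_FROM_UM_PER_MM2 = 1e-4 * 1e2  # um * mm^-2 -> cm * cm^-2

#: regular dodecahedron: V = (15 + 7 sqrt 5)/4 a^3,  A = 3 sqrt(25 + 10 sqrt 5) a^2
_DODECA_VOL_COEF = (15.0 + 7.0 * math.sqrt(5.0)) / 4.0
_DODECA_AREA_COEF = 3.0 * math.sqrt(25.0 + 10.0 * math.sqrt(5.0))


@dataclass(frozen=True)
class CellGeometry:
    """A parenchymal cell: diameter (um), volume (um^3), surface area (um^2)."""

    diameter_um: float
    volume_um3: float
    surface_area_um2: float
    shape: str  # "sphere" | "dodecahedron"

    def __post_init__(self) -> None:
        if self.volume_um3 <= 0 or self.surface_area_um2 <= 0:
            raise ValueError("cell volume and surface area must be positive")


@dataclass(frozen=True)
class CapillaryGeometry:
    """Capillary cross-section geometry (lengths um, areas um^2)."""

    lumen_diameter_um: float
    wall_thickness_um: float
    lumen_cross_section_um2: float
    wall_cross_section_um2: float
    outer_perimeter_circular_um: float
    perimeter_correction: float
    true_perimeter_um: float

    def __post_init__(self) -> None:
        if self.wall_cross_section_um2 <= 0:
            raise ValueError("wall cross-section must be positive")
        expected = self.outer_perimeter_circular_um * (1.0 + self.perimeter_correction)
        if not math.isclose(self.true_perimeter_um, expected, rel_tol=1e-12):
            raise ValueError("true_perimeter must equal circular perimeter * (1 + correction)")


@dataclass(frozen=True)
class TissueComposition:
    """Volume fractions (cm^3/cm^3 tissue) and surface densities (cm^2/cm^3)."""

    f_extracellular_fluid: float
    f_intravascular: float
    f_ec_wall: float
    f_parenchymal: float
    f_interstitial: float
    capillary_density_per_mm2: float
    s_ec_cm2_per_cm3: float
    s_pc_cm2_per_cm3: float

    def __post_init__(self) -> None:
        for name in (
            "f_extracellular_fluid",
            "f_intravascular",
            "f_ec_wall",
            "f_parenchymal",
            "f_interstitial",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        closure = self.f_intravascular + self.f_ec_wall + self.f_parenchymal + self.f_interstitial
        if abs(closure - 1.0) > 5e-3:
            raise ValueError(f"volume fractions sum to {closure}, expected 1 within 0.005")


@dataclass(frozen=True)
class InterstitialRegion:
    """One interstitial sub-region (ECM, EBM or PBM)."""

    name: str
    volume_fraction: float
    fluid_fraction: float
    partition_coefficient: float
    available_fluid_volume: float = field(default=0.0)

    def __post_init__(self) -> None:
        for name in ("fluid_fraction", "partition_coefficient"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.volume_fraction < 0:
            raise ValueError("volume fraction must be >= 0")
        if self.available_fluid_volume > self.volume_fraction + 1e-12:
            raise ValueError("available fluid volume cannot exceed the region volume")


@dataclass(frozen=True)
class InterstitialPartition:
    regions: tuple[InterstitialRegion, ...]

    @property
    def total_available(self) -> float:
        return sum(r.available_fluid_volume for r in self.regions)

    def region(self, name: str) -> InterstitialRegion:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)


def sphere_geometry(diameter_um: float) -> CellGeometry:
    """Volume pi d^3/6 and surface pi d^2 of a spherical cell."""
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    volume = math.pi * diameter_um**3 / 6.0
    area = math.pi * diameter_um**2
    return CellGeometry(diameter_um, volume, area, "sphere")


def dodecahedron_surface_from_volume(volume_um3: float) -> float:
    """Surface area of a regular dodecahedron with the given volume."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    edge = (volume_um3 / _DODECA_VOL_COEF) ** (1.0 / 3.0)
    return _DODECA_AREA_COEF * edge**2


def dodecahedron_cell(diameter_um: float) -> CellGeometry:
    """Dodecahedral cell with the same volume as a sphere of this diameter."""
    sphere = sphere_geometry(diameter_um)
    area = dodecahedron_surface_from_volume(sphere.volume_um3)
    return CellGeometry(diameter_um, sphere.volume_um3, area, "dodecahedron")


def capillary_geometry(
    lumen_diameter_um: float,
    wall_thickness_um: float,
    perimeter_correction: float,
) -> CapillaryGeometry:
    """Cross-section geometry of a capillary with a non-circular perimeter.

    The outer perimeter of an equivalent circular vessel is inflated by
    ``perimeter_correction`` (a fractional increase; 0.23 for breast-tumor
    capillaries) to obtain the true abluminal perimeter.
    """
    if lumen_diameter_um <= 0 or wall_thickness_um <= 0:
        raise ValueError("capillary dimensions must be positive")
    if perimeter_correction < 0:
        raise ValueError("perimeter correction must be >= 0")
    lumen_cs = math.pi * lumen_diameter_um**2 / 4.0
    outer_d = lumen_diameter_um + 2.0 * wall_thickness_um
    outer_cs = math.pi * outer_d**2 / 4.0
    perim = math.pi * outer_d
    return CapillaryGeometry(
        lumen_diameter_um=lumen_diameter_um,
        wall_thickness_um=wall_thickness_um,
        lumen_cross_section_um2=lumen_cs,
        wall_cross_section_um2=outer_cs - lumen_cs,
        outer_perimeter_circular_um=perim,
        perimeter_correction=perimeter_correction,
        true_perimeter_um=perim * (1.0 + perimeter_correction),
    )


def capillary_density(lumen_cross_section_um2: float, f_intravascular: float) -> float:
    """Capillaries per mm^2 needed to realize the intravascular volume fraction."""
    if lumen_cross_section_um2 <= 0:
        raise ValueError("lumen cross-section must be positive")
    if not 0.0 <= f_intravascular < 1.0:
        raise ValueError("intravascular fraction must be in [0, 1)")
    return f_intravascular / lumen_cross_section_um2 * UM2_PER_MM2


def surface_densities(
    capillary: CapillaryGeometry,
    density_per_mm2: float,
    cell: CellGeometry,
    f_parenchymal: float,
) -> tuple[float, float]:
    """(S_EC, S_PC): vessel and parenchymal-cell surface per tissue volume, cm^2/cm^3."""
    if density_per_mm2 < 0 or f_parenchymal < 0:
        raise ValueError("density and parenchymal fraction must be >= 0")
    s_ec = capillary.true_perimeter_um * density_per_mm2 * CM2_PER_CM3_FROM_UM_PER_MM2
    s_pc = f_parenchymal / cell.volume_um3 * cell.surface_area_um2 * 1e4
    return s_ec, s_pc


def ec_wall_fraction(capillary: CapillaryGeometry, density_per_mm2: float) -> float:
    """Volume fraction of tissue occupied by the endothelial walls of microvessels."""
    return capillary.wall_cross_section_um2 * density_per_mm2 / UM2_PER_MM2


def basement_membrane_fractions(
    capillary: CapillaryGeometry,
    density_per_mm2: float,
    cell_sphere: CellGeometry,
    f_parenchymal: float,
    ebm_thickness_nm: float,
    pbm_thickness_nm: float,
) -> tuple[float, float]:
    """(f_EBM, f_PBM): thin-shell volume fractions of the basement membranes.

    Uses the smooth areas (circular outer perimeter, spherical cell surface);
    the corrugation corrections apply to exchange areas, not to the BM shells.
    """
    s_ec_smooth = (
        capillary.outer_perimeter_circular_um * density_per_mm2 * CM2_PER_CM3_FROM_UM_PER_MM2
    )
    s_pc_smooth = f_parenchymal / cell_sphere.volume_um3 * cell_sphere.surface_area_um2 * 1e4
    f_ebm = s_ec_smooth * ebm_thickness_nm * 1e-7  # nm -> cm
    f_pbm = s_pc_smooth * pbm_thickness_nm * 1e-7
    return f_ebm, f_pbm


def interstitial_partition(
    regions: list[InterstitialRegion], f_interstitial: float
) -> InterstitialPartition:
    """Available fluid volume of each region: volume x fluid fraction x partition."""
    total = sum(r.volume_fraction for r in regions)
    if total > f_interstitial * (1.0 + 1e-9):
        raise ValueError(
            f"region volume fractions sum to {total}, exceeding interstitial fraction "
            f"{f_interstitial}"
        )
    out = []
    for r in regions:
        avail = r.volume_fraction * r.fluid_fraction * r.partition_coefficient
        out.append(
            InterstitialRegion(
                name=r.name,
                volume_fraction=r.volume_fraction,
                fluid_fraction=r.fluid_fraction,
                partition_coefficient=r.partition_coefficient,
                available_fluid_volume=avail,
            )
        )
    return InterstitialPartition(tuple(out))


@dataclass(frozen=True)
class TumorGeometry:
    """Full derived geometry of the tumor compartment."""

    cell_sphere: CellGeometry
    cell: CellGeometry
    capillary: CapillaryGeometry
    composition: TissueComposition
    interstitium: InterstitialPartition

    @property
    def cells_per_cm3(self) -> float:
        return self.composition.f_parenchymal / (self.cell.volume_um3 * 1e-12)

    @property
    def available_fluid_fraction(self) -> float:
        return self.interstitium.total_available

    def as_flat_dict(self) -> dict[str, float]:
        """Derived values for audit/export (one row per named quantity)."""
        c = self.composition
        d = {
            "cell_diameter_um": self.cell.diameter_um,
            "cell_volume_um3": self.cell.volume_um3,
            "cell_surface_sphere_um2": self.cell_sphere.surface_area_um2,
            "cell_surface_dodecahedron_um2": self.cell.surface_area_um2,
            "lumen_cross_section_um2": self.capillary.lumen_cross_section_um2,
            "wall_cross_section_um2": self.capillary.wall_cross_section_um2,
            "outer_perimeter_circular_um": self.capillary.outer_perimeter_circular_um,
            "true_perimeter_um": self.capillary.true_perimeter_um,
            "capillary_density_per_mm2": c.capillary_density_per_mm2,
            "f_intravascular": c.f_intravascular,
            "f_ec_wall": c.f_ec_wall,
            "f_parenchymal": c.f_parenchymal,
            "f_interstitial": c.f_interstitial,
            "s_ec_cm2_per_cm3": c.s_ec_cm2_per_cm3,
            "s_pc_cm2_per_cm3": c.s_pc_cm2_per_cm3,
            "cells_per_cm3": self.cells_per_cm3,
            "available_fluid_fraction": self.available_fluid_fraction,
        }
        for r in self.interstitium.regions:
            d[f"f_{r.name}"] = r.volume_fraction
            d[f"available_fluid_{r.name}"] = r.available_fluid_volume
        return d


def derive_tumor_geometry(
    cell_diameter_um: float = 12.0,
    lumen_diameter_um: float = 13.94,
    wall_thickness_um: float = 0.5,
    perimeter_correction: float = 0.23,
    f_extracellular_fluid: float = 0.45,
    f_intravascular: float = 0.10,
    ebm_thickness_nm: float = 50.0,
    pbm_thickness_nm: float = 30.0,
    bm_fluid_fraction: float = 0.7,
    ecm_fluid_fraction: float = 0.9318,
    partition_coefficient: float = 0.9,
    available_fluid_overrides: dict[str, float] | None = None,
) -> TumorGeometry:
    """Derive the complete tumor-compartment geometry from primitives.

    ``available_fluid_overrides`` maps region name (ECM/EBM/PBM) to a value
    that replaces the product formula — provided because published parameter
    sets sometimes carry available-fluid volumes from unrounded or amended
    intermediates that the printed fractions do not reproduce exactly.
    """
    cell_sphere = sphere_geometry(cell_diameter_um)
    cell = dodecahedron_cell(cell_diameter_um)
    cap = capillary_geometry(lumen_diameter_um, wall_thickness_um, perimeter_correction)
    density = capillary_density(cap.lumen_cross_section_um2, f_intravascular)
    f_wall = ec_wall_fraction(cap, density)
    f_interstitial = f_extracellular_fluid - f_intravascular
    f_parenchymal = 1.0 - f_intravascular - f_wall - f_interstitial
    s_ec, s_pc = surface_densities(cap, density, cell, f_parenchymal)
    f_ebm, f_pbm = basement_membrane_fractions(
        cap, density, cell_sphere, f_parenchymal, ebm_thickness_nm, pbm_thickness_nm
    )
    f_ecm = f_interstitial - f_ebm - f_pbm
    composition = TissueComposition(
        f_extracellular_fluid=f_extracellular_fluid,
        f_intravascular=f_intravascular,
        f_ec_wall=f_wall,
        f_parenchymal=f_parenchymal,
        f_interstitial=f_interstitial,
        capillary_density_per_mm2=density,
        s_ec_cm2_per_cm3=s_ec,
        s_pc_cm2_per_cm3=s_pc,
    )
    regions = [
        InterstitialRegion("ECM", f_ecm, ecm_fluid_fraction, partition_coefficient),
        InterstitialRegion("EBM", f_ebm, bm_fluid_fraction, partition_coefficient),
        InterstitialRegion("PBM", f_pbm, bm_fluid_fraction, partition_coefficient),
    ]
    interstitium = interstitial_partition(regions, f_interstitial)
    if available_fluid_overrides:
        patched = []
        for r in interstitium.regions:
            if r.name in available_fluid_overrides:
                patched.append(
                    InterstitialRegion(
                        r.name,
                        r.volume_fraction,
                        r.fluid_fraction,
                        r.partition_coefficient,
                        available_fluid_overrides[r.name],
                    )
                )
            else:
                patched.append(r)
        interstitium = InterstitialPartition(tuple(patched))
    return TumorGeometry(cell_sphere, cell, cap, composition, interstitium)
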