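"""Profile-scale physics and depth-weighted aggregation.

Operations
----------
* porosity partition from saturated/dry core masses: micro-pores
  ``P_mi = 100 (W1 - W2) / V`` (grams of pore water per 100 mL core are
  numerically volume percent) and macro-pores
  ``P_ma = (liquid% + gaseous%) - P_mi``;
* bulk density ``W2 / V`` (g mL-1 == Mg m-3);
* effective soil depth (ESD): depth from the surface to the top of the first
  horizon whose penetrometer compactness reaches the fine-root limit
  (default 0.718 MPa, strict ``<`` to remain effective);
* mapping of spot core measurements onto described horizons;
* depth-thickness-weighted profile means ``Mw = sum(T_i I_i) / sum(T_i)``
  with the study's thickness conventions (75 cm physical, 100 cm chemical,
  20 cm biological);
* nutrient stocks within the ESD:
  ``sum over horizons of thickness_m x bulk_density x concentration``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .datasets import HorizonMeasurement, SoilProfile

__all__ = [
    "CoreSaturationRecord",
    "PorosityResult",
    "WeightedMeanResult",
    "StockResult",
    "THICKNESS_CONVENTIONS",
    "ESD_THRESHOLD_MPA",
    "porosity_partition",
    "bulk_density",
    "effective_soil_depth",
    "map_measurements_to_horizons",
    "biological_layer_values",
    "weighted_mean",
    "aggregate_parameter",
    "nutrient_stock",
]

#: profile thickness (cm) over which each parameter family is averaged
THICKNESS_CONVENTIONS = {"physical": 75.0, "chemical": 100.0, "biological": 20.0}

#: penetrometer resistance (MPa) above which fine-root growth is restricted
ESD_THRESHOLD_MPA = 0.718

PARAMETER_FAMILY = {
    "solid": "physical", "liquid": "physical", "gaseous": "physical",
    "P_ma": "physical", "P_mi": "physical", "total_pores": "physical",
    "bulk_density": "physical", "SHC": "physical",
    "fractal_dimension": "physical", "void_ratio": "physical",
    "pH_H2O": "chemical", "pH_KCl": "chemical", "OC": "chemical",
    "TN": "chemical", "Ca": "chemical", "Mg": "chemical", "K": "chemical",
    "Na": "chemical", "CEC": "chemical", "base_saturation": "chemical",
    "NO3_N": "chemical", "available_P": "chemical", "P_absorption": "chemical",
    "B_C": "biological", "B_N": "biological",
    "beta_glucosidase": "biological", "protease": "biological",
}


@dataclass(frozen=True)
class CoreSaturationRecord:
    """Masses of one 100 mL core, saturated (W1) and oven-dry (W2), in grams."""

    W1: float
    W2: float
    core_volume_mL: float = 100.0
    liquid_pct: float = 0.0
    gaseous_pct: float = 0.0

    def __post_init__(self) -> None:
        if self.W2 <= 0:
            raise ValueError("oven-dry mass W2 must be positive")
        if self.W1 < self.W2:
            raise ValueError("saturated mass W1 cannot be below oven-dry mass W2")
        if self.core_volume_mL <= 0:
            raise ValueError("core volume must be positive")
        if self.liquid_pct + self.gaseous_pct > 100.0 + 1e-9:
            raise ValueError("liquid + gaseous fractions exceed 100 %")


@dataclass(frozen=True)
class PorosityResult:
    P_mi: float
    P_ma: float


@dataclass(frozen=True)
class WeightedMeanResult:
    parameter: str
    farm_id: str
    Mw: float
    profile_thickness_cm: float
    weights_used: tuple[tuple[str, float, float], ...]  # (horizon, T, I)


@dataclass(frozen=True)
class StockResult:
    farm_id: str
    constituent: str
    esd_cm: float
    stock: float
    unit: str
    per_horizon: tuple[tuple[str, float], ...]


def porosity_partition(rec: CoreSaturationRecord) -> PorosityResult:
    """Split core porosity into micro- and macro-pore volume percentages.

    Water held at saturation fills the micro-pores, so the mass difference in
    grams over a 100 mL core is numerically the micro-pore percentage.  The
    field three-phase (liquid + gaseous) fraction is total porosity; the
    remainder is macro-pores, floored at 0 with a warning.
    """
    p_mi = 100.0 * (rec.W1 - rec.W2) / rec.core_volume_mL  # rho_water = 1 g/mL
    p_ma = (rec.liquid_pct + rec.gaseous_pct) - p_mi
    if p_ma < 0:
        warnings.warn(
            f"macro-pore fraction negative ({p_ma:.2f} %); floored at 0",
            stacklevel=2,
        )
        p_ma = 0.0
    return PorosityResult(P_mi=p_mi, P_ma=p_ma)


def bulk_density(W2: float, core_volume_mL: float = 100.0) -> float:
    """Oven-dry mass over core volume; g mL-1 reported as Mg m-3."""
    if W2 <= 0 or core_volume_mL <= 0:
        raise ValueError("mass and volume must be positive")
    return W2 / core_volume_mL


def effective_soil_depth(
    profile: SoilProfile, threshold_MPa: float = ESD_THRESHOLD_MPA
) -> float:
    """Depth (cm) to the top of the first horizon at or above the compactness
    limit; the described depth if no horizon reaches it."""
    for h in profile.horizons:
        if h.compactness_MPa is None:
            raise ValueError(
                f"profile {profile.farm_id}: horizon {h.name} has no compactness"
            )
        if h.compactness_MPa >= threshold_MPa:
            return h.top_cm
    return profile.described_depth_cm


def map_measurements_to_horizons(
    profile: SoilProfile,
    measurements: list[HorizonMeasurement],
    parameter: str,
) -> tuple[dict[str, float], list[tuple[str, str]]]:
    """Assign one value of ``parameter`` to every horizon of the profile.

    A horizon whose depth interval contains a measurement interval takes that
    value (mean if several).  A horizon with no measurement borrows from the
    measured horizon whose midpoint is nearest its own (tie: the shallower
    one).  Returns ``(values_by_horizon, mapping_report)`` where the report
    lists ``(horizon, source)`` with source ``"direct"`` or the donor name.
    """
    ms = [m for m in measurements if m.parameter == parameter]
    if not ms:
        raise ValueError(f"no measurements for parameter {parameter!r}")
    direct: dict[str, list[float]] = {}
    for m in ms:
        for h in profile.horizons:
            if m.top_cm >= h.top_cm and m.bottom_cm <= h.bottom_cm:
                direct.setdefault(h.name, []).append(m.effective_value)
                break
    if not direct:
        raise ValueError(
            f"no measurement interval for {parameter!r} falls inside a horizon"
        )
    values: dict[str, float] = {}
    report: list[tuple[str, str]] = []
    measured = [h for h in profile.horizons if h.name in direct]
    for h in profile.horizons:
        if h.name in direct:
            values[h.name] = sum(direct[h.name]) / len(direct[h.name])
            report.append((h.name, "direct"))
        else:
            donor = min(
                measured,
                key=lambda d: (abs(d.midpoint_cm - h.midpoint_cm), d.top_cm),
            )
            values[h.name] = sum(direct[donor.name]) / len(direct[donor.name])
            report.append((h.name, donor.name))
    return values, report


def biological_layer_values(
    profile: SoilProfile,
    measurements: list[HorizonMeasurement],
    parameter: str,
    window_cm: float = THICKNESS_CONVENTIONS["biological"],
) -> tuple[dict[str, float], list[tuple[str, str]]]:
    """Two-depth biological mapping over the surface window.

    Biology is sampled at a surface depth (interval starting at 0) and one
    subsurface depth.  The surface value describes the first horizon; the
    subsurface value describes every deeper horizon inside the window.
    """
    ms = [m for m in measurements if m.parameter == parameter]
    if not ms:
        raise ValueError(f"no measurements for parameter {parameter!r}")
    surface = [m for m in ms if m.top_cm == 0]
    deeper = [m for m in ms if m.top_cm > 0]
    if not surface or not deeper:
        raise ValueError(
            f"biological mapping for {parameter!r} needs one surface and one "
            "subsurface sample"
        )
    surf_val = sum(m.effective_value for m in surface) / len(surface)
    sub_val = sum(m.effective_value for m in deeper) / len(deeper)
    values: dict[str, float] = {}
    report: list[tuple[str, str]] = []
    for h in profile.horizons:
        if h.overlap_cm(0.0, window_cm) <= 0:
            continue
        if h is profile.horizons[0]:
            values[h.name] = surf_val
            report.append((h.name, "surface sample"))
        else:
            values[h.name] = sub_val
            report.append((h.name, "subsurface sample"))
    return values, report


def weighted_mean(
    profile: SoilProfile,
    values_by_horizon: dict[str, float],
    profile_thickness_cm: float,
    parameter: str = "",
) -> WeightedMeanResult:
    """Depth-thickness-weighted mean over [0, profile_thickness_cm).

    T_i is the overlap of horizon i with the averaging window, I_i its mapped
    value; Mw = sum(T_i I_i) / sum(T_i).  Raises if the horizons do not cover
    the window or a covered horizon has no value.
    """
    if profile_thickness_cm <= 0:
        raise ValueError("profile thickness must be positive")
    if profile.described_depth_cm < profile_thickness_cm - 1e-9:
        raise ValueError(
            f"profile {profile.farm_id} described to {profile.described_depth_cm} cm "
            f"does not cover the {profile_thickness_cm} cm window"
        )
    weights: list[tuple[str, float, float]] = []
    for h in profile.horizons:
        t = h.overlap_cm(0.0, profile_thickness_cm)
        if t <= 0:
            continue
        if h.name not in values_by_horizon:
            raise ValueError(
                f"profile {profile.farm_id}: horizon {h.name} overlaps the window "
                "but has no mapped value"
            )
        weights.append((h.name, t, values_by_horizon[h.name]))
    total_t = sum(t for _, t, _ in weights)
    mw = sum(t * i for _, t, i in weights) / total_t
    return WeightedMeanResult(
        parameter=parameter,
        farm_id=profile.farm_id,
        Mw=mw,
        profile_thickness_cm=total_t,
        weights_used=tuple(weights),
    )


def aggregate_parameter(
    profile: SoilProfile,
    measurements: list[HorizonMeasurement],
    parameter: str,
    family: str | None = None,
) -> WeightedMeanResult:
    """Map measurements to horizons and take the weighted mean using the
    thickness convention of the parameter's family."""
    family = family or PARAMETER_FAMILY.get(parameter)
    if family not in THICKNESS_CONVENTIONS:
        raise ValueError(f"unknown parameter family for {parameter!r}")
    thickness = THICKNESS_CONVENTIONS[family]
    if family == "biological":
        values, _ = biological_layer_values(profile, measurements, parameter, thickness)
    else:
        values, _ = map_measurements_to_horizons(profile, measurements, parameter)
    return weighted_mean(profile, values, thickness, parameter=parameter)


_STOCK_UNITS = {"g_per_kg": "kg m-2", "mg_per_kg": "g m-2"}


def nutrient_stock(
    profile: SoilProfile,
    esd_cm: float,
    bulk_density_by_horizon: dict[str, float],
    concentration_by_horizon: dict[str, float],
    unit: str = "g_per_kg",
    constituent: str = "",
) -> StockResult:
    """Mass of a constituent per unit area within the effective soil depth.

    Element basis: per horizon (truncated at the ESD),
    ``thickness_m x bulk_density (Mg m-3) x concentration``; the numeric
    product is kg m-2 for g kg-1 concentrations and g m-2 for mg kg-1.
    Not-detected concentrations must be passed as 0.
    """
    if unit not in _STOCK_UNITS:
        raise ValueError(f"unit must be one of {sorted(_STOCK_UNITS)}")
    if esd_cm <= 0:
        raise ValueError("esd_cm must be positive")
    per_horizon: list[tuple[str, float]] = []
    for h in profile.horizons:
        t_cm = h.overlap_cm(0.0, esd_cm)
        if t_cm <= 0:
            continue
        if h.name not in bulk_density_by_horizon:
            raise ValueError(f"missing bulk density for horizon {h.name}")
        if h.name not in concentration_by_horizon:
            raise ValueError(f"missing concentration for horizon {h.name}")
        contribution = (
            (t_cm / 100.0)
            * bulk_density_by_horizon[h.name]
            * concentration_by_horizon[h.name]
        )
        per_horizon.append((h.name, contribution))
    return StockResult(
        farm_id=profile.farm_id,
        constituent=constituent,
        esd_cm=esd_cm,
        stock=sum(c for _, c in per_horizon),
        unit=_STOCK_UNITS[unit],
        per_horizon=tuple(per_horizon),
    )
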