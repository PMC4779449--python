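"""Domain types, bundled study data and tabular I/O.

The study design: two long-term unfertilised vegetable farms (UF) and two
adjacent control farms (CF) on Japanese andosols, one pair at Eniwa and one at
Narita.  Each farm contributes one described soil profile (horizon boundaries
plus penetrometer compactness), replicated core physics, per-horizon chemistry,
two-depth biology, and a mean dry crop yield.  These are the inputs to every
downstream computation; they are bundled here so the whole pipeline runs
without any external file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import pandas as pd

from . import _tables

__all__ = [
    "SoilHorizon",
    "SoilProfile",
    "HorizonMeasurement",
    "YieldRecord",
    "FixtureSet",
    "SchemaError",
    "UNIT_REGISTRY",
    "load_study_fixtures",
    "read_profile_csv",
    "write_profile_csv",
]


class SchemaError(ValueError):
    """A CSV row or record violates the schema or a type invariant."""


#: parameter name -> unit string; single source of truth for unit validation.
UNIT_REGISTRY = {
    "solid": "%",
    "liquid": "%",
    "gaseous": "%",
    "P_ma": "%",
    "P_mi": "%",
    "total_pores": "%",
    "bulk_density": "Mg m-3",
    "SHC": "cm s-1",
    "void_ratio": "%",
    "fractal_dimension": "-",
    "pH_H2O": "-",
    "pH_KCl": "-",
    "pH_NaF": "-",
    "OC": "g kg-1",
    "TN": "g kg-1",
    "Ca": "cmolc kg-1",
    "Mg": "cmolc kg-1",
    "K": "cmolc kg-1",
    "Na": "cmolc kg-1",
    "CEC": "cmolc kg-1",
    "base_saturation": "%",
    "NO3_N": "mg kg-1",
    "available_P": "mg kg-1",
    "P_absorption": "mg 100g-1",
    "Al_o": "g kg-1",
    "Fe_o": "g kg-1",
    "Si_o": "g kg-1",
    "Alo_half_Feo": "%",
    "B_C": "ug g-1",
    "B_N": "ug g-1",
    "beta_glucosidase": "umol h-1 g-1",
    "protease": "umol h-1 g-1",
    "compactness": "MPa",
}


@dataclass(frozen=True)
class SoilHorizon:
    """One described horizon; depth interval is half-open [top_cm, bottom_cm)."""

    name: str
    top_cm: float
    bottom_cm: float
    compactness_MPa: float | None = None
    open_ended: bool = False

    def __post_init__(self) -> None:
        if self.top_cm < 0 or self.bottom_cm < 0:
            raise SchemaError(f"horizon {self.name}: negative depth")
        if not self.top_cm < self.bottom_cm:
            raise SchemaError(
                f"horizon {self.name}: top_cm must be < bottom_cm "
                f"({self.top_cm} >= {self.bottom_cm})"
            )

    @property
    def thickness_cm(self) -> float:
        return self.bottom_cm - self.top_cm

    @property
    def midpoint_cm(self) -> float:
        return 0.5 * (self.top_cm + self.bottom_cm)

    def overlap_cm(self, top: float, bottom: float) -> float:
        """Thickness of this horizon inside [top, bottom)."""
        return max(0.0, min(self.bottom_cm, bottom) - max(self.top_cm, top))


@dataclass(frozen=True)
class SoilProfile:
    """Ordered, contiguous horizons for one farm; the unit of aggregation."""

    farm_id: str
    horizons: tuple[SoilHorizon, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "horizons", tuple(self.horizons))
        if not self.horizons:
            raise SchemaError(f"profile {self.farm_id}: no horizons")
        if self.horizons[0].top_cm != 0:
            raise SchemaError(f"profile {self.farm_id}: first horizon must start at 0")
        for upper, lower in zip(self.horizons, self.horizons[1:]):
            if not math.isclose(upper.bottom_cm, lower.top_cm):
                raise SchemaError(
                    f"profile {self.farm_id}: non-contiguous horizons "
                    f"{upper.name} [..{upper.bottom_cm}) / {lower.name} [{lower.top_cm}..)"
                )

    @property
    def described_depth_cm(self) -> float:
        return self.horizons[-1].bottom_cm

    def horizon(self, name: str) -> SoilHorizon:
        for h in self.horizons:
            if h.name == name:
                return h
        raise KeyError(f"profile {self.farm_id}: no horizon named {name!r}")


@dataclass(frozen=True)
class HorizonMeasurement:
    """One measured value at a depth interval of a farm's profile.

    ``value is None`` together with ``not_detected`` marks an "n.d." cell;
    those contribute 0 to weighted means and stocks.
    """

    farm_id: str
    top_cm: float
    bottom_cm: float
    parameter: str
    value: float | None
    units: str = ""
    replicate_sd: float | None = None
    n_replicates: int | None = None
    not_detected: bool = False
    annotation: str = ""

    def __post_init__(self) -> None:
        if not self.top_cm < self.bottom_cm:
            raise SchemaError(
                f"measurement {self.parameter}@{self.farm_id}: bad interval "
                f"[{self.top_cm}, {self.bottom_cm})"
            )
        if self.value is None and not self.not_detected:
            raise SchemaError(
                f"measurement {self.parameter}@{self.farm_id}: missing value "
                "without not_detected flag"
            )
        if self.parameter in UNIT_REGISTRY and self.units:
            if self.units != UNIT_REGISTRY[self.parameter]:
                raise SchemaError(
                    f"measurement {self.parameter}@{self.farm_id}: unit "
                    f"{self.units!r} does not match registry "
                    f"{UNIT_REGISTRY[self.parameter]!r}"
                )

    @property
    def effective_value(self) -> float:
        """Numeric value with the not-detected convention applied (n.d. -> 0)."""
        return 0.0 if self.value is None else float(self.value)

    @property
    def midpoint_cm(self) -> float:
        return 0.5 * (self.top_cm + self.bottom_cm)


@dataclass(frozen=True)
class YieldRecord:
    farm_id: str
    dry_yield_t_ha_crop: float
    crop: str = ""

    def __post_init__(self) -> None:
        if self.dry_yield_t_ha_crop < 0:
            raise SchemaError(f"yield {self.farm_id}: negative yield")


@dataclass
class FixtureSet:
    """Everything the pipeline needs for one or more farms."""

    profiles: dict[str, SoilProfile]
    measurements: list[HorizonMeasurement]
    yields: list[YieldRecord]

    def measurements_for(
        self, farm_id: str, parameter: str | None = None
    ) -> list[HorizonMeasurement]:
        out = [m for m in self.measurements if m.farm_id == farm_id]
        if parameter is not None:
            out = [m for m in out if m.parameter == parameter]
        return out

    def yield_for(self, farm_id: str) -> YieldRecord:
        for y in self.yields:
            if y.farm_id == farm_id:
                return y
        raise KeyError(farm_id)


_STUDY_FARMS = {
    "eniwa": ("E-UF", "E-CF"),
    "narita": ("N-UF", "N-CF"),
    "all": _tables.FARMS,
}

_PHYSICAL_PARAMS = ("solid", "liquid", "gaseous", "P_ma", "P_mi", "bulk_density", "SHC")
_CHEMICAL_PARAMS = (
    "pH_H2O", "pH_KCl", "OC", "TN", "Ca", "Mg", "K", "Na",
    "CEC", "base_saturation", "NO3_N", "available_P", "P_absorption",
)
_OXALATE_PARAMS = ("pH_NaF", "Al_o", "Fe_o", "Si_o", "Alo_half_Feo")


def _meas(farm, top, bottom, parameter, value, sd=None, n=None, annotation=""):
    return HorizonMeasurement(
        farm_id=farm,
        top_cm=float(top),
        bottom_cm=float(bottom),
        parameter=parameter,
        value=None if value is None else float(value),
        units=UNIT_REGISTRY.get(parameter, ""),
        replicate_sd=sd,
        n_replicates=n,
        not_detected=value is None,
        annotation=annotation,
    )


def load_study_fixtures(study: Literal["eniwa", "narita", "all"] = "all") -> FixtureSet:
    """Return the bundled study data for one site or for all four farms.

    Idempotent; every number is a printed table cell.  Sampling-depth labels
    are stored exactly as printed per farm (they differ slightly between the
    profile description and the core schedule for some farms).
    """
    if study not in _STUDY_FARMS:
        raise ValueError(f"unknown study {study!r}")
    farms = _STUDY_FARMS[study]

    profiles = {
        farm: SoilProfile(
            farm_id=farm,
            horizons=tuple(
                SoilHorizon(name, top, bottom, compactness, open_ended)
                for name, top, bottom, compactness, open_ended in _tables.PROFILES[farm]
            ),
        )
        for farm in farms
    }

    measurements: list[HorizonMeasurement] = []
    for farm in farms:
        for row in _tables.PHYSICAL[farm]:
            horizon, top, bottom = row[0], row[1], row[2]
            values = dict(zip(_PHYSICAL_PARAMS, row[3:8] + (row[8], row[10])))
            for param, value in values.items():
                sd = row[9] if param == "bulk_density" else None
                n = 3 if param == "bulk_density" else None
                measurements.append(
                    _meas(farm, top, bottom, param, value, sd, n, annotation=horizon)
                )
        for row in _tables.CHEMISTRY[farm]:
            horizon = row[0]
            h = profiles[farm].horizon(horizon)
            for param, value in zip(_CHEMICAL_PARAMS, row[1:]):
                measurements.append(
                    _meas(farm, h.top_cm, h.bottom_cm, param, value, n=2,
                          annotation=horizon)
                )
        for row in _tables.OXALATE[farm]:
            horizon = row[0]
            h = profiles[farm].horizon(horizon)
            for param, value in zip(_OXALATE_PARAMS, row[1:]):
                measurements.append(
                    _meas(farm, h.top_cm, h.bottom_cm, param, value, annotation=horizon)
                )
        for horizon, top, bottom, micro, void_pct, fd, sig in _tables.MICROMORPHOLOGY[farm]:
            measurements.append(
                _meas(farm, top, bottom, "void_ratio", void_pct, annotation=micro)
            )
            measurements.append(
                _meas(farm, top, bottom, "fractal_dimension", fd, annotation=sig)
            )
        for horizon, top, bottom, params in _tables.BIOLOGY[farm]:
            for param, (mean, sd, sig) in params.items():
                measurements.append(
                    _meas(farm, top, bottom, param, mean, sd, 3, annotation=sig)
                )

    yields = [
        YieldRecord(farm, *(_tables.YIELDS[farm])) for farm in farms
    ]
    return FixtureSet(profiles=profiles, measurements=measurements, yields=yields)


# ---------------------------------------------------------------------------
# CSV I/O

_SCHEMAS = {
    "horizons": ["farm_id", "horizon", "top_cm", "bottom_cm", "compactness_MPa",
                 "open_ended"],
    "measurements": ["farm_id", "top_cm", "bottom_cm", "parameter", "value",
                     "units", "replicate_sd", "n_replicates"],
    "yields": ["farm_id", "dry_yield_t_ha_crop", "crop"],
}


def read_profile_csv(path, schema: Literal["horizons", "measurements", "yields"]):
    """Read one of the three tabular schemas into typed records.

    Returns a dict of :class:`SoilProfile` for ``horizons``, a list of
    :class:`HorizonMeasurement` for ``measurements`` and a list of
    :class:`YieldRecord` for ``yields``.  Round-trips with
    :func:`write_profile_csv`.
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")

    if schema == "horizons":
        profiles: dict[str, SoilProfile] = {}
        for farm_id, group in df.groupby("farm_id", sort=False):
            horizons = []
            for i, row in group.iterrows():
                try:
                    horizons.append(
                        SoilHorizon(
                            name=row["horizon"],
                            top_cm=float(row["top_cm"]),
                            bottom_cm=float(row["bottom_cm"]),
                            compactness_MPa=(
                                None if row["compactness_MPa"] == ""
                                else float(row["compactness_MPa"])
                            ),
                            open_ended=row["open_ended"].lower() in ("true", "1"),
                        )
                    )
                except (ValueError, SchemaError) as exc:
                    raise SchemaError(f"{path} row {i + 2}: {exc}") from exc
            horizons.sort(key=lambda h: h.top_cm)
            try:
                profiles[farm_id] = SoilProfile(farm_id, tuple(horizons))
            except SchemaError as exc:
                raise SchemaError(f"{path}: {exc}") from exc
        return profiles

    if schema == "measurements":
        records = []
        for i, row in df.iterrows():
            try:
                value = None if row["value"] in ("", "n.d.") else float(row["value"])
                records.append(
                    HorizonMeasurement(
                        farm_id=row["farm_id"],
                        top_cm=float(row["top_cm"]),
                        bottom_cm=float(row["bottom_cm"]),
                        parameter=row["parameter"],
                        value=value,
                        units=row["units"],
                        replicate_sd=(
                            None if row["replicate_sd"] == ""
                            else float(row["replicate_sd"])
                        ),
                        n_replicates=(
                            None if row["n_replicates"] == ""
                            else int(float(row["n_replicates"]))
                        ),
                        not_detected=value is None,
                    )
                )
            except (ValueError, SchemaError) as exc:
                raise SchemaError(f"{path} row {i + 2}: {exc}") from exc
        return records

    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                YieldRecord(
                    farm_id=row["farm_id"],
                    dry_yield_t_ha_crop=float(row["dry_yield_t_ha_crop"]),
                    crop=row["crop"],
                )
            )
        except (ValueError, SchemaError) as exc:
            raise SchemaError(f"{path} row {i + 2}: {exc}") from exc
    return records


def write_profile_csv(path, records, schema: Literal["horizons", "measurements", "yields"]) -> None:
    """Write typed records in one of the three schemas (UTF-8, comma, header)."""
    if schema == "horizons":
        if isinstance(records, dict):
            records = list(records.values())
        rows = [
            {
                "farm_id": p.farm_id,
                "horizon": h.name,
                "top_cm": h.top_cm,
                "bottom_cm": h.bottom_cm,
                "compactness_MPa": "" if h.compactness_MPa is None else h.compactness_MPa,
                "open_ended": h.open_ended,
            }
            for p in records
            for h in p.horizons
        ]
    elif schema == "measurements":
        rows = [
            {
                "farm_id": m.farm_id,
                "top_cm": m.top_cm,
                "bottom_cm": m.bottom_cm,
                "parameter": m.parameter,
                "value": "n.d." if m.value is None else repr(m.value),
                "units": m.units,
                "replicate_sd": "" if m.replicate_sd is None else repr(m.replicate_sd),
                "n_replicates": "" if m.n_replicates is None else m.n_replicates,
            }
            for m in records
        ]
    elif schema == "yields":
        rows = [
            {
                "farm_id": y.farm_id,
                "dry_yield_t_ha_crop": y.dry_yield_t_ha_crop,
                "crop": y.crop,
            }
            for y in records
        ]
    else:
        raise ValueError(f"unknown schema {schema!r}")
    pd.DataFrame(rows, columns=_SCHEMAS[schema]).to_csv(path, index=False)
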