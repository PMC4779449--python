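"""End-to-end orchestration: rebuild the derived tables and validate the
synthetic generators.

``reproduce_study`` recomputes, from the bundled raw tables only, the
study's derived surface: effective soil depths, the depth-weighted profile
means, the OC/TN nutrient stocks within the ESD and the yield correlations -- and annotates every designated cell
against the published value at its printed precision.

``run_synthetic_validation`` exercises the generator stack: analytic fractal
fixtures, void-ratio recovery, the spongy > blocky contour-complexity
ordering, and recovery of the implanted positive yield-ESD dependence over
ensembles of synthetic farms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import _tables
from .biostats import correlate_with_yield, round_half_up
from .datasets import FixtureSet, HorizonMeasurement, load_study_fixtures
from .micromorph import FdConfig, analyze_micrograph, box_count, fit_fractal_dimension
from .profile import (
    aggregate_parameter,
    effective_soil_depth,
    map_measurements_to_horizons,
    nutrient_stock,
)
from .synthetic import (
    SyntheticImageSpec,
    make_ensemble,
    make_fractal_fixture,
    make_micrograph,
)

__all__ = ["reproduce_study", "run_synthetic_validation", "write_report", "CellCheck"]

SUMMARY_PARAMETERS = [
    "bulk_density", "P_ma", "P_mi", "total_pores", "SHC", "fractal_dimension",
    "OC", "TN", "Ca", "Mg", "K", "Na", "CEC", "base_saturation", "NO3_N",
    "available_P", "B_C", "B_N", "beta_glucosidase", "protease",
]

# printed decimal places, per parameter, for match-at-printed-precision checks
_DECIMALS_MEANS = {
    "bulk_density": 2, "fractal_dimension": 2, "OC": 1, "TN": 1,
    "NO3_N": 2, "B_C": 2,
}
_DECIMALS_STOCKS = {"OC": 1, "TN": 2}

# |computed - printed| allowed for cells where the published number carries
# extra rounding of its inputs (bulk density printed to 2 dp propagates ~0.015
# into the E-UF TN stock)
_ABS_TOLERANCE = {("stocks", "TN", "E-UF"): 0.02}


@dataclass(frozen=True)
class CellCheck:
    table: str
    parameter: str
    farm: str
    computed: float
    printed: float
    match: bool


def _with_total_pores(measurements: list[HorizonMeasurement]) -> list[HorizonMeasurement]:
    """Append per-sample total porosity (P_ma + P_mi) derived measurements."""
    out = list(measurements)
    by_key: dict[tuple, dict[str, HorizonMeasurement]] = {}
    for m in measurements:
        if m.parameter in ("P_ma", "P_mi"):
            by_key.setdefault((m.farm_id, m.top_cm, m.bottom_cm), {})[m.parameter] = m
    for (farm, top, bottom), parts in by_key.items():
        if {"P_ma", "P_mi"} <= parts.keys():
            out.append(
                HorizonMeasurement(
                    farm_id=farm, top_cm=top, bottom_cm=bottom,
                    parameter="total_pores",
                    value=parts["P_ma"].effective_value + parts["P_mi"].effective_value,
                    units="%",
                )
            )
    return out


def compute_weighted_means(fixtures: FixtureSet) -> pd.DataFrame:
    """Depth-weighted profile means for every parameter and farm;
    index = parameter, columns = farm."""
    measurements = _with_total_pores(fixtures.measurements)
    data: dict[str, dict[str, float]] = {}
    for parameter in SUMMARY_PARAMETERS:
        data[parameter] = {}
        for farm, profile in fixtures.profiles.items():
            ms = [m for m in measurements if m.farm_id == farm]
            data[parameter][farm] = aggregate_parameter(profile, ms, parameter).Mw
    frame = pd.DataFrame(data).T
    cations = frame.loc[["Ca", "Mg", "K", "Na"]].sum()
    frame.loc["exchangeable_total"] = cations
    frame.loc["ESD"] = {
        farm: effective_soil_depth(profile)
        for farm, profile in fixtures.profiles.items()
    }
    return frame


def compute_stocks(fixtures: FixtureSet, constituents=("OC", "TN")) -> pd.DataFrame:
    """Element-basis nutrient stocks within the ESD, kg m-2 for
    g kg-1 constituents; index = constituent, columns = farm."""
    data: dict[str, dict[str, float]] = {c: {} for c in constituents}
    for farm, profile in fixtures.profiles.items():
        ms = fixtures.measurements_for(farm)
        esd = effective_soil_depth(profile)
        bd, _ = map_measurements_to_horizons(profile, ms, "bulk_density")
        for constituent in constituents:
            conc, _ = map_measurements_to_horizons(profile, ms, constituent)
            result = nutrient_stock(
                profile, esd, bd, conc, unit="g_per_kg", constituent=constituent
            )
            data[constituent][farm] = result.stock
    return pd.DataFrame(data).T


def compute_yield_correlations(fixtures: FixtureSet, weighted_means: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of each weighted-mean parameter (and ESD) against dry yield."""
    yields = {y.farm_id: y.dry_yield_t_ha_crop for y in fixtures.yields}
    means = {p: weighted_means.loc[p].to_dict() for p in weighted_means.index}
    results = correlate_with_yield(means, yields)
    return pd.DataFrame(
        [
            {"parameter": c.parameter, "r": c.r, "n": c.n, "p_value": c.p_value,
             "low_power": c.low_power}
            for c in results
        ]
    ).set_index("parameter")


def _check(table, parameter, farm, computed, printed, decimals) -> CellCheck:
    tol = _ABS_TOLERANCE.get((table, parameter, farm))
    if tol is not None:
        match = abs(computed - printed) <= tol
    else:
        match = round_half_up(computed, decimals) == round(printed, decimals)
    return CellCheck(table, parameter, farm, computed, printed, match)


def reproduce_study() -> dict:
    """Recompute the full derived surface and annotate the designated cells.

    Returns a bundle with the weighted-mean table, stock table, ESD row,
    correlation table, the list of :class:`CellCheck` annotations and an
    overall ``ok`` flag (True when every designated cell matches).
    """
    fixtures = load_study_fixtures("all")
    weighted_means = compute_weighted_means(fixtures)
    stocks = compute_stocks(fixtures)
    correlations = compute_yield_correlations(fixtures, weighted_means)

    checks: list[CellCheck] = []
    for parameter, farm in _tables.DESIGNATED_WEIGHTED_MEANS:
        checks.append(
            _check(
                "weighted_means", parameter, farm,
                computed=float(weighted_means.loc[parameter, farm]),
                printed=_tables.PUBLISHED_WEIGHTED_MEANS[parameter][farm],
                decimals=_DECIMALS_MEANS[parameter],
            )
        )
    for parameter, farm in _tables.DESIGNATED_STOCKS:
        checks.append(
            _check(
                "stocks", parameter, farm,
                computed=float(stocks.loc[parameter, farm]),
                printed=_tables.PUBLISHED_STOCKS[parameter][farm],
                decimals=_DECIMALS_STOCKS[parameter],
            )
        )
    for farm, printed in _tables.ESD_PRINTED.items():
        checks.append(
            _check("esd", "ESD", farm, float(weighted_means.loc["ESD", farm]), printed, 0)
        )
    r_esd = float(correlations.loc["ESD", "r"])
    checks.append(
        _check("correlation", "r_yield_esd", "all", r_esd,
               _tables.CORRELATIONS_PRINTED["ESD"], 2)
    )
    # the yield-FD correlation depends on the documented gap-mapping choice for
    # one unmeasured horizon; the published 0.84 is checked as a range
    r_fd = float(correlations.loc["fractal_dimension", "r"])
    checks.append(
        CellCheck("correlation", "r_yield_fd", "all", r_fd,
                  _tables.CORRELATIONS_PRINTED["fractal_dimension"],
                  match=0.83 <= round_half_up(r_fd, 2) <= 0.86)
    )

    return {
        "weighted_means": weighted_means,
        "stocks": stocks,
        "correlations": correlations,
        "checks": checks,
        "ok": all(c.match for c in checks),
    }


def run_synthetic_validation(seed: int = 0, n_ensembles: int = 100) -> dict:
    """Ground-truth recovery report for the synthetic generator stack."""
    if n_ensembles < 1:
        raise ValueError("need at least one ensemble")
    report: dict[str, float] = {}

    carpet = make_fractal_fixture("sierpinski_carpet", order=5)
    pairs = box_count(carpet, [3, 9, 27, 81])
    report["carpet_fd"] = fit_fractal_dimension(pairs, mode="filled").D
    square = make_fractal_fixture("filled_square", order=8)
    report["filled_square_fd"] = fit_fractal_dimension(
        box_count(square, [4, 8, 16, 32, 64, 128, 256]), mode="filled"
    ).D
    line = make_fractal_fixture("line", order=8)
    report["line_fd"] = fit_fractal_dimension(
        box_count(line, [4, 8, 16, 32, 64, 128, 256]), mode="filled"
    ).D

    errors = []
    for microstructure in ("granular", "spongy", "subangular_blocky"):
        for target in (15.0, 25.0, 35.0):
            for offset in range(3):
                mg = make_micrograph(
                    SyntheticImageSpec(
                        microstructure=microstructure, target_void_pct=target,
                        seed=seed + offset,
                    )
                )
                errors.append(abs(100.0 * mg.mask.mean() - target))
    report["void_ratio_max_abs_error_pct"] = float(max(errors))

    config = FdConfig(mode="contour")
    fd_gap = []
    for offset in range(10):
        spec = dict(target_void_pct=25.0, seed=seed + 1000 + offset)
        spongy = analyze_micrograph(
            make_micrograph(SyntheticImageSpec(microstructure="spongy", **spec)), config
        )
        blocky = analyze_micrograph(
            make_micrograph(
                SyntheticImageSpec(microstructure="subangular_blocky", **spec)
            ),
            config,
        )
        fd_gap.append(spongy["box_count"].D - blocky["box_count"].D)
    report["spongy_minus_blocky_fd_median"] = float(np.median(fd_gap))

    positive = 0
    esd_ordering = 0
    for i in range(n_ensembles):
        farms = make_ensemble(n_uf=4, n_cf=4, seed=seed + i)
        esds = np.array([effective_soil_depth(p) for p, _, _ in farms])
        yields = np.array([y.dry_yield_t_ha_crop for _, _, y in farms])
        r = float(np.corrcoef(esds, yields)[0, 1])
        positive += r > 0
        esd_ordering += esds[:4].min() > esds[4:].max()
    report["ensemble_positive_r_pct"] = 100.0 * positive / n_ensembles
    report["ensemble_esd_uf_gt_cf_pct"] = 100.0 * esd_ordering / n_ensembles
    report["n_ensembles"] = n_ensembles
    return report


def write_report(bundle: dict, outdir) -> None:
    """Write the reproduction bundle as TSVs, JSON and a plain-text summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["weighted_means"].to_csv(outdir / "weighted_means.tsv", sep="\t")
    bundle["stocks"].to_csv(outdir / "esd_stocks.tsv", sep="\t")
    bundle["correlations"].to_csv(outdir / "yield_correlations.tsv", sep="\t")
    checks = [c.__dict__ for c in bundle["checks"]]
    (outdir / "checks.json").write_text(json.dumps(checks, indent=2))
    lines = ["designated cell checks (computed vs printed):"]
    for c in bundle["checks"]:
        status = "ok " if c.match else "MISMATCH"
        lines.append(
            f"  [{status}] {c.table:12s} {c.parameter:18s} {c.farm:5s} "
            f"computed={c.computed:.4f} printed={c.printed}"
        )
    lines.append(f"overall: {'all designated cells match' if bundle['ok'] else 'MISMATCH'}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
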