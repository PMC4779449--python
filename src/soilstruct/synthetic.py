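"""Synthetic micrographs, analytic fractal fixtures and archetype profiles.

Everything downstream of raw data is testable against ground truth built
here:

* deterministic fractal fixtures with known box-counting dimension (filled
  square D = 2, one-pixel line D = 1, Sierpinski carpet D = log 8 / log 3);
* random binary textures emulating the three microstructure classes seen in
  the study's thin sections -- granular (solid grains in a void matrix),
  spongy (porous crumb network with channels) and subangular blocky (polygonal
  peds separated by thin planar voids) -- with the realized void ratio driven
  to the requested target by quantile thresholding of a continuous field;
* whole-farm archetypes: UF-like profiles (no pressure pan, soft to depth,
  organic-rich subsoil) and CF-like profiles (compacted pan below the plough
  layer, hence a thin effective soil depth), with a dry yield generated as a
  linear function of ESD plus Gaussian noise.

The yield model constants are calibrated on the four study farms (slope
~0.028 t ha-1 per cm of ESD, intercept 1.47 t ha-1, residual SD 0.34 t ha-1)
and exist to give the correlation stage a known positive dependence to
recover; they are a test harness, not a site model.

Determinism: every generator call derives one private PCG64 stream from
(seed, stream-id), so identical specs give identical output across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .datasets import HorizonMeasurement, SoilHorizon, SoilProfile, YieldRecord
from .micromorph import BinaryMicrograph

__all__ = [
    "SyntheticImageSpec",
    "SyntheticProfileSpec",
    "InfeasibleTargetError",
    "make_fractal_fixture",
    "make_micrograph",
    "make_profile",
    "make_ensemble",
    "save_micrograph",
    "YIELD_INTERCEPT_T_HA",
    "YIELD_SLOPE_T_HA_PER_CM",
    "YIELD_NOISE_SD_T_HA",
]

MAX_SIDE_PX = 8192  # pixel budget for deterministic fixtures

# dry-yield model: linear in ESD, fitted to the four study farms
YIELD_INTERCEPT_T_HA = 1.47
YIELD_SLOPE_T_HA_PER_CM = 0.028
YIELD_NOISE_SD_T_HA = 0.34

_STREAMS = {"granular": 1, "spongy": 2, "subangular_blocky": 3, "profile": 4,
            "ensemble": 5}


class InfeasibleTargetError(ValueError):
    """The requested void ratio cannot be realized for the chosen texture."""


@dataclass(frozen=True)
class SyntheticImageSpec:
    width_px: int = 256
    height_px: int = 256
    microstructure: Literal[
        "granular", "spongy", "subangular_blocky", "fractal_fixture"
    ] = "granular"
    target_void_pct: float = 25.0
    grain_size_range_px: tuple[float, float] = (6.0, 16.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 64 or self.height_px < 64:
            raise ValueError("image dimensions must be at least 64 px")
        if not 0 <= self.target_void_pct <= 100:
            raise ValueError("target_void_pct must be in [0, 100]")
        lo, hi = self.grain_size_range_px
        if not 0 < lo <= hi:
            raise ValueError("grain_size_range_px must be a positive interval")


@dataclass(frozen=True)
class SyntheticProfileSpec:
    archetype: Literal["UF_like", "CF_like"] = "UF_like"
    pan_depth_cm: tuple[float, float] | None = None
    n_horizons: int = 6
    noise_sd: float = 0.05
    seed: int = 0
    farm_id: str = ""

    def __post_init__(self) -> None:
        if self.archetype == "CF_like":
            if self.pan_depth_cm is None:
                raise ValueError("CF_like profiles require pan_depth_cm")
            top, bottom = self.pan_depth_cm
            if not 0 < top < bottom <= 100:
                raise ValueError("pan_depth_cm must lie inside (0, 100]")
        elif self.pan_depth_cm is not None:
            raise ValueError("UF_like profiles must not declare a pan")
        if self.n_horizons < 2:
            raise ValueError("need at least 2 horizons")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, _STREAMS[stream]])


# ---------------------------------------------------------------------------
# analytic fixtures

def make_fractal_fixture(
    kind: Literal["filled_square", "line", "sierpinski_carpet"], order: int
) -> BinaryMicrograph:
    """Seed-free fixture with analytically known box-counting dimension.

    ``filled_square`` / ``line`` are rendered at side 2**order so the default
    dyadic box ladder divides them exactly; the carpet is rendered at side
    3**order so counting at powers of 3 is exact.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if kind in ("filled_square", "line"):
        side = 2**order
    elif kind == "sierpinski_carpet":
        side = 3**order
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    if side > MAX_SIDE_PX:
        raise ValueError(f"order {order} exceeds the {MAX_SIDE_PX} px budget")

    if kind == "filled_square":
        mask = np.ones((side, side), dtype=bool)
    elif kind == "line":
        mask = np.zeros((side, side), dtype=bool)
        mask[0, :] = True
    else:
        cell = np.ones((1, 1), dtype=bool)
        hole = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=bool)
        for _ in range(order):
            cell = np.kron(cell, hole)
        mask = cell
    return BinaryMicrograph(mask=mask, provenance=f"fixture:{kind}(order={order})")


# ---------------------------------------------------------------------------
# texture generators

def _quantile_void(field: np.ndarray, void_frac: float, rng) -> np.ndarray:
    """Void = upper ``void_frac`` quantile of a continuous field (ties jittered)."""
    field = field + rng.uniform(0.0, 1e-6, size=field.shape)
    if void_frac <= 0:
        return np.zeros_like(field, dtype=bool)
    if void_frac >= 1:
        return np.ones_like(field, dtype=bool)
    threshold = np.quantile(field, 1.0 - void_frac)
    return field > threshold


def _granular_field(spec: SyntheticImageSpec, rng) -> np.ndarray:
    """Signed distance to the boundary of randomly packed solid discs.

    Large values = deep in the void matrix, negative = inside a grain;
    thresholding moves the grain boundaries in or out uniformly.
    """
    h, w = spec.height_px, spec.width_px
    lo, hi = spec.grain_size_range_px
    mean_area = np.pi * ((lo + hi) / 4.0) ** 2
    solid_frac = 1.0 - spec.target_void_pct / 100.0
    n_grains = max(1, int(1.6 * solid_frac * h * w / mean_area))
    discs = np.zeros((h, w), dtype=bool)
    centers = rng.uniform([0, 0], [h, w], size=(n_grains, 2))
    radii = rng.uniform(lo / 2.0, hi / 2.0, size=n_grains)
    for (cy, cx), r in zip(centers, radii):
        y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
        x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
        yy, xx = np.ogrid[y0:y1, x0:x1]
        discs[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    if discs.all() or not discs.any():
        raise InfeasibleTargetError(
            "degenerate disc packing; adjust grain sizes or target void ratio"
        )
    return ndimage.distance_transform_edt(~discs) - ndimage.distance_transform_edt(discs)


def _spongy_field(spec: SyntheticImageSpec, rng) -> np.ndarray:
    """Correlated Gaussian field; its upper tail is a crumbly channel network."""
    sigma = max(1.0, spec.grain_size_range_px[0] / 3.0)
    noise = rng.standard_normal((spec.height_px, spec.width_px))
    return ndimage.gaussian_filter(noise, sigma=sigma, mode="wrap")


def _blocky_field(spec: SyntheticImageSpec, rng) -> np.ndarray:
    """Margin between the two nearest ped seeds; small along the planar
    boundaries of a Voronoi tessellation."""
    h, w = spec.height_px, spec.width_px
    block_side = 3.0 * spec.grain_size_range_px[1]
    n_seeds = max(4, int(h * w / block_side**2))
    seeds = rng.uniform([0, 0], [h, w], size=(n_seeds, 2))
    yy, xx = np.mgrid[0:h, 0:w]
    points = np.column_stack([yy.ravel(), xx.ravel()])
    dists, _ = cKDTree(seeds).query(points, k=2)
    return -(dists[:, 1] - dists[:, 0]).reshape(h, w)  # void = upper tail


def make_micrograph(spec: SyntheticImageSpec) -> BinaryMicrograph:
    """Generate a binary texture of the requested microstructure class.

    The realized void fraction is driven to ``target_void_pct`` by quantile
    thresholding and checked to within 1 percentage point.  The
    ``fractal_fixture`` class returns a Sierpinski carpet padded to the
    requested frame (its void ratio is fixed by the construction and
    ``target_void_pct`` is ignored).
    """
    if spec.microstructure == "fractal_fixture":
        order = int(np.floor(np.log(min(spec.width_px, spec.height_px)) / np.log(3)))
        carpet = make_fractal_fixture("sierpinski_carpet", order).mask
        mask = np.zeros((spec.height_px, spec.width_px), dtype=bool)
        mask[: carpet.shape[0], : carpet.shape[1]] = carpet
        return BinaryMicrograph(
            mask=mask, provenance=f"synthetic:fractal_fixture(order={order})"
        )

    rng = _rng(spec.seed, spec.microstructure)
    field = {
        "granular": _granular_field,
        "spongy": _spongy_field,
        "subangular_blocky": _blocky_field,
    }[spec.microstructure](spec, rng)
    mask = _quantile_void(np.asarray(field, dtype=float), spec.target_void_pct / 100.0, rng)
    realized = 100.0 * mask.mean()
    if abs(realized - spec.target_void_pct) > 1.0:
        raise InfeasibleTargetError(
            f"{spec.microstructure}: realized void {realized:.2f} % misses "
            f"target {spec.target_void_pct:.2f} % by more than 1 point"
        )
    return BinaryMicrograph(
        mask=mask,
        provenance=(
            f"synthetic:{spec.microstructure}(seed={spec.seed}, "
            f"target={spec.target_void_pct}%, realized={realized:.2f}%)"
        ),
    )


def save_micrograph(path, micrograph: BinaryMicrograph) -> None:
    """Write as 8-bit PNG, 0 = solid, 255 = void."""
    from PIL import Image

    Image.fromarray(micrograph.mask.astype(np.uint8) * 255, mode="L").save(path)


# ---------------------------------------------------------------------------
# profile archetypes

def _boundaries(spec: SyntheticProfileSpec, rng) -> list[float]:
    """Interior horizon boundaries on [0, 100] cm, pan edges preserved."""
    fixed = set()
    if spec.pan_depth_cm is not None:
        fixed.update(float(v) for v in spec.pan_depth_cm if v < 100)
    interior = set(fixed)
    attempts = 0
    while len(interior) < spec.n_horizons - 1 and attempts < 1000:
        candidate = round(float(rng.uniform(5, 95)), 1)
        if all(abs(candidate - b) >= 4.0 for b in interior):
            interior.add(candidate)
        attempts += 1
    if len(interior) < spec.n_horizons - 1:
        raise ValueError("could not place the requested number of horizons")
    return sorted(interior)


_HORIZON_NAMES = ("Ap", "A1", "A2", "AB", "Bw1", "Bw2", "Bw3", "Bw4", "Bw5", "Bw6")


def make_profile(
    spec: SyntheticProfileSpec,
) -> tuple[SoilProfile, list[HorizonMeasurement], YieldRecord]:
    """Generate one archetype farm: profile, measurements and a dry yield.

    CF-like profiles are compacted (>= 0.718 MPa) exactly inside
    ``pan_depth_cm`` and soft above it, so the effective soil depth equals the
    pan top by construction; UF-like profiles are soft throughout and the ESD
    is the described depth (100 cm).  Bulk density, organic carbon, total N
    and two-depth microbial biomass C are generated per horizon with relative
    Gaussian noise ``noise_sd``; subsoil OC/TN are elevated in the UF
    archetype.  The yield is linear in ESD plus noise.
    """
    rng = _rng(spec.seed, "profile")
    farm_id = spec.farm_id or f"{spec.archetype}-{spec.seed}"
    edges = [0.0, *_boundaries(spec, rng), 100.0]
    pan = spec.pan_depth_cm
    horizons = []
    for i, (top, bottom) in enumerate(zip(edges, edges[1:])):
        in_pan = pan is not None and top >= pan[0] - 1e-9 and bottom <= pan[1] + 1e-9
        if in_pan:
            compactness = float(rng.uniform(0.9, 1.8))
        elif pan is not None and top >= pan[1] - 1e-9:
            compactness = float(rng.uniform(0.2, 0.68))
        else:
            compactness = float(rng.uniform(0.05, 0.55))
        name = _HORIZON_NAMES[i] if i < len(_HORIZON_NAMES) else f"H{i}"
        horizons.append(
            SoilHorizon(name, top, bottom, compactness, open_ended=(bottom == 100.0))
        )
    profile = SoilProfile(farm_id=farm_id, horizons=tuple(horizons))

    uf = spec.archetype == "UF_like"

    def noisy(base: float) -> float:
        return float(max(1e-3, base * (1.0 + spec.noise_sd * rng.standard_normal())))

    measurements: list[HorizonMeasurement] = []
    for h in profile.horizons:
        mid = h.midpoint_cm
        bd = 0.85 - 0.0035 * mid
        oc = (55.0 if uf else 45.0) - (0.25 if uf else 0.33) * mid
        if uf and 40 <= mid <= 80:
            oc *= 1.6  # buried organic-rich subsoil horizon
        in_pan = pan is not None and h.top_cm >= pan[0] - 1e-9 and h.bottom_cm <= pan[1] + 1e-9
        if in_pan:
            bd += 0.25
            oc *= 0.8
        for parameter, value in (
            ("bulk_density", noisy(bd)),
            ("OC", noisy(oc)),
            ("TN", noisy(oc / 15.0)),
            ("NO3_N", noisy(12.0 if uf else 6.0)),
        ):
            measurements.append(
                HorizonMeasurement(
                    farm_id=farm_id, top_cm=h.top_cm, bottom_cm=h.bottom_cm,
                    parameter=parameter, value=value,
                )
            )
    for (top, bottom), base in ((
        (0.0, 5.0), 300.0 if uf else 190.0), ((15.0, 20.0), 250.0 if uf else 130.0)):
        measurements.append(
            HorizonMeasurement(
                farm_id=farm_id, top_cm=top, bottom_cm=bottom,
                parameter="B_C", value=noisy(base), n_replicates=3,
            )
        )

    esd = profile.described_depth_cm
    for h in profile.horizons:
        if h.compactness_MPa >= 0.718:
            esd = h.top_cm
            break
    yield_value = (
        YIELD_INTERCEPT_T_HA
        + YIELD_SLOPE_T_HA_PER_CM * esd
        + YIELD_NOISE_SD_T_HA * float(rng.standard_normal())
    )
    record = YieldRecord(
        farm_id=farm_id, dry_yield_t_ha_crop=max(0.1, yield_value), crop="synthetic"
    )
    return profile, measurements, record


def make_ensemble(
    n_uf: int = 4, n_cf: int = 4, seed: int = 0, noise_sd: float = 0.05
) -> list[tuple[SoilProfile, list[HorizonMeasurement], YieldRecord]]:
    """A mixed set of UF-/CF-like farms with randomized pan placements."""
    rng = _rng(seed, "ensemble")
    farms = []
    for i in range(n_uf):
        sub = int(rng.integers(0, 2**31 - 1))
        farms.append(
            make_profile(
                SyntheticProfileSpec(
                    archetype="UF_like", noise_sd=noise_sd, seed=sub,
                    farm_id=f"UF-{i}",
                )
            )
        )
    for i in range(n_cf):
        sub = int(rng.integers(0, 2**31 - 1))
        pan_top = round(float(rng.uniform(10, 45)), 1)
        pan_bottom = round(pan_top + float(rng.uniform(8, 20)), 1)
        farms.append(
            make_profile(
                SyntheticProfileSpec(
                    archetype="CF_like", pan_depth_cm=(pan_top, pan_bottom),
                    noise_sd=noise_sd, seed=sub, farm_id=f"CF-{i}",
                )
            )
        )
    return farms
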