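"""Quantitative micromorphometry of thin-section micrographs.

Workflow: a greyscale micrograph is thresholded into a void/solid mask
(``binarize``), the void ratio is the void-pixel percentage (``void_ratio``),
the void-phase boundary is extracted (``extract_contours``), and the
box-counting curve N(eps) over a geometric ladder of box sizes is fitted in
log-log space (``box_count`` + ``fit_fractal_dimension``):

    log10 N(eps) = -D log10 eps + a

D (the absolute slope) is the box-counting fractal dimension of the structure;
higher D means a more complex, space-filling void boundary.  Two structures
are compared with an ANCOVA equal-slopes test on their log-log curves
(``compare_fd_ancova``).

Counting conventions (recorded in result provenance):

* the grid is anchored at pixel (0, 0); partial boxes at the right/bottom
  edges are counted;
* the default counting target is the CONTOUR of the void phase (4-connected
  boundary); a filled-set mode is provided for calibration fixtures;
* default box sizes are 4, 8, 16, 32, 64, 128, 256 px, clipped to the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BinaryMicrograph",
    "BoxCountResult",
    "AncovaResult",
    "FdConfig",
    "DEFAULT_BOX_SIZES",
    "load_image",
    "binarize",
    "void_ratio",
    "extract_contours",
    "box_count",
    "default_box_sizes",
    "fit_fractal_dimension",
    "compare_fd_ancova",
    "analyze_micrograph",
]

DEFAULT_BOX_SIZES = (4, 8, 16, 32, 64, 128, 256)

#: ITU-R 601 luma weights used to collapse RGB input to greyscale.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class BinaryMicrograph:
    """Boolean void/solid grid (True = void) with physical pixel size in um."""

    mask: np.ndarray
    pixel_size_um: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class BoxCountResult:
    box_sizes_px: tuple[int, ...]
    counts: tuple[int, ...]
    D: float
    intercept_a: float
    r_squared: float
    mode: str = "contour"
    offsets_strategy: str = "single grid anchored at (0,0), partial edge boxes counted"

    def as_series(self) -> pd.Series:
        return pd.Series(
            {"D": self.D, "intercept_a": self.intercept_a, "r_squared": self.r_squared}
        )


@dataclass(frozen=True)
class AncovaResult:
    f_statistic: float
    p_value: float
    df_interaction: int
    df_residual: int
    groups: tuple[str, str] = ("A", "B")


@dataclass(frozen=True)
class FdConfig:
    """Choices for ``analyze_micrograph``; defaults follow the study protocol."""

    mode: str = "contour"              # "contour" | "filled"
    box_sizes_px: tuple[int, ...] | None = None
    binarize_method: str = "otsu"      # "otsu" | "fixed"
    fixed_level: float = 128.0
    void_is: str = "bright"            # "bright" | "dark"
    pixel_size_um: float = 1.0


def load_image(path) -> np.ndarray:
    """Read PNG/TIFF/BMP as float greyscale (RGB collapsed with luma weights)."""
    from PIL import Image

    with Image.open(path) as img:
        arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    return arr.astype(float)


def binarize(
    image: np.ndarray,
    method: str = "otsu",
    level: float | None = None,
    void_is: str = "bright",
    pixel_size_um: float = 1.0,
) -> BinaryMicrograph:
    """Threshold a greyscale image into a void/solid mask.

    ``void_is`` declares which phase the bright pixels are.  Otsu is the
    default, parameter-free choice; ``method="fixed"`` uses ``level``.
    Thresholding is `>= threshold` for the bright phase.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D greyscale image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if method == "otsu":
        if np.ptp(image) == 0:
            raise ValueError("constant image: Otsu threshold is degenerate")
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(image))
        bright = image > threshold
    elif method == "fixed":
        if level is None:
            raise ValueError("fixed method requires a level")
        threshold = float(level)
        bright = image >= threshold
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    if void_is == "bright":
        mask = bright
    elif void_is == "dark":
        mask = ~bright
    else:
        raise ValueError(f"void_is must be 'bright' or 'dark', got {void_is!r}")
    return BinaryMicrograph(
        mask=mask,
        pixel_size_um=pixel_size_um,
        provenance=f"binarize(method={method}, threshold={threshold:g}, void_is={void_is})",
    )


def void_ratio(micrograph: BinaryMicrograph) -> float:
    """Void-phase pixel percentage of the whole image, in [0, 100]."""
    return 100.0 * float(np.count_nonzero(micrograph.mask)) / micrograph.mask.size


def extract_contours(micrograph: BinaryMicrograph) -> BinaryMicrograph:
    """Boundary of the void phase: void pixels 4-adjacent to solid or border."""
    mask = micrograph.mask
    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        mask
        & padded[:-2, 1:-1] & padded[2:, 1:-1]
        & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return BinaryMicrograph(
        mask=mask & ~interior,
        pixel_size_um=micrograph.pixel_size_um,
        provenance=micrograph.provenance + " | contour(4-connectivity, border=solid)",
    )


def box_count(
    target: BinaryMicrograph | np.ndarray, box_sizes_px
) -> list[tuple[int, int]]:
    """Count occupied grid boxes of side eps for each requested eps.

    The grid is anchored at pixel (0, 0); partial boxes at the right/bottom
    edges are included.  A box is counted when it contains at least one True
    pixel.
    """
    mask = target.mask if isinstance(target, BinaryMicrograph) else np.asarray(target, bool)
    if not mask.any():
        raise ValueError("empty structure: no True pixels to count")
    pairs = []
    h, w = mask.shape
    for eps in box_sizes_px:
        eps = int(eps)
        if eps < 1:
            raise ValueError(f"box size must be >= 1, got {eps}")
        ph, pw = -h % eps, -w % eps
        padded = np.pad(mask, ((0, ph), (0, pw)), constant_values=False)
        blocks = padded.reshape(padded.shape[0] // eps, eps, padded.shape[1] // eps, eps)
        n = int(blocks.any(axis=(1, 3)).sum())
        pairs.append((eps, n))
    return pairs


def default_box_sizes(shape: tuple[int, int]) -> tuple[int, ...]:
    """The protocol ladder 4..256 px clipped to the smaller image dimension."""
    limit = min(shape)
    sizes = tuple(s for s in DEFAULT_BOX_SIZES if s <= limit)
    if len(sizes) < 3:
        raise ValueError(f"image of shape {shape} too small for the default ladder")
    return sizes


def fit_fractal_dimension(
    pairs, mode: str = "contour", fit_range: tuple[int, int] | None = None
) -> BoxCountResult:
    """OLS fit of log10 N on log10 eps; D is the absolute slope.

    ``fit_range`` optionally restricts the fit to eps in [lo, hi].  R^2 is
    reported so that departures from power-law scaling are visible.
    """
    pairs = [(int(e), int(n)) for e, n in pairs]
    if fit_range is not None:
        lo, hi = fit_range
        pairs = [(e, n) for e, n in pairs if lo <= e <= hi]
    if len(pairs) < 3:
        raise ValueError("need at least 3 (eps, N) pairs to fit")
    if any(n < 1 for _, n in pairs):
        raise ValueError("all counts must be >= 1")
    eps = np.log10([e for e, _ in pairs])
    logn = np.log10([n for _, n in pairs])
    if np.ptp(logn) == 0:
        # structure fits in one box at every size: dimension 0 by convention
        slope, intercept, r2 = 0.0, float(logn[0]), 1.0
    else:
        fit = stats.linregress(eps, logn)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue) ** 2
    return BoxCountResult(
        box_sizes_px=tuple(e for e, _ in pairs),
        counts=tuple(n for _, n in pairs),
        D=-slope,
        intercept_a=intercept,
        r_squared=r2,
        mode=mode,
    )


def compare_fd_ancova(pairs_a, pairs_b, groups=("A", "B")) -> AncovaResult:
    """Equal-slopes ANCOVA on two log-log box-count curves.

    Fits log10 N ~ group + log10 eps + group x log10 eps and F-tests the
    interaction term; rejecting means the two fractal dimensions differ.
    Degenerate zero-residual designs are resolved by convention: zero
    interaction effect gives F = 0 / p = 1, a nonzero effect with zero
    residual gives F = inf / p = 0.
    """
    import statsmodels.api as sm

    if len(pairs_a) < 3 or len(pairs_b) < 3:
        raise ValueError("each group needs at least 3 (eps, N) pairs")
    if any(n < 1 for _, n in [*pairs_a, *pairs_b]):
        raise ValueError("all counts must be >= 1")
    rows = [(np.log10(e), np.log10(n), 0.0) for e, n in pairs_a]
    rows += [(np.log10(e), np.log10(n), 1.0) for e, n in pairs_b]
    df = pd.DataFrame(rows, columns=["logeps", "logn", "group"])
    x_full = sm.add_constant(
        np.column_stack(
            [df["group"], df["logeps"], df["group"] * df["logeps"]]
        )
    )
    x_red = sm.add_constant(np.column_stack([df["group"], df["logeps"]]))
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError("singular design: cannot separate group slopes")
    full = sm.OLS(df["logn"], x_full).fit()
    red = sm.OLS(df["logn"], x_red).fit()
    df_int = 1
    df_resid = int(full.df_resid)
    num = (red.ssr - full.ssr) / df_int
    scale = max(red.ssr, 1.0)
    if num <= 1e-12 * scale:
        f_stat, p = 0.0, 1.0
    elif full.ssr <= 1e-12 * scale:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = float(num / (full.ssr / df_resid))
        p = float(stats.f.sf(f_stat, df_int, df_resid))
    return AncovaResult(
        f_statistic=f_stat,
        p_value=p,
        df_interaction=df_int,
        df_residual=df_resid,
        groups=tuple(groups),
    )


def analyze_micrograph(image, config: FdConfig = FdConfig()) -> dict:
    """Full per-image analysis: binarize, void ratio, (contour,) box-count, fit.

    ``image`` may be a greyscale array or an already-binarized
    :class:`BinaryMicrograph` (in which case binarization options are ignored).
    """
    if isinstance(image, BinaryMicrograph):
        micrograph = image
    else:
        micrograph = binarize(
            image,
            method=config.binarize_method,
            level=config.fixed_level,
            void_is=config.void_is,
            pixel_size_um=config.pixel_size_um,
        )
    vr = void_ratio(micrograph)
    target = extract_contours(micrograph) if config.mode == "contour" else micrograph
    sizes = config.box_sizes_px or default_box_sizes(micrograph.shape)
    pairs = box_count(target, sizes)
    result = fit_fractal_dimension(pairs, mode=config.mode)
    return {
        "void_ratio_pct": vr,
        "box_count": result,
        "provenance": f"{micrograph.provenance} | mode={config.mode} | sizes={sizes}",
    }
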