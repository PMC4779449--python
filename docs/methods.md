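# Methods

This note records the models, conventions and judgement calls behind
`soilstruct`, in the order data flows through the pipeline.

## Study design being modelled

Four farm soils on Japanese andosols: an unfertilised farm (UF) and an
adjacent control farm (CF) at Eniwa (Hokkaido) and at Narita (Chiba). Each
farm contributes one described profile (horizon boundaries and penetrometer
compactness), three replicate 100 mL cores at five depths (physics), duplicate
chemistry per horizon, triplicate biology at two depths (0–5 and 15–20 cm),
one thin section per core depth, and a mean dry yield. All printed table
cells are bundled in `soilstruct._tables` and loaded through
`datasets.load_paper_fixtures`; nothing is fetched.

Depth conventions: cm, surface = 0, half-open intervals [top, bottom), which
makes horizon contiguity testable without double counting. Open-ended bottom
horizons ("70–100+") are stored with bottom = 100 cm and an `open_ended`
flag; no computation reads past the stated floor, which is harmless because
every averaging window stops at or above 100 cm. "n.d." (not detected) cells
are stored as an explicit marker and contribute **0** to weighted means and
stocks — the only convention that reproduces the published available-P and
protease summary cells.

## Fractal engine

* **Binarization**: Otsu on luminance by default (the original acquisition
  software is proprietary and its threshold unpublished); a fixed-level
  alternative is provided, and the chosen threshold is recorded in the result
  provenance. RGB input collapses with ITU-R 601 luma weights.
* **Counting target**: the 4-connected contour of the void phase (void pixels
  adjacent to solid or to the image border). 4-connectivity gives the
  thinnest closed boundary. A filled-set mode exists for calibration
  fixtures and for comparison with tools that count filled sets.
* **Grid**: anchored at pixel (0, 0), one offset only; partial boxes at the
  right/bottom edges are counted (excluding them biases N at large ε on
  non-divisible image sides). Default ladder ε = 4…256 px clipped to the
  image; at least three sizes are required.
* **Fit**: OLS of log₁₀N on log₁₀ε (any base gives the same D); R² is always
  reported so non-power-law scaling is visible. A structure that fits in one
  box at every size gets D = 0 by convention.
* **ANCOVA**: equal-slopes F-test on the group × log ε interaction of the
  pooled log–log regression (statsmodels OLS under the hood). Zero-residual
  degenerate designs are resolved explicitly: zero interaction effect →
  F = 0, p = 1; nonzero effect with zero residual → F = ∞, p = 0.
* The published per-image dimensions (all in 1.366–1.692) cannot be
  recomputed without the original micrographs; the engine is instead
  validated on analytic fixtures (square, line, Sierpinski carpet) and a
  brute-force per-box oracle, and the published values serve only as
  plausibility bounds for generated textures.

## Profile operations

* **ESD rule**: depth to the top of the first horizon with compactness
  ≥ 0.718 MPa (the lower bound of the fine-root limit range), i.e. strictly
  `< 0.718` remains effective. The strict comparison is deliberate: two
  horizons print exactly 0.718 MPa and must be excluded for the four
  published depths (87, 75, 40, 17 cm) to emerge. If no horizon reaches the
  limit, ESD is the described depth.
* **Spot-core mapping**: a horizon containing a core interval takes that
  value; an unmeasured horizon borrows from the measured horizon with the
  nearest midpoint (tie → shallower). The only case in the data is the
  Eniwa-CF 2A horizon (40–50 cm), which borrows from above (midpoint 35 vs
  60); the effect of the alternative (borrow from below) on downstream
  results is carried through the yield-correlation range check.
* **Weighted means**: Mw = Σ(T·I)/ΣT with windows of 75 cm (physical,
  including fractal dimension and void ratio), 100 cm (chemical) and 20 cm
  (biological); horizons are truncated at the window. The biological window
  uses the two-depth design directly: the surface sample describes the first
  horizon, the subsurface sample the remainder of the 20 cm — the only
  weighting that reproduces the published biomass-C summary cells exactly
  (321.67 and 152.88 µg g⁻¹).
* **Stocks**: element basis, Σ thickness(m) × BD(Mg m⁻³) × concentration,
  truncated at the ESD; g kg⁻¹ inputs yield kg m⁻², mg kg⁻¹ inputs g m⁻².
  This formula reproduces the published OC stocks for three of four farms
  exactly and TN within the rounding below. The published cation / nitrate /
  available-P stock cells follow no basis we could identify (oxide
  conversion fits some cells but not others) and the Narita-CF OC/TN cells
  are ≈1.9× any recomputation from the raw tables; those cells are reported
  but not treated as reproduction checks.

### Known irreproducible published cells

* TN stock for Eniwa-UF prints 2.08 kg m⁻²; the recomputation from printed
  tables gives 2.069. Bulk densities are printed to 2 decimals, which
  propagates ±0.015 into this stock, so the check uses a ±0.02 band.
* The Narita-UF biomass-C (175.28) and β-glucosidase (0.72) summary cells
  are inconsistent with the two-depth weighting that reproduces every other
  biology cell (they recompute to 176.66 and 0.91); both are excluded from
  checks.
* Narita-CF weighted OC recomputes to 32.355 — exactly on a rounding
  boundary — while 32.3 is printed; the full-table test uses a
  half-last-digit band for this reason.
* Printed significance stars in the biology table are not all recoverable
  from the printed mean ± SD (two cells disagree by one star level); the
  star-assignment test therefore checks internal consistency of the
  F-then-t procedure, and printed stars are kept as annotations.

## Statistical conventions

Two-group comparisons follow the stated protocol: two-tailed F test on the
variance ratio at α = 0.05, then pooled-variance Student t if not rejected,
otherwise Welch t ("pooled unless F rejects" is the standard reading of
"F test … Student's t test"); stars at 0.05/0.01/0.001. Yield correlations
are Pearson r with two-sided p from the t transform; with n = 4 farms there
are 2 residual df, so results carry a low-power flag and are read as
rankings, not hypothesis tests. Comparisons against printed values use
round-half-up at the printed precision.

## Synthetic generators

* **Fixtures**: filled square and one-pixel line at side 2^order, Sierpinski
  carpet at side 3^order so that counting at powers of 3 is exact — the
  carpet oracle N(3ᵏ) = 8^(order−k) removes all discretization error.
* **Textures** (what they emulate / what they are): *granular* — randomly
  packed solid discs in a void matrix, thresholded on the signed distance to
  grain boundaries; *spongy* — upper tail of a Gaussian-smoothed noise field,
  a crumbly channel network; *subangular blocky* — thin planar voids along
  the boundaries of a Voronoi tessellation (margin between the two nearest
  seeds). The realized void ratio is set by quantile thresholding of the
  continuous field (ties jittered), so it matches the target to ≪1
  percentage point by construction; a post-check raises if a degenerate
  field misses by more than 1 point. These textures reproduce the
  *qualitative* ordering seen in real sections (spongy contour D > blocky
  contour D at equal void ratio, median gap ≈ +0.18 over 20 seeds) but are
  not photorealistic: no mineral grains, no birefringence, no imaging noise,
  and single-scale structure. Passing texture tests therefore validates the
  measurement chain, not any claim about real soils.
* **Profiles**: UF-like — all horizons soft (< 0.718 MPa) to 100 cm, bulk
  density decreasing with depth, OC elevated (×1.6) in 40–80 cm to emulate
  buried organic horizons; CF-like — a compacted pan (0.9–1.8 MPa) exactly
  within `pan_depth_cm`, so ESD = pan top by construction. Horizon
  boundaries are random with a 4 cm minimum thickness; measurements get
  relative Gaussian noise (default 5 %, matching the order of the printed
  replicate CVs).
* **Yield model**: dry yield = 1.47 + 0.028·ESD + N(0, 0.34) t ha⁻¹ — the
  OLS line and residual SD of the four study farms. It is a test harness
  for sign/strength recovery, not a yield model.
* **Determinism**: each generator call derives one private PCG64 stream from
  (seed, stream-id); there is no global random state, so identical specs give
  identical output across runs and platforms.

## Problem sizes

Default texture frames are 256 × 256 px (box ladder 4…256), the carpet
oracle runs at order 5 (243 px), the box-count brute-force cross-check uses
1000 random 64 × 64 masks, and recovery statistics use 100 eight-farm
ensembles — sizes chosen so the whole validation suite completes in seconds
while leaving every scaling regime (ε from 1 to the image side) exercised.

## Limitations

* The four-farm design supports correlation only; nothing here estimates
  causal effects of management.
* Fractal dimensions depend on binarization, counting target and grid
  convention; cross-study comparison requires identical settings (all
  choices are recorded in result provenance).
* The spot-core-to-horizon mapping assumes within-horizon homogeneity.
* Stocks assume the printed bulk density applies to the whole horizon and
  ignore coarse-fragment corrections.
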