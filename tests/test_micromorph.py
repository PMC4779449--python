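"""Fractal engine: binarization, void ratio, contours, box counting, fits
and the ANCOVA slope comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soilstruct.micromorph import (
    BinaryMicrograph,
    FdConfig,
    analyze_micrograph,
    binarize,
    box_count,
    compare_fd_ancova,
    default_box_sizes,
    extract_contours,
    fit_fractal_dimension,
    void_ratio,
)
from soilstruct.synthetic import SyntheticImageSpec, make_fractal_fixture, make_micrograph


def brute_force_box_count(mask, box_sizes):
    """Independent oracle: scan every grid box pixel by pixel."""
    h, w = mask.shape
    pairs = []
    for eps in box_sizes:
        n = 0
        for i in range(0, h, eps):
            for j in range(0, w, eps):
                if mask[i : i + eps, j : j + eps].any():
                    n += 1
        pairs.append((eps, n))
    return pairs


class TestBinarize:
    def test_two_level_image_recovers_bright_phase(self):
        image = np.zeros((64, 64))
        image[:, 32:] = 255.0
        mg = binarize(image, void_is="bright")
        assert mg.mask[:, 32:].all() and not mg.mask[:, :32].any()
        dark = binarize(image, void_is="dark")
        assert np.array_equal(dark.mask, ~mg.mask)

    def test_synthetic_mask_round_trips_through_greyscale(self):
        mask = make_micrograph(
            SyntheticImageSpec(microstructure="granular", target_void_pct=24, seed=7)
        ).mask
        recovered = binarize(mask.astype(float) * 255.0, void_is="bright")
        assert np.array_equal(recovered.mask, mask)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            binarize(np.full((64, 64), 7.0))

    def test_fixed_threshold(self):
        image = np.arange(64 * 64, dtype=float).reshape(64, 64)
        mg = binarize(image, method="fixed", level=2048.0)
        assert void_ratio(mg) == 50.0


class TestVoidRatio:
    def test_all_void_and_checkerboard(self):
        full = BinaryMicrograph(np.ones((64, 64), bool))
        assert void_ratio(full) == 100.0
        checker = BinaryMicrograph(np.indices((64, 64)).sum(axis=0) % 2 == 0)
        assert void_ratio(checker) == 50.0


class TestContours:
    def test_full_image_contour_is_one_pixel_frame(self):
        mg = BinaryMicrograph(np.ones((64, 64), bool))
        contour = extract_contours(mg).mask
        frame = np.zeros((64, 64), bool)
        frame[0, :] = frame[-1, :] = frame[:, 0] = frame[:, -1] = True
        assert np.array_equal(contour, frame)

    def test_single_void_pixel_is_its_own_contour(self):
        mask = np.zeros((64, 64), bool)
        mask[10, 20] = True
        assert np.array_equal(extract_contours(BinaryMicrograph(mask)).mask, mask)

    def test_disc_contour_length_close_to_circumference(self):
        r = 40
        yy, xx = np.mgrid[0:128, 0:128]
        disc = (yy - 64) ** 2 + (xx - 64) ** 2 <= r**2
        count = extract_contours(BinaryMicrograph(disc)).mask.sum()
        assert abs(count - 2 * np.pi * r) / (2 * np.pi * r) < 0.15

    def test_all_solid_gives_empty_contour(self):
        contour = extract_contours(BinaryMicrograph(np.zeros((64, 64), bool)))
        assert not contour.mask.any()


class TestBoxCount:
    def test_single_pixel_counts_one_box_at_every_size(self):
        mask = np.zeros((64, 64), bool)
        mask[5, 9] = True
        assert box_count(mask, [4, 8]) == [(4, 1), (8, 1)]

    def test_full_mask_counts_every_box(self):
        assert box_count(np.ones((256, 256), bool), [4]) == [(4, 4096)]

    def test_carpet_order3_matches_exhaustive_enumeration(self):
        carpet = make_fractal_fixture("sierpinski_carpet", 3)
        assert box_count(carpet, [1, 3, 9]) == [(1, 512), (3, 64), (9, 8)]
        assert box_count(carpet, [1, 3, 9]) == brute_force_box_count(carpet.mask, [1, 3, 9])

    def test_partial_edge_boxes_are_counted(self):
        mask = np.ones((10, 10), bool)  # 10 not divisible by 4
        assert box_count(mask, [4]) == [(4, 9)]  # ceil(10/4)^2

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError, match="empty structure"):
            box_count(np.zeros((64, 64), bool), [4])

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((64, 64)) < rng.uniform(0.05, 0.6)
        mask[0, 0] = True
        sizes = [1, 2, 3, 5, 7, 16, 64]
        assert box_count(mask, sizes) == brute_force_box_count(mask, sizes)

    @given(seed=st.integers(0, 10_000), density=st.floats(0.01, 0.9))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_sandwich_and_coarsening_bounds(self, seed, density):
        rng = np.random.default_rng(seed)
        mask = rng.random((64, 64)) < density
        if not mask.any():
            mask[0, 0] = True
        true_px = int(mask.sum())
        pairs = dict(box_count(mask, [2, 4, 8]))
        for eps, n in pairs.items():
            assert n >= true_px / eps**2
            assert n <= min(true_px, int(np.ceil(64 / eps)) ** 2)
        # aligned dyadic grids: coarsening merges at most 4 boxes into 1
        assert pairs[4] <= pairs[2] <= 4 * pairs[4]
        assert pairs[8] <= pairs[4] <= 4 * pairs[8]


class TestFit:
    def test_exact_power_law_recovered_with_unit_r_squared(self):
        # N = 4096 eps^-1.5 is integer at eps = 1, 4, 16, 64
        pairs = [(1, 4096), (4, 512), (16, 64), (64, 8)]
        result = fit_fractal_dimension(pairs)
        assert result.D == pytest.approx(1.5, abs=1e-9)
        assert result.r_squared == pytest.approx(1.0)

    def test_structure_in_one_box_has_dimension_zero(self):
        result = fit_fractal_dimension([(4, 1), (8, 1), (16, 1)])
        assert result.D == 0.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_fractal_dimension([(4, 10), (8, 3)])

    def test_default_ladder_clipped_to_image(self):
        assert default_box_sizes((128, 200)) == (4, 8, 16, 32, 64, 128)
        with pytest.raises(ValueError):
            default_box_sizes((8, 8))


class TestAncova:
    def test_identical_groups_give_f_zero_p_one(self):
        pairs = [(e, round(10_000 * e**-1.4)) for e in (4, 8, 16, 32, 64)]
        result = compare_fd_ancova(pairs, pairs)
        assert result.f_statistic == 0.0 and result.p_value == 1.0

    def test_distinct_exact_power_laws_rejected(self):
        a = [(e, round(1e5 * e**-1.2)) for e in (4, 8, 16, 32, 64, 128, 256)]
        b = [(e, round(1e5 * e**-1.8)) for e in (4, 8, 16, 32, 64, 128, 256)]
        result = compare_fd_ancova(a, b)
        assert result.p_value < 0.05

    def test_p_uniform_under_label_permutation(self):
        """Shuffling group labels of one noisy dataset gives uniform p."""
        from scipy import stats as sps

        rng = np.random.default_rng(42)
        eps = np.array([4, 8, 16, 32, 64, 128, 256], dtype=float)
        logn = 4.0 - 1.5 * np.log10(np.tile(eps, 2)) + rng.normal(0, 0.05, 14)
        counts = np.round(10 ** logn).astype(int)
        pvals = []
        for _ in range(200):
            labels = rng.permutation(14)
            a = [(np.tile(eps, 2)[i], counts[i]) for i in labels[:7]]
            b = [(np.tile(eps, 2)[i], counts[i]) for i in labels[7:]]
            pvals.append(compare_fd_ancova(a, b).p_value)
        assert sps.kstest(pvals, "uniform").pvalue > 0.005

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            compare_fd_ancova([(4, 5), (8, 2)], [(4, 5), (8, 2), (16, 1)])


class TestAnalyzeMicrograph:
    def test_contour_dimension_within_plane_bounds(self):
        mg = make_micrograph(
            SyntheticImageSpec(microstructure="granular", target_void_pct=24, seed=7)
        )
        result = analyze_micrograph(mg, FdConfig(mode="contour"))
        assert 1.0 <= result["box_count"].D <= 2.0
        assert abs(result["void_ratio_pct"] - 24.0) <= 1.0

    @pytest.mark.parametrize("transform", [np.fliplr, np.flipud, np.rot90])
    def test_void_ratio_and_dimension_invariant_under_symmetry(self, transform):
        mg = make_micrograph(
            SyntheticImageSpec(microstructure="spongy", target_void_pct=30, seed=3)
        )
        base = analyze_micrograph(mg, FdConfig(mode="contour"))
        moved = analyze_micrograph(
            BinaryMicrograph(transform(mg.mask).copy()), FdConfig(mode="contour")
        )
        assert moved["void_ratio_pct"] == base["void_ratio_pct"]
        assert moved["box_count"].D == pytest.approx(base["box_count"].D, abs=1e-12)
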