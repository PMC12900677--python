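"""Vessel extraction, box counting (with brute-force oracle) and the
clinical preservation metrics."""

import numpy as np
import pytest
from scipy import ndimage

from vesselsr.degrade import DegradationSpec, apply_degradation
from vesselsr.errors import ContractError
from vesselsr.synthetic import (VesselTreeParams, generate_calibration,
                                generate_fundus)
from vesselsr.vascular import (box_count, classify_delta_df, delta_df,
                               extract_vessels, fractal_dimension, gain_pct,
                               improvement_pct, vci, vtp)


def brute_force_count(mask: np.ndarray, eps: int) -> int:
    """Independent nested-loop box counter (the oracle)."""
    h, w = mask.shape
    n = 0
    for y0 in range(0, h, eps):
        for x0 in range(0, w, eps):
            if mask[y0:y0 + eps, x0:x0 + eps].any():
                n += 1
    return n


class TestBoxCount:
    def test_counts_equal_brute_force_on_random_masks(self):
        rng = np.random.default_rng(0)
        for density in (0.02, 0.1, 0.5):
            mask = (rng.uniform(size=(64, 64)) < density).astype(np.uint8)
            if not mask.any():
                continue
            res = box_count(mask)
            for eps, count in zip(res.box_sizes, res.counts):
                assert count == brute_force_count(mask, eps), eps

    def test_count_properties(self, default_fundus):
        res = box_count(default_fundus.mask)
        assert res.counts[-1] == int(default_fundus.mask.sum())  # eps = 1
        assert all(a <= b for a, b in zip(res.counts, res.counts[1:]))  # N grows as eps shrinks
        assert all(c > 0 for c in res.counts)
        assert res.k == len(res.box_sizes) >= 3
        assert not res.flagged

    @pytest.mark.parametrize("pattern,iters,expected,tol", [
        ("line", 1, 1.0, 0.05),
        ("filled_square", 1, 2.0, 0.05),
        ("sierpinski", 7, np.log(3) / np.log(2), 0.08),
    ])
    def test_calibration_dimensions(self, pattern, iters, expected, tol):
        mask, _ = generate_calibration(pattern, 512, iters)
        assert box_count(mask).df == pytest.approx(expected, abs=tol)

    def test_empty_mask_and_too_few_levels_error(self):
        with pytest.raises(ContractError):
            box_count(np.zeros((64, 64), dtype=np.uint8))
        with pytest.raises(ContractError):
            box_count(np.ones((8, 8), dtype=np.uint8), min_box=4, max_box=4)

    def test_translation_invariance_on_eps_aligned_mask(self):
        mask = np.zeros((64, 64), dtype=np.uint8)
        mask[8:24, 8:24] = 1
        shifted = np.roll(np.roll(mask, 16, axis=0), 16, axis=1)
        a, b = box_count(mask), box_count(shifted)
        assert a.counts == b.counts

    def test_flip_invariance(self, default_fundus):
        mask = default_fundus.mask
        assert box_count(mask).df == pytest.approx(
            box_count(mask[:, ::-1]).df)


class TestFractalDimension:
    def test_mask_input_bypasses_extraction(self, default_fundus):
        mask = default_fundus.mask
        assert fractal_dimension(mask) == box_count(mask).df

    def test_nearest_neighbour_upscale_changes_df_little(self):
        mask, _ = generate_calibration("sierpinski", 256, 7)
        up = np.kron(mask, np.ones((2, 2), dtype=np.uint8))
        assert abs(fractal_dimension(up) - fractal_dimension(mask)) < 0.1

    def test_delta_df_identity_and_symmetry(self, default_fundus):
        img = default_fundus.image
        assert delta_df(img, img) == 0.0
        blurred = apply_degradation(
            img, DegradationSpec(kind="gaussian_blur", sigma=2.0))
        assert delta_df(img, blurred) == pytest.approx(
            delta_df(blurred, img))

    def test_heavy_blur_destroys_fine_scale_structure(self):
        mask, _ = generate_calibration("sierpinski", 256, 7)
        img = 1.0 - mask.astype(float)  # vessels dark
        blurred = apply_degradation(
            img, DegradationSpec(kind="gaussian_blur", sigma=3.0))
        assert delta_df(img, blurred) > 0.05


class TestExtraction:
    def test_dice_against_ground_truth(self, default_fundus):
        ex = extract_vessels(default_fundus.image).astype(bool)
        gt = default_fundus.mask.astype(bool)
        dice = 2 * (ex & gt).sum() / (ex.sum() + gt.sum())
        assert dice >= 0.7

    def test_constant_image_gives_empty_mask_with_warning(self):
        with pytest.warns(UserWarning, match="constant|empty"):
            mask = extract_vessels(np.full((32, 32), 0.5))
        assert mask.sum() == 0

    def test_flip_equivariance(self, default_fundus):
        img = default_fundus.image
        a = extract_vessels(np.ascontiguousarray(img[:, ::-1]))
        b = extract_vessels(img)[:, ::-1]
        assert np.array_equal(a, b)


class TestConnectivityAndTortuosity:
    def test_identity_suite(self, default_fundus):
        m = default_fundus.mask
        img = default_fundus.image
        assert delta_df(img, img) == 0.0
        assert vci(m, m) == 1.0
        assert vtp(m, m) == 1.0

    def test_vci_formula_on_cut_skeleton(self):
        m = np.zeros((32, 32), dtype=np.uint8)
        m[16, 2:30] = 1  # one straight component
        cut = m.copy()
        cut[16, 15] = 0  # two components
        assert vci(m, m) == 1.0
        assert vci(m, cut) == pytest.approx(0.5)
        assert vci(cut, m) == pytest.approx(0.5)

    def test_vci_empty_mask_errors(self):
        with pytest.raises(ContractError):
            vci(np.zeros((16, 16), dtype=np.uint8),
                np.ones((16, 16), dtype=np.uint8))

    def test_vtp_straight_line_is_one(self):
        m = np.zeros((32, 32), dtype=np.uint8)
        m[16, 2:30] = 1
        assert vtp(m, m) == 1.0

    def test_vtp_detects_straightening(self):
        wiggly = generate_fundus(
            VesselTreeParams(seed=5, tortuosity_amp=3.0)).mask
        straight = generate_fundus(
            VesselTreeParams(seed=5, tortuosity_amp=0.0)).mask
        assert vtp(wiggly, straight) < 1.0

    def test_vtp_no_branches_errors(self):
        tiny = np.zeros((16, 16), dtype=np.uint8)
        tiny[8, 7:9] = 1
        with pytest.raises(ContractError):
            vtp(tiny, tiny)


class TestClinicalBins:
    @pytest.mark.parametrize("value,label", [
        (0.0, "excellent"),
        (0.0099, "excellent"),
        (0.01, "acceptable"),
        (0.0499, "acceptable"),
        (0.05, "moderate"),
        (0.0987, "moderate"),
        (0.10, "substantial"),
        (0.1789, "substantial"),
    ])
    def test_bin_edges(self, value, label):
        assert classify_delta_df(value) == label

    def test_monotone_never_improves_with_larger_delta(self):
        order = ["excellent", "acceptable", "moderate", "substantial"]
        grid = np.linspace(0, 0.3, 61)
        ranks = [order.index(classify_delta_df(v)) for v in grid]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))

    def test_negative_rejected(self):
        with pytest.raises(ContractError):
            classify_delta_df(-0.01)


class TestReportingUtilities:
    def test_improvement_reference_values(self):
        assert improvement_pct(0.0987, 0.1189) == pytest.approx(17.0, abs=0.05)
        assert improvement_pct(0.1789, 0.2089) == pytest.approx(14.4, abs=0.05)
        assert improvement_pct(0.5, 0.5) == 0.0

    def test_gain_reference_value(self):
        assert gain_pct(0.8456, 0.8267) == pytest.approx(2.3, abs=0.05)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ContractError):
            improvement_pct(0.1, 0.0)
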