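import numpy as np
import pytest

from srintools import (
    PROBE_ROUNDS,
    MisalignmentReport,
    ProbeImageStack,
    SRINMap,
    ThresholdSpec,
    compute_normalization,
    compute_srin,
    compute_threshold,
    detect_misalignment,
    make_phantom,
    normalize_probe,
    render_stack,
    summarize_sample,
)
from srintools.core import DEFAULT_QUANTILE

from conftest import constant_stack, random_valid_stack


def brute_force_srin(stack, q):
    """Per-pixel reference implementation of the scoring transform."""
    p = {r: np.asarray(stack.round(r).pixels, float) for r in ("P0",) + PROBE_ROUNDS}
    t = float(np.quantile(p["P0"], q))
    h, w = stack.shape
    srin = np.full((h, w), np.nan)
    raw = np.full((h, w), np.nan)
    valid = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            n = p["P1"][i, j] - p["P0"][i, j] - t
            if n <= 0:
                continue
            valid[i, j] = True
            s_clip = s_raw = 0.0
            for label in PROBE_ROUNDS:
                r = (p[label][i, j] - p["P0"][i, j] - t) / n
                s_raw += max(r, 0.0)
                s_clip += min(max(r, 0.0), 1.0)
            raw[i, j] = 2.5 * s_raw
            srin[i, j] = 2.5 * s_clip
    return srin, raw, valid


class TestThreshold:
    def test_constant_background(self):
        assert compute_threshold(np.full((5, 5), 40.0), 0.75).value == 40.0

    def test_matches_sorted_quantile_oracle(self):
        p0 = np.arange(101, dtype=float).reshape(1, -1)
        spec = compute_threshold(p0, 0.75)
        assert spec.value == 75.0
        # general sorted-interpolation oracle
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 500, (10, 10))
        for q in (0.0, 0.3, 0.75, 1.0):
            srt = np.sort(vals.ravel())
            pos = q * (srt.size - 1)
            lo, hi = int(np.floor(pos)), int(np.ceil(pos))
            expect = srt[lo] + (pos - lo) * (srt[hi] - srt[lo])
            assert compute_threshold(vals, q).value == pytest.approx(expect, abs=1e-12)

    def test_default_quantile(self):
        assert DEFAULT_QUANTILE == 0.75

    def test_threshold_within_background_range(self, rng):
        vals = rng.uniform(10, 90, (20, 20))
        t = compute_threshold(vals, 0.4).value
        assert vals.min() <= t <= vals.max()

    @pytest.mark.parametrize("q", [-0.1, 1.5])
    def test_invalid_quantile(self, q):
        with pytest.raises(ValueError, match="quantile"):
            compute_threshold(np.ones((2, 2)), q)


class TestNormalization:
    def test_arithmetic(self):
        norm = compute_normalization(
            np.full((1, 2), 100.0), np.full((1, 2), 20.0), 30.0
        )
        assert norm.values[0, 0] == 50.0
        assert norm.valid_mask.all()
        neg = compute_normalization(
            np.full((1, 1), 40.0), np.full((1, 1), 20.0), 30.0
        )
        assert neg.values[0, 0] == -10.0
        assert not neg.valid_mask.any()

    def test_matches_loop_oracle(self, rng):
        p1, p0 = rng.uniform(0, 300, (9, 9)), rng.uniform(0, 100, (9, 9))
        norm = compute_normalization(p1, p0, 25.0)
        for i in range(9):
            for j in range(9):
                assert norm.values[i, j] == p1[i, j] - p0[i, j] - 25.0
                assert norm.valid_mask[i, j] == (norm.values[i, j] > 0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            compute_normalization(np.ones((2, 2)), np.ones((2, 3)), 1.0)


class TestNormalizeProbe:
    def test_probe1_self_normalizes_to_one(self, valid_stack):
        t = compute_threshold(valid_stack.round("P0"), 0.75)
        norm = compute_normalization(
            valid_stack.round("P1"), valid_stack.round("P0"), t
        )
        r1 = normalize_probe(
            valid_stack.round("P1"), valid_stack.round("P0"), t, norm
        )
        assert np.all(r1[norm.valid_mask] == 1.0)
        assert np.all(np.isnan(r1[~norm.valid_mask]))

    def test_background_level_probe_is_zero(self):
        p0 = np.full((3, 3), 20.0)
        t = ThresholdSpec(q=0.0, value=20.0)
        norm = compute_normalization(np.full((3, 3), 120.0), p0, t)
        r = normalize_probe(np.full((3, 3), 40.0), p0, t, norm)
        assert np.all(r == 0.0)

    def test_matches_division_oracle(self, rng, valid_stack):
        t = compute_threshold(valid_stack.round("P0"), 0.75)
        norm = compute_normalization(
            valid_stack.round("P1"), valid_stack.round("P0"), t
        )
        r3 = normalize_probe(
            valid_stack.round("P3"), valid_stack.round("P0"), t, norm
        )
        p3 = valid_stack.pixels("P3")
        p0 = valid_stack.pixels("P0")
        for i, j in zip(*np.nonzero(norm.valid_mask)):
            assert r3[i, j] == (p3[i, j] - p0[i, j] - t.value) / norm.values[i, j]


class TestComputeSrin:
    def test_four_probes_detected_scores_ten(self):
        m = compute_srin(constant_stack(20, 120, 120, 120, 120), q=0.0)
        assert np.all(m.srin == 10.0)

    def test_three_probes_detected_scores_seven_point_five(self):
        m = compute_srin(constant_stack(20, 120, 120, 120, 40), q=0.0)
        assert np.all(m.srin == 7.5)

    def test_one_probe_detected_scores_floor(self):
        m = compute_srin(constant_stack(20, 120, 40, 40, 40), q=0.0)
        assert np.all(m.srin == 2.5)

    def test_no_signal_masked_with_warning(self):
        with pytest.warns(UserWarning, match="no valid pixels"):
            m = compute_srin(constant_stack(20, 30, 30, 30, 30), q=1.0)
        assert not m.valid_mask.any()
        assert np.all(np.isnan(m.srin))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(3):
            stack = random_valid_stack(rng, (32, 32))
            m = compute_srin(stack, q=0.6)
            srin_o, raw_o, valid_o = brute_force_srin(stack, 0.6)
            np.testing.assert_array_equal(m.valid_mask, valid_o)
            np.testing.assert_allclose(
                m.srin[valid_o], srin_o[valid_o], rtol=1e-12, atol=0
            )
            np.testing.assert_allclose(
                m.raw[valid_o], raw_o[valid_o], rtol=1e-12, atol=0
            )

    def test_clipped_score_bounds_on_valid_pixels(self, rng):
        stack = random_valid_stack(rng)
        m = compute_srin(stack)
        v = m.srin[m.valid_mask]
        assert v.size and np.all((v >= 2.5) & (v <= 10.0))

    def test_misaligned_mask_subset_of_valid(self, rng):
        stack = random_valid_stack(rng)
        m = compute_srin(stack)
        assert not np.any(m.misaligned_mask & ~m.valid_mask)
        np.testing.assert_array_equal(
            m.misaligned_mask[m.valid_mask], m.raw[m.valid_mask] > 10.0
        )


class TestDetectMisalignment:
    def test_no_flags_zero_statistic(self):
        m = compute_srin(constant_stack(20, 120, 120, 120, 120), q=0.0)
        rep = detect_misalignment(m, grid_size=2)
        assert rep.flagged_fraction == 0.0
        assert rep.statistic == 0.0
        assert rep.p_value == 1.0

    def test_concentrated_flags_match_hand_chi_square(self):
        """All 40 flags in one quadrant of a 2x2 grid with equal valid counts.

        Expected 10 per cell; statistic = (30^2 + 3 * 10^2) / 10 = 120.
        """
        h = w = 20
        valid = np.ones((h, w), dtype=bool)
        flagged = np.zeros((h, w), dtype=bool)
        flagged[:10, :4] = True  # 40 pixels, all in the top-left cell
        srin = np.full((h, w), 5.0)
        m = SRINMap(
            srin=srin,
            raw=np.where(flagged, 11.0, 5.0),
            valid_mask=valid,
            misaligned_mask=flagged,
            ratios={r: srin for r in PROBE_ROUNDS},
            threshold=ThresholdSpec(0.75, 1.0),
        )
        rep = detect_misalignment(m, grid_size=2)
        assert rep.flagged_fraction == 40 / 400
        assert rep.statistic == pytest.approx(120.0)
        assert rep.dof == 3
        assert rep.p_value < 1e-20
        assert rep.grid_counts.sum() == 40

    def test_shift_increases_flagged_fraction(self):
        phantom = make_phantom((96, 96), seed=21)
        stack0, _ = render_stack(phantom, seed=22)
        stack5, _ = render_stack(phantom, offsets={"P2": (5, 0)}, seed=22)
        f0 = detect_misalignment(compute_srin(stack0)).flagged_fraction
        f5 = detect_misalignment(compute_srin(stack5)).flagged_fraction
        assert f5 > f0

    def test_no_valid_pixels_rejected(self):
        with pytest.warns(UserWarning):
            m = compute_srin(constant_stack(20, 30, 30, 30, 30), q=1.0)
        with pytest.raises(ValueError, match="no valid pixels"):
            detect_misalignment(m)

    def test_report_frame_shape(self, rng):
        m = compute_srin(random_valid_stack(rng))
        rep = detect_misalignment(m, grid_size=4)
        df = rep.to_frame()
        assert len(df) == 16
        assert df["valid"].sum() == int(m.valid_mask.sum())


class TestSummarizeSample:
    def test_single_uniform_replicate(self):
        m = compute_srin(constant_stack(20, 120, 120, 120, 120), q=0.0)
        assert summarize_sample([m]).averaged_srin == 10.0

    def test_mean_of_medians(self):
        m1 = compute_srin(constant_stack(20, 120, 120, 120, 40), q=0.0)  # 7.5
        m2 = compute_srin(constant_stack(20, 120, 120, 120, 120), q=0.0)  # 10
        s = summarize_sample([m1, m2])
        assert s.replicate_medians == [7.5, 10.0]
        assert s.averaged_srin == 8.75

    def test_matches_sort_based_median_oracle(self, rng):
        maps = [compute_srin(random_valid_stack(rng)) for _ in range(3)]
        s = summarize_sample(maps)
        for med, m in zip(s.replicate_medians, maps):
            vals = np.sort(m.srin[m.scoring_mask])
            n = vals.size
            expect = (
                vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
            )
            assert med == pytest.approx(expect, abs=1e-12)

    def test_empty_replicate_identified(self):
        good = compute_srin(constant_stack(20, 120, 120, 120, 120), q=0.0)
        with pytest.warns(UserWarning):
            bad = compute_srin(constant_stack(20, 30, 30, 30, 30), q=1.0)
        with pytest.raises(ValueError, match="replicate 1"):
            summarize_sample([good, bad])
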