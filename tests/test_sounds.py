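"""Envelopes, dynamic-threshold segmentation, contrast and fusion."""

import numpy as np
import pytest

from gastroscg import (SoundSegmentation, compute_contrast,
                       compute_envelopes, fuse_detections, segment_sounds)
from gastroscg.synthetic import _burst

RATE = 400.0


def _two_burst_cycle(rate=RATE, n=280, s1=(0.10, 0.15), s2=(0.35, 0.12),
                     noise=0.0, seed=0):
    t = np.arange(n) / rate
    x = (_burst(t, s1[0], s1[1], 25.0)
         + 0.6 * _burst(t, s2[0], s2[1], 25.0))
    if noise:
        x = x + noise * np.random.default_rng(seed).standard_normal(n)
    return x


class TestEnvelopes:
    def test_unit_peak_and_parity(self):
        x = _two_burst_cycle()
        a1, s1 = compute_envelopes(x, RATE)
        a2, s2 = compute_envelopes(-x, RATE)
        assert a1.max() == pytest.approx(1.0)
        assert s1.max() == pytest.approx(1.0)
        assert np.array_equal(a1, a2) and np.array_equal(s1, s2)

    def test_gabor_fwhm_matches_analytic(self):
        fs, sig = 400.0, 0.03
        t = np.arange(-0.5, 0.5, 1 / fs)
        g = np.exp(-0.5 * (t / sig) ** 2) * np.sin(2 * np.pi * 25 * t)
        abs_env, _ = compute_envelopes(g, fs)
        fwhm = np.sum(abs_env >= 0.5) / fs
        analytic = 2 * np.sqrt(2 * np.log(2)) * sig
        assert fwhm == pytest.approx(analytic, rel=0.20)

    def test_all_zero_cycle_fatal(self):
        with pytest.raises(ValueError):
            compute_envelopes(np.zeros(100), RATE)


class TestSegmentSounds:
    def test_two_burst_cycle_ordering(self):
        x = _two_burst_cycle()
        for env in compute_envelopes(x, RATE):
            seg = segment_sounds(env, RATE, r_time=0.05)
            assert seg is not None
            assert seg.t1 < 0.10 + 0.15 and seg.t2 > 0.10
            assert seg.t2 <= seg.t3 < 0.35 + 0.12 and seg.t4 > 0.35
            assert seg.t0 <= seg.t1 < seg.t2 <= seg.t3 < seg.t4 <= seg.t5

    def test_burst_before_r_peak_fails(self):
        t = np.arange(280) / RATE
        x = _burst(t, 0.02, 0.1, 25.0)   # only energy before r_time
        env, _ = compute_envelopes(x, RATE)
        assert segment_sounds(env, RATE, r_time=0.15) is None

    def test_flat_low_envelope_fails_all_thresholds(self):
        env = np.full(280, 0.05)
        assert segment_sounds(env, RATE, r_time=0.05) is None

    def test_boundaries_near_burst_extent(self):
        """Refined crossings sit close to the true burst support."""
        x = _two_burst_cycle()
        env, _ = compute_envelopes(x, RATE)
        seg = segment_sounds(env, RATE, r_time=0.05)
        assert seg.t1 == pytest.approx(0.10, abs=0.03)
        assert seg.t2 == pytest.approx(0.25, abs=0.03)


class TestContrast:
    def test_known_std_ratio(self):
        rate = 100.0
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        x[100:200] *= 2.0    # S1 twice the background std
        seg = SoundSegmentation(0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
        c1, c2 = compute_contrast(x, seg, rate)
        assert c1 == pytest.approx(
            np.std(x[100:200]) / np.std(np.r_[x[200:300], x[400:500]]))
        assert c2 == pytest.approx(1.0, abs=0.3)

    def test_constant_cycle_infinite_sentinel(self):
        seg = SoundSegmentation(0.0, 1.0, 2.0, 3.0, 4.0, 5.0)
        c1, c2 = compute_contrast(np.ones(500), seg, 100.0)
        assert np.isinf(c1) and np.isinf(c2)

    def test_monotone_in_background_noise(self):
        meds = []
        for noise in (0.02, 0.1, 0.3):
            vals = []
            for seed in range(10):
                x = _two_burst_cycle(noise=noise, seed=seed)
                env, _ = compute_envelopes(x, RATE)
                seg = segment_sounds(env, RATE, r_time=0.05)
                if seg is None:
                    vals.append(0.0)
                    continue
                try:
                    c1, _ = compute_contrast(x, seg, RATE)
                except ValueError:   # degenerate background
                    c1 = 0.0
                vals.append(min(c1, 1e6))
            meds.append(np.median(vals))
        assert meds[0] >= meds[1] >= meds[2]


class TestFusion:
    def _cycles(self):
        return {a: (_two_burst_cycle(), RATE)
                for a in ("acc_x", "acc_y", "acc_z", "acc_n")}

    def test_identical_candidates_fuse_to_common_value(self):
        seg = SoundSegmentation(0.0, 0.10, 0.24, 0.34, 0.46, 0.70)
        fused = fuse_detections([seg, seg, seg], self._cycles())
        assert fused.t1 == pytest.approx(seg.t1, abs=1e-9)
        assert fused.t4 == pytest.approx(seg.t4, abs=1e-9)

    def test_hand_computed_weighted_mean(self):
        """Two candidates with relevance 3 vs 1 fuse at the 3:1 point."""
        x = _two_burst_cycle()
        cyc = {"acc_x": (x, RATE)}
        a = SoundSegmentation(0.0, 0.10, 0.24, 0.34, 0.46, 0.70, source="a")
        b = SoundSegmentation(0.0, 0.20, 0.26, 0.36, 0.47, 0.70, source="b")
        ca = compute_contrast(x, a, RATE)
        cb = compute_contrast(x, b, RATE)
        fused = fuse_detections([a, b], cyc)
        w = np.array([min(ca[0], 1e6), min(cb[0], 1e6)])
        expect_t1 = (w[0] * 0.10 + w[1] * 0.20) / w.sum()
        assert fused.t1 == pytest.approx(expect_t1, abs=1e-9)

    def test_low_contrast_candidate_discarded(self):
        """A candidate placed on pure background is ignored everywhere."""
        good = SoundSegmentation(0.0, 0.10, 0.24, 0.34, 0.46, 0.70,
                                 source="good")
        # 'sounds' in background zones: contrast << 2 on every axis
        bad = SoundSegmentation(0.0, 0.26, 0.31, 0.50, 0.60, 0.70,
                                source="bad")
        fused = fuse_detections([good, bad], self._cycles())
        assert fused.t1 == pytest.approx(good.t1, abs=1e-6)
        assert fused.t3 == pytest.approx(good.t3, abs=1e-6)

    def test_all_discarded_returns_none(self):
        bad = SoundSegmentation(0.0, 0.26, 0.31, 0.50, 0.60, 0.70)
        assert fuse_detections([bad], self._cycles()) is None

    def test_fused_inside_convex_hull(self, clean_cohort):
        for item in clean_cohort:
            res = item["res"]
            if res.fused is None:
                continue
            for attr in ("t1", "t2", "t3", "t4"):
                vals = [getattr(c, attr) for c in res.candidates]
                v = getattr(res.fused, attr)
                assert min(vals) - 1e-9 <= v <= max(vals) + 1e-9
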