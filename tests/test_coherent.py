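"""Cycle padding, dominant-group selection, phase alignment, outliers."""

import numpy as np
import pytest

from gastroscg import (PipelineConfig, ScenarioConfig, coherent_mean,
                       dominant_group, generate_recording, pad_cycles,
                       phase_align_acc, remove_outlier_cycles, run_pipeline)
from gastroscg.coherent import _mean_pairwise_r
from gastroscg.qrs import CycleSet


def _cycleset(lengths, rate=400.0):
    rng = np.random.default_rng(0)
    return CycleSet(channel_id="t", onsets=np.arange(len(lengths)) * 1.0,
                    cycles=[rng.standard_normal(n) for n in lengths],
                    r_offset=0.05, hr_bpm=60.0, rate=rate)


class TestPadCycles:
    def test_median_length_rule(self):
        C, valid = pad_cycles(_cycleset([400, 500, 600]))
        assert C.shape == (3, 500)
        assert list(valid) == [400, 500, 500]
        assert np.all(C[0, 400:] == 0.0)

    def test_single_and_equal_lengths_unchanged(self):
        C, _ = pad_cycles(_cycleset([300]))
        assert C.shape == (1, 300)
        cs = _cycleset([250, 250, 250])
        C, _ = pad_cycles(cs)
        for i in range(3):
            assert np.array_equal(C[i], cs.cycles[i])


class TestDominantGroup:
    def test_identical_cycles_all_members(self):
        c = np.sin(np.linspace(0, 6, 100))
        C = np.tile(c, (10, 1))
        g = dominant_group(C, max_lag=3)
        assert g.members.size == 10
        assert np.allclose(g.corrs, 1.0)

    def test_brute_force_pairwise_oracle(self):
        """8 copies of waveform A + 2 uncorrelated: members are the A's."""
        rng = np.random.default_rng(7)
        t = np.linspace(0, 1, 120)
        a = np.exp(-0.5 * ((t - 0.3) / 0.04) ** 2)
        C = np.vstack([a + 0.05 * rng.standard_normal(120)
                       for _ in range(8)]
                      + [rng.standard_normal(120) for _ in range(2)])
        g = dominant_group(C, rho=0.6, max_lag=0)
        assert sorted(g.members) == list(range(8))
        # oracle: full pairwise zero-lag correlation matrix
        R = np.corrcoef(C)
        med = np.array([np.median(np.delete(R[i], i)) for i in range(10)])
        assert g.template_idx == int(np.argmax(med))
        oracle_members = np.flatnonzero(R[g.template_idx] > 0.6)
        assert np.array_equal(np.sort(g.members), oracle_members)

    def test_uncorrelated_pair_leaves_template_only(self):
        x = np.sin(np.linspace(0, 2 * np.pi, 64))
        y = np.cos(np.linspace(0, 2 * np.pi, 64))
        g = dominant_group(np.vstack([x, y]), rho=0.6, max_lag=0)
        assert g.members.size == 1
        assert g.members[0] == g.template_idx


class TestPhaseAlign:
    def _cycles_with_jitter(self, jitters, rate=400.0):
        m = int(0.7 * rate)
        t = np.arange(m) / rate
        def cyc(j):
            return (np.sin(2 * np.pi * 25 * (t - 0.08 - j))
                    * np.exp(-0.5 * ((t - 0.12 - j) / 0.03) ** 2)
                    + 0.5 * np.sin(2 * np.pi * 25 * (t - 0.38))
                    * np.exp(-0.5 * ((t - 0.42) / 0.025) ** 2))
        return np.vstack([cyc(j) for j in jitters]), m

    def test_injected_jitter_recovered_within_one_sample(self):
        rate = 400.0
        jit = np.array([0.0, 0.010, -0.015, 0.005, -0.0075])
        C, m = self._cycles_with_jitter(jit, rate)
        s1 = (0, int(0.3 * rate))
        s2 = (int(0.3 * rate), m)
        A, shifts = phase_align_acc(C, 0, s1, s2, max_lag=20)
        for k, j in enumerate(jit):
            assert abs(shifts[k][0] - round(j * rate)) <= 1

    def test_zero_jitter_zero_lags(self):
        C, m = self._cycles_with_jitter([0.0] * 4)
        A, shifts = phase_align_acc(C, 0, (0, m // 2), (m // 2, m), 20)
        assert all(s == (0, 0) for s in shifts)
        assert np.array_equal(A, C)

    def test_saturation_at_max_lag_without_correlation_loss(self):
        """Jitter beyond max_lag: exhaustive scan picks the bound."""
        rate = 400.0
        C, m = self._cycles_with_jitter([0.0, 0.040], rate)
        max_lag = 8   # 20 ms < 40 ms injected
        s1, s2 = (0, int(0.3 * rate)), (int(0.3 * rate), m)
        before = _mean_pairwise_r(C)
        A, shifts = phase_align_acc(C, 0, s1, s2, max_lag)
        assert abs(shifts[1][0]) <= max_lag
        # exhaustive-lag oracle within the bound
        best = max(range(-max_lag, max_lag + 1), key=lambda l: np.corrcoef(
            np.roll(C[1], -l)[s1[0]:s1[1]], C[0][s1[0]:s1[1]])[0, 1])
        assert shifts[1][0] in (best, 0)
        assert _mean_pairwise_r(A) >= before - 1e-12


class TestOutlierCycles:
    def test_energy_outlier_removed(self):
        C = np.vstack([np.ones((9, 50)), np.full((1, 50), np.sqrt(50.0))])
        kept = remove_outlier_cycles(C)
        assert list(kept) == list(range(9))

    def test_equal_energies_all_kept(self):
        C = np.ones((5, 40))
        assert remove_outlier_cycles(C).size == 5

    def test_near_equal_energies_all_kept(self):
        C = np.vstack([np.ones(30), np.ones(30), np.full(30, 1.005)])
        assert remove_outlier_cycles(C).size == 3

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        C = rng.standard_normal((12, 60))
        C[3] *= 9.0
        kept = remove_outlier_cycles(C)
        again = remove_outlier_cycles(C, kept)
        assert np.array_equal(kept, again)


class TestCoherentMean:
    def test_single_member_is_that_cycle(self):
        C = np.vstack([np.arange(10.0), np.arange(10.0)[::-1]])
        cm = coherent_mean(C, np.array([0]))
        assert np.array_equal(cm.mean_cycle, C[0])
        assert cm.coherent_fraction == 50.0

    def test_noise_floor_scales_as_inverse_sqrt_n(self):
        t = np.arange(280) / 400.0
        tmpl = np.exp(-0.5 * ((t - 0.05) / 0.008) ** 2)
        sigma = 0.3 * np.std(tmpl)
        for N in (4, 16):
            ratios = []
            for s in range(20):
                rng = np.random.default_rng(100 + s)
                C = tmpl + sigma * rng.standard_normal((N, t.size))
                g = dominant_group(C, max_lag=3)
                cm = coherent_mean(C, g.members)
                resid = cm.mean_cycle - tmpl
                ratios.append(np.sqrt(np.mean(resid ** 2))
                              / (sigma / np.sqrt(N)))
            assert np.median(ratios) <= 1.2

    def test_no_members_is_an_error(self):
        with pytest.raises(ValueError):
            coherent_mean(np.ones((3, 10)), np.array([], dtype=int))


class TestPipelineAlignment:
    def test_alignment_never_reduces_intercycle_correlation(self,
                                                            clean_cohort):
        for item in clean_cohort[:5]:
            res = item["res"]
            for axis, cm in res.acc_means.items():
                cs = res.cyclesets[axis]
                C, _ = pad_cycles(cs)
                before = _mean_pairwise_r(C)
                after = _mean_pairwise_r(cm.aligned_cycles)
                assert after >= before - 1e-9
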