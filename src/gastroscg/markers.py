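"""Hemodynamic markers, time-profiles and reference validation.

From the fused sound boundaries: systole runs from the start of S1 to
the start of S2 (t1 to t3) and diastole is the remainder of the cycle,
so systole + diastole equals the total cycle duration by construction.
Peak-to-peak amplitudes inside each sound window are taken per axis on
the coherent mean cycle and condensed into the Euclidean norm across
the available axes — which also keeps recordings missing an axis
usable.

Time-profiles track the markers through a recording: sound durations
over a sliding window of four cardiac cycles (the mean cycle inside the
window is re-segmented and re-fused), peak-to-peak values over a
two-cycle window.  Profiles from the implant can be compared with a
reference channel via Pearson correlation, and QRS detections are
validated with the 50-ms centered-window matching rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coherent import CoherentMean, average_cycleset
from .qrs import CycleSet, RPeakSeries
from .sounds import SoundSegmentation, compute_envelopes, fuse_detections, \
    segment_sounds

__all__ = [
    "MarkerSet", "TimeProfile", "QrsValidation",
    "derive_markers", "duration_profile", "p2p_profile",
    "validate_qrs", "profile_correlation",
]


@dataclass
class MarkerSet:
    hr_bpm: float
    total_cycle_ms: float
    systole_ms: float
    diastole_ms: float
    s1_duration_ms: float
    s2_duration_ms: float
    p2p_s1: dict = field(default_factory=dict)   # per axis, input units
    p2p_s2: dict = field(default_factory=dict)
    p2p_s1_norm: float = float("nan")
    p2p_s2_norm: float = float("nan")
    missing_axes: tuple = ()


@dataclass
class TimeProfile:
    times: np.ndarray        # window-center seconds
    values: np.ndarray
    window_cycles: int
    marker_id: str


@dataclass
class QrsValidation:
    tp: int
    fp: int
    fn: int
    jitter_ms_mean: float
    jitter_ms_sd: float

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else float("nan")

    @property
    def positive_predictivity(self) -> float:
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else float("nan")


def _window_p2p(cycle: np.ndarray, rate: float, ta: float, tb: float) -> float:
    a, b = int(round(ta * rate)), int(round(tb * rate))
    seg = cycle[max(0, a): min(cycle.size, b)]
    if seg.size == 0:
        return float("nan")
    return float(seg.max() - seg.min())


def derive_markers(fused: SoundSegmentation, cycle_len_s: float,
                   hr_bpm: float,
                   acc_means: dict[str, CoherentMean]) -> MarkerSet:
    """Durations and peak-to-peak amplitudes from a fused segmentation."""
    systole = fused.t3 - fused.t1
    diastole = cycle_len_s - systole
    p2p_s1, p2p_s2 = {}, {}
    missing = []
    for axis in ("acc_x", "acc_y", "acc_z", "acc_n"):
        cm = acc_means.get(axis)
        if cm is None:
            missing.append(axis)
            continue
        p2p_s1[axis] = _window_p2p(cm.mean_cycle, cm.rate, fused.t1, fused.t2)
        p2p_s2[axis] = _window_p2p(cm.mean_cycle, cm.rate, fused.t3, fused.t4)
    norm = lambda d: float(np.sqrt(np.nansum(
        [v ** 2 for v in d.values()]))) if d else float("nan")
    return MarkerSet(
        hr_bpm=hr_bpm,
        total_cycle_ms=1e3 * cycle_len_s,
        systole_ms=1e3 * systole,
        diastole_ms=1e3 * diastole,
        s1_duration_ms=1e3 * fused.s1_duration,
        s2_duration_ms=1e3 * fused.s2_duration,
        p2p_s1=p2p_s1, p2p_s2=p2p_s2,
        p2p_s1_norm=norm(p2p_s1), p2p_s2_norm=norm(p2p_s2),
        missing_axes=tuple(missing),
    )


def _subset(cs: CycleSet, sl: slice) -> CycleSet:
    return CycleSet(channel_id=cs.channel_id, onsets=cs.onsets[sl],
                    cycles=cs.cycles[sl], r_offset=cs.r_offset,
                    hr_bpm=cs.hr_bpm, rate=cs.rate)


def duration_profile(acc_cycles: dict[str, CycleSet], window_cycles: int = 4,
                     rho: float = 0.6, max_lag_s: float = 0.05
                     ) -> dict[str, TimeProfile]:
    """Sliding-window global S1/S2 duration profiles.

    Per window: coherent mean per axis, candidate segmentations on both
    envelopes, contrast-weighted fusion — the recording-level chain at
    window scale.  Windows advance by one cycle; a window whose fusion
    fails contributes no point.
    """
    any_cs = next(iter(acc_cycles.values()))
    n_cyc = len(any_cs)
    if n_cyc < window_cycles:
        raise ValueError(
            f"need >= {window_cycles} cycles, have {n_cyc}")
    times, s1_vals, s2_vals = [], [], []
    for start in range(n_cyc - window_cycles + 1):
        sl = slice(start, start + window_cycles)
        means, cyc_map, cands = {}, {}, []
        for axis, cs in acc_cycles.items():
            cm = average_cycleset(_subset(cs, sl), is_acc=True, rho=rho,
                                  max_lag_s=max_lag_s)
            if cm is None:
                continue
            means[axis] = cm
            cyc_map[axis] = (cm.mean_cycle[: cm.valid_len], cm.rate)
            try:
                envs = compute_envelopes(cm.mean_cycle[: cm.valid_len],
                                         cm.rate)
            except ValueError:
                continue
            for env, tag in zip(envs, ("abs", "sqr")):
                seg = segment_sounds(env, cm.rate, cm.r_offset,
                                     source=f"{axis}:{tag}")
                if seg is not None:
                    cands.append(seg)
        if not cands:
            continue
        fused = fuse_detections(cands, cyc_map)
        if fused is None:
            continue
        center = float(np.mean(any_cs.onsets[sl] + any_cs.r_offset))
        times.append(center)
        s1_vals.append(fused.s1_duration)
        s2_vals.append(fused.s2_duration)
    t = np.asarray(times)
    return {
        "s1": TimeProfile(t, np.asarray(s1_vals), window_cycles,
                          "s1_duration"),
        "s2": TimeProfile(t.copy(), np.asarray(s2_vals), window_cycles,
                          "s2_duration"),
    }


def p2p_profile(acc_means: dict[str, CoherentMean],
                fused: SoundSegmentation, onsets: np.ndarray,
                r_offset: float, window_cycles: int = 2
                ) -> dict[tuple[str, str], TimeProfile]:
    """Sliding mean of per-cycle peak-to-peak values per axis and sound.

    Per-cycle p2p is measured on the phase-aligned individual cycles
    inside the fused sound windows (a two-cycle window cannot support
    envelope re-segmentation, so the recording-level boundaries apply).
    """
    out = {}
    r_times = np.asarray(onsets) + r_offset
    for axis, cm in acc_means.items():
        if cm is None:
            continue
        members = cm.member_idx
        if members.size < window_cycles:
            continue
        for sound, (ta, tb) in (("s1", (fused.t1, fused.t2)),
                                ("s2", (fused.t3, fused.t4))):
            per_cycle = np.array([
                _window_p2p(cm.aligned_cycles[i], cm.rate, ta, tb)
                for i in members])
            times, vals = [], []
            for s in range(members.size - window_cycles + 1):
                w = per_cycle[s: s + window_cycles]
                times.append(float(np.mean(r_times[members[s: s + window_cycles]])))
                vals.append(float(np.nanmean(w)))
            out[(axis, sound)] = TimeProfile(
                np.asarray(times), np.asarray(vals), window_cycles,
                f"p2p_{sound}")
    return out


def validate_qrs(test: RPeakSeries, ref: RPeakSeries,
                 tol_s: float = 0.05, centered: bool = True) -> QrsValidation:
    """Match detections to reference instants and count TP/FP/FN.

    A detection is a true positive when it lies within a centered
    window of ``tol_s`` (i.e. +/- tol/2) around an unmatched reference
    instant; matching is greedy, one-to-one, in time order.  With
    ``centered=False`` the full-width reading (+/- tol) is used.
    """
    half = tol_s / 2 if centered else tol_s
    t, rf = np.asarray(test.times), np.asarray(ref.times)
    i = j = tp = 0
    jit = []
    while i < rf.size and j < t.size:
        d = t[j] - rf[i]
        if abs(d) <= half:
            tp += 1
            jit.append(abs(d))
            i += 1
            j += 1
        elif d < 0:
            j += 1
        else:
            i += 1
    fp = t.size - tp
    fn = rf.size - tp
    jit_ms = 1e3 * np.asarray(jit)
    return QrsValidation(
        tp=tp, fp=fp, fn=fn,
        jitter_ms_mean=float(jit_ms.mean()) if tp else float("nan"),
        jitter_ms_sd=float(jit_ms.std()) if tp else float("nan"),
    )


def profile_correlation(p: TimeProfile, ref: TimeProfile,
                        max_dt_s: float = 1.0,
                        method: str = "pearson") -> float:
    """Correlation of two time-profiles after nearest-neighbor pairing.

    Points are paired to the nearest reference window center within
    ``max_dt_s`` (about one cardiac cycle).  Returns NaN when fewer
    than three pairs exist or either side has zero variance.
    """
    if p.times.size == 0 or ref.times.size == 0:
        return float("nan")
    xs, ys = [], []
    for t, v in zip(p.times, p.values):
        k = int(np.argmin(np.abs(ref.times - t)))
        if abs(ref.times[k] - t) <= max_dt_s:
            xs.append(v)
            ys.append(ref.values[k])
    x, y = np.asarray(xs), np.asarray(ys)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    if method == "spearman":
        from scipy.stats import spearmanr
        return float(spearmanr(x, y).statistic)
    return float(np.corrcoef(x, y)[0, 1])
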