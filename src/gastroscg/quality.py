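"""Three-stage quality classification and beat-level SNR.

A recording survives analysis only if (1) it has at least three
coherent cycles on the ECG and on at least one accelerometer axis,
(2) some axis shows both S1 and S2 contrast strictly above 2, and
(3) none of its S1/S2 duration or peak-to-peak markers is a cohort
outlier (three scaled MADs from the median).

Beat SNR follows

    SNR = 10 * log10( S^2 / ( (1/M) * sum |x_m|^2 ) )   [dB]

with S the signal-portion value (R-peak amplitude for ECG; the peak
absolute amplitude of S1 or S2 for ACC) and x_1..x_M the noise-only
samples (ECG: the inter-wave zones between QRS, T and P; ACC: the gap
between S1 and S2).  Recording SNR is the mean over beats.  ECG SNR is
reported on both filter configurations: "QRS-ECG" (20-50 Hz) and
"TP-ECG" (5-50 Hz, P/T waves preserved).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import Waveform, mad_outlier_mask
from .qrs import RPeakSeries
from .sounds import SoundSegmentation

__all__ = [
    "BeatSnrInput", "QualityReport", "EcgNoiseZones",
    "snr_beat", "snr_ecg_recording", "snr_acc_recording",
    "stage1_gate", "stage2_gate", "stage3_gate",
]


@dataclass
class BeatSnrInput:
    S: float                  # signal-portion value, input units
    noise: np.ndarray         # noise-only samples, input units

    def __post_init__(self) -> None:
        self.noise = np.asarray(self.noise, dtype=float)
        if self.noise.size < 1:
            raise ValueError("need at least one noise sample")
        if not math.isfinite(self.S):
            raise ValueError("signal value must be finite")


def snr_beat(inp: BeatSnrInput) -> float:
    """Beat SNR in dB; +/-inf sentinels for silent noise / zero signal."""
    p_noise = float(np.mean(np.abs(inp.noise) ** 2))
    if p_noise == 0:
        return float("inf")
    if inp.S == 0:
        return float("-inf")
    return 10.0 * math.log10(inp.S ** 2 / p_noise)


@dataclass
class EcgNoiseZones:
    """Per-beat exclusion zones isolating the inter-wave noise segments.

    The QRS zone is R +/- ``qrs_half_s``; the T zone spans
    ``[R + t_start_s, R + t_end_s]`` scaled by RR/0.8 (T latency tracks
    cycle length); the P zone precedes the next R.  What remains of the
    beat is noise-only.
    """

    qrs_half_s: float = 0.06
    t_start_s: float = 0.15
    t_end_s: float = 0.40
    p_start_s: float = 0.20   # before next R
    p_end_s: float = 0.08     # before next R


def _beat_noise_mask(n: int, rate: float, r0: float, r1: float,
                     zones: EcgNoiseZones, t_offset: float) -> np.ndarray:
    """Noise-sample mask for the beat spanning [r0, r1) seconds."""
    i = lambda t: int(round((t - t_offset) * rate))
    mask = np.zeros(n, dtype=bool)
    a, b = max(0, i(r0)), min(n, i(r1))
    mask[a:b] = True
    rr = r1 - r0
    scale = rr / 0.8
    excl = [
        (r0 - zones.qrs_half_s, r0 + zones.qrs_half_s),
        (r0 + zones.t_start_s * scale, r0 + zones.t_end_s * scale),
        (r1 - zones.p_start_s, r1 - zones.p_end_s),
        (r1 - zones.qrs_half_s, r1 + zones.qrs_half_s),
    ]
    for (ta, tb) in excl:
        mask[max(0, i(ta)): max(0, min(n, i(tb)))] = False
    return mask


def _finite_mean(vals: list[float]) -> float:
    finite = [v for v in vals if math.isfinite(v)]
    return float(np.mean(finite)) if finite else float("nan")


def snr_ecg_recording(ecg_tp: Waveform, ecg_qrs: Waveform, r: RPeakSeries,
                      zones: EcgNoiseZones | None = None
                      ) -> tuple[float, float]:
    """Mean beat SNR of the recording on the TP and QRS band signals."""
    if len(r) < 2:
        raise ValueError("need at least two R peaks (one full beat)")
    zones = zones or EcgNoiseZones()
    out = []
    for w in (ecg_tp, ecg_qrs):
        beat_snrs = []
        for r0, r1 in zip(r.times[:-1], r.times[1:]):
            mask = _beat_noise_mask(w.n, w.rate, r0, r1, zones, w.t0_offset)
            if not mask.any():
                continue  # zones swallowed the whole beat; skip it
            ridx = int(round((r0 - w.t0_offset) * w.rate))
            if not 0 <= ridx < w.n:
                continue
            s = abs(w.samples[ridx])
            beat_snrs.append(snr_beat(BeatSnrInput(s, w.samples[mask])))
        out.append(_finite_mean(beat_snrs))
    return out[0], out[1]


def snr_acc_recording(acc_means: dict, fused: SoundSegmentation
                      ) -> dict[str, tuple[float, float]]:
    """Per-axis (S1, S2) SNR averaged over the coherent beats.

    ``acc_means`` maps axis name to a :class:`~gastroscg.coherent.CoherentMean`;
    each member cycle is one beat.  Signal = peak |amplitude| inside the
    fused sound window; noise = the samples strictly between S1 and S2.
    """
    out = {}
    for axis, cm in acc_means.items():
        if cm is None:
            continue
        fs = cm.rate
        i1, i2 = int(round(fused.t1 * fs)), int(round(fused.t2 * fs))
        i3, i4 = int(round(fused.t3 * fs)), int(round(fused.t4 * fs))
        s1_vals, s2_vals = [], []
        for idx in cm.member_idx:
            cyc = cm.aligned_cycles[idx]
            gap = cyc[i2:i3]
            if gap.size == 0:
                continue
            for (a, b), dest in (((i1, i2), s1_vals), ((i3, i4), s2_vals)):
                seg = cyc[a:b]
                if seg.size == 0:
                    continue
                s = float(np.max(np.abs(seg)))
                dest.append(snr_beat(BeatSnrInput(s, gap)))
        out[axis] = (_finite_mean(s1_vals), _finite_mean(s2_vals))
    return out


# ----------------------------------------------------------- gates ----

def stage1_gate(ecg_coherent_n: int, acc_coherent_n: dict[str, int],
                min_cycles: int = 3, acc_reading: str = "count"
                ) -> bool:
    """Coherent-cycle floor: >=3 on the ECG and on at least one ACC axis.

    ``acc_reading="count"`` requires ``min_cycles`` coherent cycles on
    some axis; ``"any"`` is the laxer grammatical reading needing only
    one coherent cycle on some axis.
    """
    if ecg_coherent_n < min_cycles:
        return False
    if not acc_coherent_n:
        return False
    floor = min_cycles if acc_reading == "count" else 1
    return any(n >= floor for n in acc_coherent_n.values())


def stage2_gate(contrasts: dict[str, tuple[float, float]],
                min_contrast: float = 2.0) -> bool:
    """Sound-contrast gate: some axis with both contrasts strictly > 2."""
    return any(c1 > min_contrast and c2 > min_contrast
               for c1, c2 in contrasts.values())


def stage3_gate(marker_table: np.ndarray, n_mad: float = 3.0) -> np.ndarray:
    """Cohort-level outlier removal on the four sound markers.

    ``marker_table`` has one row per recording and columns
    (s1_duration, s2_duration, p2p_s1, p2p_s2).  A recording is removed
    when ANY column flags it as a scaled-MAD outlier.  With fewer than
    three recordings the gate keeps everything (no usable spread).
    Returns a keep-mask.
    """
    tbl = np.atleast_2d(np.asarray(marker_table, dtype=float))
    n = tbl.shape[0]
    if n < 3:
        return np.ones(n, dtype=bool)
    removed = np.zeros(n, dtype=bool)
    for j in range(tbl.shape[1]):
        col = tbl[:, j]
        ok = np.isfinite(col)
        flag = np.zeros(n, dtype=bool)
        flag[ok] = mad_outlier_mask(col[ok], n_mad)
        removed |= flag
    return ~removed


@dataclass
class QualityReport:
    stage1_pass: bool = False
    stage2_pass: bool = False
    stage3_pass: bool | None = None   # cohort-level; None until evaluated
    ecg_coherent_pct: float = float("nan")
    acc_coherent_pct: dict = field(default_factory=dict)
    s1_contrast: dict = field(default_factory=dict)
    s2_contrast: dict = field(default_factory=dict)
    snr: dict = field(default_factory=dict)   # e.g. {"TP_ECG": dB, "S1:acc_x": dB}
    hr_bpm: float = float("nan")
    mean_intercycle_r: float = float("nan")

    @property
    def rejection_stage(self) -> int | None:
        if not self.stage1_pass:
            return 1
        if not self.stage2_pass:
            return 2
        if self.stage3_pass is False:
            return 3
        return None

    @property
    def preserved(self) -> bool:
        return bool(self.stage1_pass and self.stage2_pass
                    and self.stage3_pass is not False)
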