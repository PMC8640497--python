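"""Synthetic gastric-site ECG + 3-axis accelerometer recordings.

The generator emulates the phenomenology of 30-s acquisitions from a
gastric implant, with full ground truth for every event it synthesizes:

* sinus-rhythm ECG built from Gaussian P-QRS-T lobes, with truncated
  Gaussian R-R jitter (a deliberately simple rhythm model — enough for
  median-R-R heart-rate estimation, not a physiological HRV model);
* S1 and S2 as Tukey-windowed sinusoid bursts (~25 Hz carrier, inside
  the 20-40 Hz analysis band) at configurable latencies after each R
  peak, with independent beat-to-beat latency jitter emulating
  preload/afterload/inotropy variation;
* a constant gravity vector along a fixed implant orientation, so the
  derived norm axis behaves like a projection of the vibration vector
  (|g + s| ~ |g| + u.s for |s| << g);
* baseline wander from respiration (~0.3 Hz) and the gastric slow wave
  (~0.05 Hz), broadband white noise, and high-amplitude band-limited
  artifact bursts ("growls") hitting the accelerometer hard and the
  ECG electrodes weakly;
* a saturating startup transient in the first second, emulating the
  amplifier recovery after wake-up from the low-power mode.

Output is deterministic for a fixed (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt, windows

from .core import Recording, Waveform
from .io import compute_norm_axis

__all__ = ["ScenarioConfig", "GroundTruth", "generate_recording",
           "inject_artifacts"]


@dataclass
class ScenarioConfig:
    duration_s: float = 30.0
    ecg_rate: float = 1000.0
    acc_rate: float = 4000.0
    seed: int = 0

    # rhythm
    hr_bpm: float = 90.0
    rr_jitter_s: float = 0.03       # iid truncated-Gaussian R-R jitter sd

    # ECG morphology (amplitudes in a.u., R peak = 1)
    p_amp: float = 0.15
    q_amp: float = -0.15
    r_amp: float = 1.0
    s_amp: float = -0.25
    t_amp: float = 0.30

    # heart sounds
    s1_latency_s: float = 0.03      # onset after R
    s1_duration_s: float = 0.15
    s2_latency_s: float = 0.30
    s2_duration_s: float = 0.12
    carrier_hz: float = 25.0
    s1_amp: tuple = (1.0, 0.8, 0.6)  # per measured axis, device units
    s2_rel_amp: float = 0.6          # S2 amplitude as a fraction of S1
    latency_jitter_s: float = 0.005  # beat-to-beat sd, both sounds

    # baseline and noise
    gravity: float = 9.81
    orientation: tuple = (0.36, 0.48, 0.80)   # unit implant attitude
    resp_hz: float = 0.3
    resp_amp_ecg: float = 2.0
    resp_amp_acc: float = 2.0
    slow_hz: float = 0.05
    slow_amp_ecg: float = 3.0
    slow_amp_acc: float = 3.0
    noise_sd_ecg: float = 0.03
    noise_sd_acc: float = 0.05

    # growl bursts
    burst_rate_per_min: float = 2.0
    burst_duration_s: float = 2.0
    burst_amp_acc: float = 20.0      # multiples of the peak S1 amplitude
    burst_band_acc: tuple = (5.0, 25.0)
    burst_amp_ecg: float = 1.0       # a.u. on the ECG electrodes
    burst_band_ecg: tuple = (5.0, 15.0)

    # startup transient
    startup_amp: float = 20.0
    startup_tau_s: float = 0.2
    startup_rail: float = 15.0

    def validate(self) -> None:
        if min(self.duration_s, self.ecg_rate, self.acc_rate,
               self.hr_bpm, self.s1_duration_s, self.s2_duration_s,
               self.carrier_hz) <= 0:
            raise ValueError("rates and durations must be > 0")
        if self.s1_latency_s + self.s1_duration_s >= self.s2_latency_s:
            raise ValueError("S1 must end before S2 starts")


@dataclass
class GroundTruth:
    """Per-event truth for one synthesized recording.

    ``p2p_s1``/``p2p_s2`` hold the peak-to-peak of the clean in-band
    (20-40 Hz) vibration component per beat and axis — the quantity the
    amplitude markers are defined on; ``p2p_s1_raw``/``p2p_s2_raw``
    hold the raw unfiltered burst peak-to-peak.
    """

    r_times: np.ndarray
    s1_windows: np.ndarray           # (n_beats, 2) start/end, s
    s2_windows: np.ndarray
    p2p_s1: dict = field(default_factory=dict)   # axis -> per-beat p2p
    p2p_s2: dict = field(default_factory=dict)
    p2p_s1_raw: dict = field(default_factory=dict)
    p2p_s2_raw: dict = field(default_factory=dict)
    burst_intervals: list = field(default_factory=list)
    hr_bpm: float = float("nan")


def _gauss(t: np.ndarray, c: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - c) / sigma) ** 2)


def _burst(t: np.ndarray, onset: float, dur: float, f: float) -> np.ndarray:
    """Tukey(0.5)-windowed sinusoid burst on [onset, onset + dur]."""
    w = np.zeros_like(t)
    i0 = np.searchsorted(t, onset)
    i1 = np.searchsorted(t, onset + dur)
    if i1 <= i0:
        return w
    tt = t[i0:i1] - onset
    win = windows.tukey(i1 - i0, alpha=0.5)
    w[i0:i1] = win * np.sin(2 * np.pi * f * tt)
    return w


def _bandlimited_noise(rng, n: int, rate: float,
                       band: tuple[float, float]) -> np.ndarray:
    x = rng.standard_normal(n)
    sos = butter(4, band, btype="bandpass", fs=rate, output="sos")
    y = sosfiltfilt(sos, x)
    peak = np.max(np.abs(y))
    return y / peak if peak > 0 else y


def generate_recording(cfg: ScenarioConfig,
                       rec_id: str = "synthetic"
                       ) -> tuple[Recording, GroundTruth]:
    """Synthesize one recording plus its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    t_ecg = np.arange(int(cfg.duration_s * cfg.ecg_rate)) / cfg.ecg_rate
    t_acc = np.arange(int(cfg.duration_s * cfg.acc_rate)) / cfg.acc_rate

    # --- rhythm -------------------------------------------------------
    mean_rr = 60.0 / cfg.hr_bpm
    r_times = []
    t = 1.2  # first beat after the startup transient
    while t < cfg.duration_s - 0.2:
        r_times.append(t)
        jit = np.clip(rng.normal(0.0, cfg.rr_jitter_s),
                      -3 * cfg.rr_jitter_s, 3 * cfg.rr_jitter_s)
        t += max(0.3, mean_rr + jit)
    r_times = np.asarray(r_times)
    n_beats = r_times.size

    # --- ECG ----------------------------------------------------------
    ecg = np.zeros_like(t_ecg)
    for i, r in enumerate(r_times):
        rr = (r_times[i + 1] - r) if i + 1 < n_beats else mean_rr
        scale = rr / 0.8
        for amp, c, sig in (
            (cfg.p_amp, r - 0.16, 0.022),
            (cfg.q_amp, r - 0.02, 0.008),
            (cfg.r_amp, r, 0.010),
            (cfg.s_amp, r + 0.02, 0.008),
            (cfg.t_amp, r + 0.275 * scale, 0.040),
        ):
            ecg += amp * _gauss(t_ecg, c, sig)

    # --- heart sounds (clean per-axis vibration components) -----------
    s1_amps = np.asarray(cfg.s1_amp, dtype=float)
    s2_amps = cfg.s2_rel_amp * s1_amps
    u = np.asarray(cfg.orientation, dtype=float)
    u = u / np.linalg.norm(u)
    s1_on = r_times + cfg.s1_latency_s + np.clip(
        rng.normal(0, cfg.latency_jitter_s, n_beats),
        -3 * cfg.latency_jitter_s, 3 * cfg.latency_jitter_s)
    s2_on = r_times + cfg.s2_latency_s + np.clip(
        rng.normal(0, cfg.latency_jitter_s, n_beats),
        -3 * cfg.latency_jitter_s, 3 * cfg.latency_jitter_s)
    vib = np.zeros((3, t_acc.size))
    for i in range(n_beats):
        b1 = _burst(t_acc, s1_on[i], cfg.s1_duration_s, cfg.carrier_hz)
        b2 = _burst(t_acc, s2_on[i], cfg.s2_duration_s, cfg.carrier_hz)
        for k in range(3):
            vib[k] += s1_amps[k] * b1 + s2_amps[k] * b2
    # ground-truth p2p: per beat/axis on the clean vibration component;
    # the in-band variant passes the clean signal through the 20-40 Hz
    # analysis band (zero phase), since that is the band the amplitude
    # markers are defined on.  The norm axis uses the gravity
    # linearization |g + s| ~ |g| + u.s, i.e. the projection u.vib.
    sos_acc = butter(5, 40.0, btype="lowpass", fs=cfg.acc_rate, output="sos")
    sos_acc_hp = butter(5, 20.0, btype="highpass", fs=cfg.acc_rate,
                        output="sos")
    clean = {("acc_x", "acc_y", "acc_z")[k]: vib[k] for k in range(3)}
    clean["acc_n"] = (u[:, None] * vib).sum(axis=0)
    inband = {a: sosfiltfilt(sos_acc, sosfiltfilt(sos_acc_hp, x))
              for a, x in clean.items()}
    axes4 = ("acc_x", "acc_y", "acc_z", "acc_n")
    p2p_s1 = {a: np.zeros(n_beats) for a in axes4}
    p2p_s2 = {a: np.zeros(n_beats) for a in axes4}
    p2p_s1_raw = {a: np.zeros(n_beats) for a in axes4}
    p2p_s2_raw = {a: np.zeros(n_beats) for a in axes4}
    for i in range(n_beats):
        for (on, dur, band, raw) in (
            (s1_on[i], cfg.s1_duration_s, p2p_s1, p2p_s1_raw),
            (s2_on[i], cfg.s2_duration_s, p2p_s2, p2p_s2_raw),
        ):
            i0 = int(on * cfg.acc_rate)
            i1 = min(t_acc.size, int((on + dur) * cfg.acc_rate))
            if i1 <= i0:
                continue
            for a in axes4:
                seg = inband[a][i0:i1]
                band[a][i] = seg.max() - seg.min()
                seg = clean[a][i0:i1]
                raw[a][i] = seg.max() - seg.min()

    # --- baseline, noise, startup ------------------------------------
    ph = rng.uniform(0, 2 * np.pi, size=4)
    ecg += cfg.resp_amp_ecg * np.sin(2 * np.pi * cfg.resp_hz * t_ecg + ph[0])
    ecg += cfg.slow_amp_ecg * np.sin(2 * np.pi * cfg.slow_hz * t_ecg + ph[1])
    ecg += cfg.noise_sd_ecg * rng.standard_normal(t_ecg.size)
    acc = np.empty_like(vib)
    for k in range(3):
        acc[k] = (vib[k] + cfg.gravity * u[k]
                  + cfg.resp_amp_acc * u[k]
                  * np.sin(2 * np.pi * cfg.resp_hz * t_acc + ph[2])
                  + cfg.slow_amp_acc * u[k]
                  * np.sin(2 * np.pi * cfg.slow_hz * t_acc + ph[3])
                  + cfg.noise_sd_acc * rng.standard_normal(t_acc.size))
    if cfg.startup_amp > 0:
        ecg += cfg.startup_amp * np.exp(-t_ecg / cfg.startup_tau_s)
        np.clip(ecg, -cfg.startup_rail, cfg.startup_rail, out=ecg)
        for k in range(3):
            acc[k] += cfg.startup_amp * np.exp(-t_acc / cfg.startup_tau_s)

    wav = lambda x, r: Waveform(x, r)
    ax, ay, az = (wav(acc[k], cfg.acc_rate) for k in range(3))
    rec = Recording(id=rec_id, ecg=wav(ecg, cfg.ecg_rate),
                    acc_x=ax, acc_y=ay, acc_z=az,
                    acc_n=compute_norm_axis(ax, ay, az),
                    meta={"synthetic": "1", "seed": str(cfg.seed)})
    gt = GroundTruth(
        r_times=r_times,
        s1_windows=np.column_stack([s1_on, s1_on + cfg.s1_duration_s]),
        s2_windows=np.column_stack([s2_on, s2_on + cfg.s2_duration_s]),
        p2p_s1=p2p_s1, p2p_s2=p2p_s2,
        p2p_s1_raw=p2p_s1_raw, p2p_s2_raw=p2p_s2_raw,
        hr_bpm=60.0 / mean_rr,
    )

    # --- growl bursts -------------------------------------------------
    n_bursts = int(round(cfg.burst_rate_per_min * cfg.duration_s / 60.0))
    if n_bursts > 0 and cfg.burst_amp_acc > 0:
        starts = np.sort(rng.uniform(1.0, cfg.duration_s
                                     - cfg.burst_duration_s, n_bursts))
        intervals = [(float(s), float(s + cfg.burst_duration_s))
                     for s in starts]
        rec, gt = inject_artifacts(
            rec, gt, intervals,
            amp_acc=cfg.burst_amp_acc * float(s1_amps.max()),
            band_acc=cfg.burst_band_acc,
            amp_ecg=cfg.burst_amp_ecg, band_ecg=cfg.burst_band_ecg,
            rng=rng)
    return rec, gt


def inject_artifacts(rec: Recording, gt: GroundTruth,
                     intervals: list[tuple[float, float]],
                     amp_acc: float, band_acc: tuple = (5.0, 25.0),
                     amp_ecg: float = 0.0, band_ecg: tuple = (5.0, 15.0),
                     rng=None) -> tuple[Recording, GroundTruth]:
    """Add band-limited high-amplitude artifact bursts to a recording.

    Bursts are added on the measured accelerometer axes (the norm axis
    is re-derived) and, when ``amp_ecg`` > 0, on the ECG.  Intervals
    reaching past the record end are clipped.
    """
    rng = rng or np.random.default_rng(0)
    chans = {k: w.samples.copy() for k, w in rec.channels().items()
             if k != "acc_n"}
    gt_intervals = list(gt.burst_intervals)
    for (a, b) in intervals:
        b = min(b, rec.ecg.t0_offset + rec.ecg.duration)
        if b <= a:
            continue
        gt_intervals.append((a, b))
        for name, x in chans.items():
            w = rec.channels()[name]
            amp = amp_ecg if name == "ecg" else amp_acc
            band = band_ecg if name == "ecg" else band_acc
            if amp <= 0:
                continue
            i0 = int(round((a - w.t0_offset) * w.rate))
            i1 = int(round((b - w.t0_offset) * w.rate))
            i0, i1 = max(0, i0), min(x.size, i1)
            if i1 - i0 < 16:
                continue
            noise = _bandlimited_noise(rng, i1 - i0, w.rate, band)
            taper = windows.tukey(i1 - i0, alpha=0.2)
            x[i0:i1] += amp * taper * noise
    new = {k: rec.channels()[k].copy_with(samples=v)
           for k, v in chans.items()}
    measured = [new.get(a) for a in ("acc_x", "acc_y", "acc_z")
                if new.get(a) is not None]
    acc_n = compute_norm_axis(*measured) if measured else None
    out = Recording(id=rec.id, ecg=new["ecg"],
                    acc_x=new.get("acc_x"), acc_y=new.get("acc_y"),
                    acc_z=new.get("acc_z"), acc_n=acc_n,
                    start_time=rec.start_time, meta=dict(rec.meta))
    return out, replace(gt, burst_intervals=gt_intervals)
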