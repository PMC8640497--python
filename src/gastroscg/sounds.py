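"""S1/S2 segmentation on coherent-mean accelerometer cycles.

Each coherent mean cycle is peak-normalized and reduced to two smoothed
envelopes — absolute value ("Abs") and square ("Sqr").  A dynamic
threshold scanned downward from 0.7 to 0.1 locates the dominant S1 lobe
in the first half of the cycle (never earlier than the R peak), then S2
between the end of S1 and the end of the cycle; the sound boundaries
``t1..t4`` are the envelope crossing points.  Every axis x envelope
combination yields a candidate segmentation; candidates are fused into
the final boundaries by a contrast-weighted average, where the contrast
of a segmentation is the ratio of the standard deviation inside the
sound to that of the background (the union of ``t2-t3`` and ``t4-t5``).

Cycle landmarks: t0 cycle start (from ECG), t1/t2 start/end of S1,
t3/t4 start/end of S2, t5 end of cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "SoundSegmentation",
    "compute_envelopes", "segment_sounds", "compute_contrast",
    "fuse_detections",
]


@dataclass
class SoundSegmentation:
    """Cycle landmarks in seconds from cycle start."""

    t0: float
    t1: float
    t2: float
    t3: float
    t4: float
    t5: float
    source: str = ""               # "<axis>:<envelope>" or "fused"
    s1_contrast: float = float("nan")
    s2_contrast: float = float("nan")
    per_axis_contrast: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ok = (self.t0 <= self.t1 < self.t2 <= self.t3 < self.t4 <= self.t5)
        if not ok:
            raise ValueError(
                f"landmark ordering violated: "
                f"{self.t0:.4f} <= {self.t1:.4f} < {self.t2:.4f} <= "
                f"{self.t3:.4f} < {self.t4:.4f} <= {self.t5:.4f}"
            )

    @property
    def s1_duration(self) -> float:
        return self.t2 - self.t1

    @property
    def s2_duration(self) -> float:
        return self.t4 - self.t3


def compute_envelopes(mean_cycle: np.ndarray, rate: float,
                      smooth_s: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed Abs and Sqr envelopes of the peak-normalized cycle.

    A 20-ms moving average removes the 20-40 Hz carrier ripple while
    staying far below the ~150 ms sound durations; each envelope is then
    rescaled to unit peak so that the 0.1-0.7 dynamic threshold is
    expressed as a fraction of the strongest lobe.
    """
    x = np.asarray(mean_cycle, dtype=float)
    peak = np.max(np.abs(x))
    if peak == 0:
        raise ValueError("all-zero cycle: nothing to normalize")
    x = x / peak
    win = max(1, int(round(smooth_s * rate)))
    abs_env = uniform_filter1d(np.abs(x), win)
    sqr_env = uniform_filter1d(x * x, win)
    abs_env /= abs_env.max()
    sqr_env /= sqr_env.max()
    return abs_env, sqr_env


def _regions(above: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) index pairs."""
    d = np.diff(above.astype(int), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def _find_sound(env: np.ndarray, lo: int, hi_onset: int, hi: int,
                thresholds: np.ndarray,
                refine_floor: float | None) -> tuple[int, int] | None:
    """Locate one sound lobe inside ``[lo, hi)``.

    The lobe is the supra-threshold region found at the highest
    threshold whose onset falls in ``[lo, hi_onset)``; its boundaries
    are then widened to the ``refine_floor`` crossings (the full extent
    of the lobe) without leaving ``[lo, hi)``.
    """
    seg = env[:hi]
    for thr in thresholds:
        cands = [(a, b) for (a, b) in _regions(seg >= thr)
                 if lo <= a < hi_onset]
        if not cands:
            continue
        a, b = max(cands, key=lambda ab: seg[ab[0]:ab[1]].max())
        if refine_floor is not None:
            while a > lo and seg[a - 1] >= refine_floor:
                a -= 1
            while b < hi and seg[b] >= refine_floor:
                b += 1
        return int(a), int(b)
    return None


def segment_sounds(env: np.ndarray, rate: float, r_time: float,
                   valid_len: int | None = None,
                   thr_range: tuple[float, float] = (0.1, 0.7),
                   thr_step: float = 0.05,
                   refine_floor: float | None = 0.1,
                   source: str = "") -> SoundSegmentation | None:
    """Dynamic-threshold S1/S2 segmentation of one envelope.

    S1 is searched in the first half of the cycle with the R peak as the
    earliest admissible onset, S2 between the end of S1 and the end of
    the cycle.  Returns ``None`` when either sound cannot be found at
    any threshold (a segmentation failure for this axis/envelope).
    """
    env = np.asarray(env, dtype=float)
    n = env.size if valid_len is None else int(valid_len)
    r_idx = int(round(r_time * rate))
    if not 0 <= r_idx < n:
        raise ValueError("r_time outside the cycle")
    lo_thr, hi_thr = thr_range
    thresholds = np.arange(hi_thr, lo_thr - 1e-9, -thr_step)
    half = n // 2  # boundary sample belongs to the second half
    s1 = _find_sound(env, r_idx, half, n, thresholds, refine_floor)
    if s1 is None:
        return None
    t1, t2 = s1
    s2 = _find_sound(env, t2 + 1, n, n, thresholds, refine_floor)
    if s2 is None:
        return None
    t3, t4 = s2
    return SoundSegmentation(
        t0=0.0, t1=t1 / rate, t2=t2 / rate, t3=t3 / rate, t4=t4 / rate,
        t5=n / rate, source=source,
    )


def compute_contrast(mean_cycle: np.ndarray, seg: SoundSegmentation,
                     rate: float) -> tuple[float, float]:
    """Std ratio of each sound to the inter-sound background.

    A silent background (zero std) yields an infinite contrast: the
    sounds trivially stand out; gates treat the sentinel as a pass.
    """
    x = np.asarray(mean_cycle, dtype=float)
    idx = [int(round(t * rate)) for t in
           (seg.t1, seg.t2, seg.t3, seg.t4, seg.t5)]
    i1, i2, i3, i4, i5 = (min(max(i, 0), x.size) for i in idx)
    bg = np.concatenate([x[i2:i3], x[i4:i5]])
    if bg.size < 3:
        # a couple of samples cannot estimate a background level
        raise ValueError("empty or degenerate background segment")
    bg_std = float(np.std(bg))
    out = []
    for a, b in ((i1, i2), (i3, i4)):
        s_std = float(np.std(x[a:b])) if b > a else 0.0
        out.append(s_std / bg_std if bg_std > 0 else float("inf"))
    return out[0], out[1]


def fuse_detections(candidates: list[SoundSegmentation],
                    cycles: dict[str, tuple[np.ndarray, float]],
                    min_contrast: float = 2.0) -> SoundSegmentation | None:
    """Fuse per-axis/per-envelope candidates into final S1/S2 instants.

    Each candidate's boundaries are replicated on every available axis
    and their contrast re-evaluated there; entries below
    ``min_contrast`` are discarded.  Surviving contrasts form the S1 and
    S2 relevance vectors, and the fused instants are the
    relevance-weighted averages of the candidate boundaries — so a
    sound detected cleanly on one axis can still define the global
    timing even if invisible on another.  Returns ``None`` when every
    entry of a sound is discarded.
    """
    if not candidates:
        raise ValueError("no candidate segmentations to fuse")
    w1 = w2 = 0.0
    acc1 = np.zeros(2)  # weighted t1, t2
    acc2 = np.zeros(2)  # weighted t3, t4
    per_axis: dict[str, list] = {}
    for cand in candidates:
        for axis, (cyc, rate) in cycles.items():
            try:
                c1, c2 = compute_contrast(cyc, cand, rate)
            except ValueError:
                continue
            c1, c2 = min(c1, 1e6), min(c2, 1e6)  # cap the inf sentinel
            per_axis.setdefault(axis, []).append((cand.source, c1, c2))
            if c1 >= min_contrast:
                w1 += c1
                acc1 += c1 * np.array([cand.t1, cand.t2])
            if c2 >= min_contrast:
                w2 += c2
                acc2 += c2 * np.array([cand.t3, cand.t4])
    if w1 == 0 or w2 == 0:
        return None
    t1, t2 = acc1 / w1
    t3, t4 = acc2 / w2
    t5 = float(np.median([c.t5 for c in candidates]))
    # enforce landmark ordering; disagreeing candidates may interleave
    t3 = max(t3, t2)
    if t4 <= t3:
        t4 = t3 + 1e-6
    t5 = max(t5, t4)
    fused = SoundSegmentation(0.0, t1, t2, t3, t4, t5, source="fused")
    best1 = best2 = 0.0
    pa = {}
    for axis, (cyc, rate) in cycles.items():
        try:
            c1, c2 = compute_contrast(cyc, fused, rate)
        except ValueError:
            continue
        pa[axis] = (c1, c2)
        best1, best2 = max(best1, c1), max(best2, c2)
    fused.s1_contrast, fused.s2_contrast = best1, best2
    fused.per_axis_contrast = pa
    return fused
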