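"""Core containers for multichannel implant recordings.

A :class:`Recording` bundles one ECG channel with up to three accelerometer
axes acquired synchronously from the gastric implant, plus the derived
Euclidean-norm axis ("N-axis") which is treated downstream as a fourth
accelerometer channel.  Channels may have different sampling rates (the
device samples ECG at 1000 or 498 Hz and the accelerometer at 4 kHz), so
each channel carries its own rate and time offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

ACC_AXES = ("acc_x", "acc_y", "acc_z", "acc_n")


@dataclass
class Waveform:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : ndarray
        Signal values.  ECG is in mV-equivalent arbitrary units, ACC in
        device units (the acquisition bandwidth is stated but not the
        physical scale, so amplitudes are reported in input units).
    rate : float
        Sampling rate in samples/s, strictly positive.
    t0_offset : float
        Time of the first sample, in seconds from recording start.
    """

    samples: np.ndarray
    rate: float
    t0_offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("waveform needs a 1-D array with >= 1 sample")
        if not self.rate > 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            idx = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ValueError(f"non-finite sample at index {idx}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record span covered by this channel, in seconds."""
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset + np.arange(self.n) / self.rate

    def copy_with(self, **kw) -> "Waveform":
        return replace(self, **kw)


@dataclass
class Recording:
    """Synchronized ECG + accelerometer channels of one 30-s acquisition."""

    id: str
    ecg: Waveform
    acc_x: Waveform | None = None
    acc_y: Waveform | None = None
    acc_z: Waveform | None = None
    acc_n: Waveform | None = None
    start_time: str | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- channel access -------------------------------------------------
    def acc_channels(self) -> dict[str, Waveform]:
        """Present accelerometer channels (measured axes + derived norm)."""
        out = {}
        for name in ACC_AXES:
            w = getattr(self, name)
            if w is not None:
                out[name] = w
        return out

    def channels(self) -> dict[str, Waveform]:
        out = {"ecg": self.ecg}
        out.update(self.acc_channels())
        return out

    def has_acc(self) -> bool:
        return any(getattr(self, a) is not None for a in ACC_AXES[:3])

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.ecg is None:
            raise ValueError("recording must contain an ECG channel")
        chans = self.channels()
        slowest = min(w.rate for w in chans.values())
        durs = {k: w.duration for k, w in chans.items()}
        tol = 1.0 / slowest  # one sample period of the slowest channel
        dmin, dmax = min(durs.values()), max(durs.values())
        if dmax - dmin > tol + 1e-12:
            raise ValueError(
                f"channel durations differ beyond one slow-channel sample: {durs}"
            )
        if self.has_acc() and self.acc_n is None:
            raise ValueError("acc_n missing although measured ACC axes are present")
        if self.acc_n is not None and not self.has_acc():
            raise ValueError("acc_n present without any measured ACC axis")

    def map_channels(self, fn) -> "Recording":
        """Apply ``fn(name, waveform) -> waveform`` to every channel."""
        kw = {name: fn(name, w) for name, w in self.channels().items()}
        return replace(self, ecg=kw.pop("ecg"), **kw)


def mad_outlier_mask(values: np.ndarray, n_mad: float = 3.0,
                     rel_floor: float = 0.1) -> np.ndarray:
    """Boolean mask of outliers under the scaled-MAD rule.

    A value is an outlier when it is more than ``n_mad`` scaled median
    absolute deviations (scale factor 1.4826, consistent for a normal
    distribution) away from the median.  The detection threshold is
    floored at ``rel_floor`` times the median magnitude: when the bulk
    of the data is nearly identical the raw MAD collapses toward zero
    and would flag ordinary fluctuations, so deviations within 10% of
    the median are never treated as outliers.  A zero threshold (all
    values identical) marks nothing.
    """
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    thr = max(n_mad * 1.4826 * mad, rel_floor * abs(med))
    if thr == 0:
        return np.zeros(v.shape, dtype=bool)
    return np.abs(v - med) > thr
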