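"""Reading and writing multichannel recordings.

Two on-disk formats are supported:

* **Columnar CSV** — one column per channel, header ``name:rate`` per
  column, shorter (slower) channels padded with empty cells.  Optional
  ``# key=value`` comment lines carry metadata.  Floats are written at
  full repr precision so a write→read round trip is bit-exact.
* **WFDB subset** — a classic ``.hea``/``.dat`` pair, format 16, one
  ``.dat`` holding all signals frame-interleaved.  Channels with rates
  that are integer multiples of the slowest rate are stored with the
  corresponding samples-per-frame.  Storage is int16 with a per-signal
  gain, so round trips are exact only up to quantization.

The derived norm axis is computed at load time, before any baseline
processing, and treated downstream as a fourth accelerometer axis.
"""

from __future__ import annotations

import os
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .core import ACC_AXES, Recording, Waveform

__all__ = [
    "compute_norm_axis",
    "resample",
    "load_recording",
    "save_recording",
]


def compute_norm_axis(*axes: Waveform | None) -> Waveform:
    """Per-sample Euclidean norm of the accelerometer axes.

    Accepts any non-empty subset of the measured axes (recordings missing
    one or more axes are still usable); a single axis degenerates to its
    absolute value.  Must be called on raw signals, before baseline
    removal, so that the norm reflects the acquired acceleration vector.
    """
    present = [a for a in axes if a is not None]
    if not present:
        raise ValueError("norm axis requires at least one accelerometer axis")
    rate = present[0].rate
    n = present[0].n
    for a in present[1:]:
        if a.rate != rate or a.n != n:
            raise ValueError("accelerometer axes must share rate and length")
    stack = np.stack([a.samples for a in present])
    return Waveform(np.sqrt(np.sum(stack * stack, axis=0)), rate,
                    present[0].t0_offset)


def resample(w: Waveform, target_rate: float) -> Waveform:
    """Band-limited rate conversion via polyphase filtering."""
    if not target_rate > 0:
        raise ValueError("target_rate must be > 0")
    if target_rate == w.rate:
        return w
    frac = Fraction(target_rate / w.rate).limit_denominator(10000)
    out = resample_poly(w.samples, frac.numerator, frac.denominator,
                        padtype="line")
    return Waveform(out, target_rate, w.t0_offset)


# ---------------------------------------------------------------- CSV --

def _write_csv(rec: Recording, path: str) -> None:
    cols = {}
    for name, w in rec.channels().items():
        cols[f"{name}:{w.rate:g}"] = pd.Series(w.samples)
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# id={rec.id}\n")
        if rec.start_time is not None:
            fh.write(f"# start_time={rec.start_time}\n")
        fh.write(f"# t0_offset={rec.ecg.t0_offset!r}\n")
        for k, v in rec.meta.items():
            fh.write(f"# {k}={v}\n")
        # repr is the shortest exact decimal form: bit-exact round trip
        df.to_csv(fh, index=False, float_format=lambda v: repr(float(v)))


def _read_csv(path: str) -> Recording:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    rec_id = meta.pop("id", os.path.splitext(os.path.basename(path))[0])
    start_time = meta.pop("start_time", None)
    t0 = float(meta.pop("t0_offset", 0.0))
    waves: dict[str, Waveform] = {}
    for col in df.columns:
        name, _, rate_s = col.partition(":")
        if not rate_s:
            raise ValueError(f"CSV column {col!r} lacks a ':rate' suffix")
        vals = df[col].to_numpy(dtype=float)
        # trailing blanks (rate padding) parse as NaN; interior NaN is a
        # genuine input error caught by the Waveform invariant
        nonnan = np.flatnonzero(~np.isnan(vals))
        vals = vals[: nonnan[-1] + 1] if nonnan.size else vals[:0]
        waves[name] = Waveform(vals, float(rate_s), t0)
    return _assemble(rec_id, waves, start_time, meta)


# --------------------------------------------------------------- WFDB --

_FMT = 16  # two's-complement 16-bit little-endian


def _write_wfdb(rec: Recording, path: str) -> None:
    base, _ = os.path.splitext(path)
    name = os.path.basename(base)
    chans = rec.channels()
    frame_rate = min(w.rate for w in chans.values())
    spf = {}
    for cname, w in chans.items():
        ratio = w.rate / frame_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"WFDB subset needs rates commensurate with the slowest "
                f"channel ({frame_rate} Hz); {cname} at {w.rate} Hz is not — "
                f"use CSV instead"
            )
        spf[cname] = int(round(ratio))
    n_frames = min(w.n // spf[c] for c, w in chans.items())
    sig_lines, columns = [], []
    for cname, w in chans.items():
        x = w.samples[: n_frames * spf[cname]]
        amax = np.max(np.abs(x))
        gain = 32000.0 / amax if amax > 0 else 1.0
        d = np.clip(np.round(x * gain), -32768, 32767).astype("<i2")
        columns.append(d.reshape(n_frames, spf[cname]))
        units = "mV" if cname == "ecg" else "au"
        sig_lines.append(
            f"{name}.dat {_FMT}x{spf[cname]} {gain:.12g}(0)/{units} "
            f"16 0 {int(d[0])} 0 0 {cname}"
        )
    frames = np.concatenate(columns, axis=1)
    frames.tofile(base + ".dat")
    with open(base + ".hea", "w") as fh:
        fh.write(f"{name} {len(chans)} {frame_rate:g} {n_frames}\n")
        fh.write("\n".join(sig_lines) + "\n")
        fh.write(f"# t0_offset={rec.ecg.t0_offset!r}\n")
        for k, v in rec.meta.items():
            fh.write(f"# {k}={v}\n")


def _read_wfdb(path: str) -> Recording:
    base, ext = os.path.splitext(path)
    if ext not in (".hea", ""):
        base = path
    with open(base + ".hea") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    head = lines[0].split()
    n_sig, frame_rate, n_frames = int(head[1]), float(head[2]), int(head[3])
    meta: dict[str, str] = {}
    sigs = []
    for ln in lines[1:]:
        if ln.startswith("#"):
            k, _, v = ln[1:].strip().partition("=")
            meta[k.strip()] = v
        elif ln.strip():
            sigs.append(ln.split())
    if len(sigs) != n_sig:
        raise ValueError("header signal count mismatch")
    t0 = float(meta.pop("t0_offset", 0.0))
    spf, gains, names = [], [], []
    for parts in sigs:
        fmt = parts[1]
        s = int(fmt.split("x")[1]) if "x" in fmt else 1
        spf.append(s)
        gains.append(float(parts[2].split("(")[0].split("/")[0]))
        names.append(parts[-1])
    raw = np.fromfile(base + ".dat", dtype="<i2")
    frames = raw.reshape(n_frames, sum(spf))
    waves, col = {}, 0
    for nm, s, g in zip(names, spf, gains):
        d = frames[:, col : col + s].reshape(-1).astype(float) / g
        waves[nm] = Waveform(d, frame_rate * s, t0)
        col += s
    rec_id = meta.pop("id", os.path.basename(base))
    return _assemble(rec_id, waves, meta.pop("start_time", None), meta)


# ------------------------------------------------------------ assembly --

def _assemble(rec_id: str, waves: dict[str, Waveform],
              start_time: str | None, meta: dict[str, str]) -> Recording:
    if "ecg" not in waves:
        raise ValueError("recording has no 'ecg' channel")
    kw = {a: waves.get(a) for a in ACC_AXES[:3]}
    measured = [w for w in kw.values() if w is not None]
    acc_n = waves.get("acc_n")
    if acc_n is None and measured:
        acc_n = compute_norm_axis(*measured)
    return Recording(id=rec_id, ecg=waves["ecg"], acc_n=acc_n,
                     start_time=start_time, meta=meta, **kw)


def load_recording(path: str, format: str | None = None) -> Recording:
    """Load a recording from CSV or the WFDB subset.

    The format is inferred from the extension when not given.  The norm
    axis is derived on the raw samples if the file does not store one.
    """
    if format is None:
        format = "wfdb" if path.endswith((".hea", ".dat")) else "csv"
    if not os.path.exists(path if format == "csv" else
                          os.path.splitext(path)[0] + ".hea"):
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv(path)
    if format == "wfdb":
        return _read_wfdb(path)
    raise ValueError(f"unknown format {format!r}")


def save_recording(rec: Recording, path: str, format: str | None = None) -> None:
    if format is None:
        format = "wfdb" if path.endswith((".hea", ".dat")) else "csv"
    if format == "csv":
        _write_csv(rec, path)
    elif format == "wfdb":
        _write_wfdb(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")
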