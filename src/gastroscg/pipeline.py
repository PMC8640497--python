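"""Full processing chain over single recordings and cohorts.

Stage order: startup trim -> baseline removal -> band-pass filtering
(ECG branch: QRS and TP bands; ACC branch: 20-40 Hz at the 400 Hz
analysis rate) -> ECG normalization and QRS detection -> cycle
segmentation projected to all axes -> coherent averaging per channel ->
S1/S2 envelope segmentation and fusion -> quality gates and SNR ->
hemodynamic markers.  Stage-3 (cohort-level marker outlier removal)
runs in :func:`run_cohort` once every recording has markers.

Every step is deterministic: re-running on identical inputs and config
reproduces outputs exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import preprocess as pp
from .coherent import CoherentMean, average_cycleset
from .core import Recording
from .io import load_recording, resample
from .markers import MarkerSet, derive_markers
from .qrs import (RPeakSeries, detect_qrs, estimate_heart_rate,
                  normalize_local, segment_cycles)
from .quality import (QualityReport, snr_acc_recording,
                      snr_ecg_recording, stage1_gate, stage2_gate,
                      stage3_gate)
from .sounds import (SoundSegmentation, compute_contrast, compute_envelopes,
                     fuse_detections, segment_sounds)

__all__ = ["PipelineConfig", "PipelineResult", "CohortResult",
           "run_pipeline", "run_cohort"]


@dataclass
class PipelineConfig:
    """All tunables of the chain, defaulting to the published constants."""

    version: str = "1"
    discard_s: float = 1.0
    baseline_window_s: float = 4.0
    baseline_work_rate: float = 400.0
    analysis_rate: float = 400.0
    norm_window_s: float = 2.0
    qrs_threshold: float = 0.5
    refractory_s: float = 0.2
    rho: float = 0.6                 # coherent-group correlation threshold
    max_lag_s: float = 0.05
    thr_lo: float = 0.1
    thr_hi: float = 0.7
    thr_step: float = 0.05
    refine_floor: float | None = 0.1
    min_contrast: float = 2.0
    min_coherent: int = 3
    stage1_acc_reading: str = "count"
    n_mad: float = 3.0
    match_tol_s: float = 0.05
    duration_window_cycles: int = 4
    p2p_window_cycles: int = 2

    def to_yaml(self, path: str) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    recording_id: str
    quality: QualityReport
    markers: MarkerSet | None = None
    fused: SoundSegmentation | None = None
    candidates: list = field(default_factory=list)
    r_peaks: RPeakSeries | None = None
    hr_bpm: float = float("nan")
    ecg_mean: CoherentMean | None = None
    acc_means: dict = field(default_factory=dict)
    cyclesets: dict = field(default_factory=dict)
    log: list = field(default_factory=list)


def _preprocess(rec: Recording, cfg: PipelineConfig):
    """Trim, baseline-remove and band-filter all channels."""
    rec = pp.trim_startup(rec, cfg.discard_s)
    clean = rec.map_channels(
        lambda _n, w: pp.remove_baseline(w, cfg.baseline_window_s,
                                         cfg.baseline_work_rate))
    ecg_qrs = pp.bandpass_zero_phase(clean.ecg, pp.QRS_ECG)
    ecg_tp = pp.bandpass_zero_phase(clean.ecg, pp.TP_ECG)
    acc = {}
    for name, w in clean.acc_channels().items():
        w400 = resample(w, cfg.analysis_rate) if w.rate != cfg.analysis_rate \
            else w
        acc[name] = pp.bandpass_zero_phase(w400, pp.ACC)
    return ecg_qrs, ecg_tp, acc


def run_pipeline(rec: Recording, cfg: PipelineConfig | None = None,
                 out_dir: str | None = None) -> PipelineResult:
    """Run the full chain on one recording.

    Rejected recordings carry their rejection stage in the quality
    report together with whatever partial outputs exist; stage 3 stays
    ``None`` here (it needs a cohort).
    """
    cfg = cfg or PipelineConfig()
    res = PipelineResult(recording_id=rec.id, quality=QualityReport())
    q = res.quality

    ecg_qrs, ecg_tp, acc = _preprocess(rec, cfg)

    norm_ecg = normalize_local(ecg_qrs, cfg.norm_window_s)
    rp = detect_qrs(norm_ecg, threshold=cfg.qrs_threshold,
                    refractory_s=cfg.refractory_s)
    res.r_peaks = rp
    if len(rp) < 2:
        res.log.append("stage1: <2 R peaks detected")
        _persist(res, out_dir, cfg)
        return res
    hr = estimate_heart_rate(rp)
    res.hr_bpm = q.hr_bpm = hr

    proc = Recording(id=rec.id, ecg=norm_ecg,
                     acc_x=acc.get("acc_x"), acc_y=acc.get("acc_y"),
                     acc_z=acc.get("acc_z"), acc_n=acc.get("acc_n"),
                     meta=dict(rec.meta))
    css = segment_cycles(proc, rp, hr)
    res.cyclesets = css

    ecg_cm = average_cycleset(css["ecg"], is_acc=False, rho=cfg.rho,
                              max_lag_s=cfg.max_lag_s)
    res.ecg_mean = ecg_cm
    acc_cms = {name: average_cycleset(cs, is_acc=True, rho=cfg.rho,
                                      max_lag_s=cfg.max_lag_s)
               for name, cs in css.items() if name != "ecg"}
    res.acc_means = acc_cms

    n_ecg = ecg_cm.n_coherent if ecg_cm else 0
    acc_ns = {a: (cm.n_coherent if cm else 0) for a, cm in acc_cms.items()}
    q.stage1_pass = stage1_gate(n_ecg, acc_ns, cfg.min_coherent,
                                cfg.stage1_acc_reading)
    n_cycles = len(css["ecg"])
    q.ecg_coherent_pct = 100.0 * n_ecg / max(n_cycles, 1)
    q.acc_coherent_pct = {a: 100.0 * n / max(n_cycles, 1)
                          for a, n in acc_ns.items()}
    if ecg_cm:
        q.mean_intercycle_r = ecg_cm.mean_intercycle_r

    # -- candidate S1/S2 segmentations over axes x envelopes -----------
    cyc_map, cands = {}, []
    for axis, cm in acc_cms.items():
        if cm is None:
            continue
        cyc = cm.mean_cycle[: cm.valid_len]
        cyc_map[axis] = (cyc, cm.rate)
        try:
            envs = compute_envelopes(cyc, cm.rate)
        except ValueError:
            res.log.append(f"{axis}: all-zero mean cycle")
            continue
        for env, tag in zip(envs, ("abs", "sqr")):
            seg = segment_sounds(env, cm.rate, cm.r_offset,
                                 thr_range=(cfg.thr_lo, cfg.thr_hi),
                                 thr_step=cfg.thr_step,
                                 refine_floor=cfg.refine_floor,
                                 source=f"{axis}:{tag}")
            if seg is None:
                res.log.append(f"{axis}:{tag}: segmentation failure")
                continue
            try:
                seg.s1_contrast, seg.s2_contrast = compute_contrast(
                    cyc, seg, cm.rate)
            except ValueError:
                # lobes swallowed the cycle: no background to judge by
                res.log.append(f"{axis}:{tag}: degenerate background")
                continue
            cands.append(seg)
    res.candidates = cands

    contrasts = {}
    for axis in cyc_map:
        own = [c for c in cands if c.source.startswith(axis + ":")]
        if own:
            best = max(own, key=lambda c: min(c.s1_contrast, c.s2_contrast))
            contrasts[axis] = (best.s1_contrast, best.s2_contrast)
    q.s1_contrast = {a: c[0] for a, c in contrasts.items()}
    q.s2_contrast = {a: c[1] for a, c in contrasts.items()}
    q.stage2_pass = stage2_gate(contrasts, cfg.min_contrast)

    fused = fuse_detections(cands, cyc_map, cfg.min_contrast) if cands \
        else None
    res.fused = fused

    # -- SNR and markers ----------------------------------------------
    tp_snr, qrs_snr = snr_ecg_recording(ecg_tp, ecg_qrs, rp)
    q.snr["TP_ECG"] = tp_snr
    q.snr["QRS_ECG"] = qrs_snr
    if fused is not None:
        for axis, (s1, s2) in snr_acc_recording(acc_cms, fused).items():
            q.snr[f"S1:{axis}"] = s1
            q.snr[f"S2:{axis}"] = s2
        res.markers = derive_markers(fused, fused.t5, hr, acc_cms)
    _persist(res, out_dir, cfg)
    return res


def _persist(res: PipelineResult, out_dir: str | None,
             cfg: PipelineConfig) -> None:
    if out_dir is None:
        return
    d = os.path.join(out_dir, res.recording_id)
    os.makedirs(d, exist_ok=True)
    cfg.to_yaml(os.path.join(d, "config.yaml"))
    if res.r_peaks is not None:
        pd.DataFrame({"time_s": res.r_peaks.times,
                      "confidence": res.r_peaks.confidence}
                     ).to_csv(os.path.join(d, "peaks.csv"), index=False)
    means = {}
    if res.ecg_mean is not None:
        means["ecg"] = res.ecg_mean
    means.update({a: m for a, m in res.acc_means.items() if m is not None})
    if means:
        n = max(m.mean_cycle.size for m in means.values())
        cols = {a: np.pad(m.mean_cycle.astype(float),
                          (0, n - m.mean_cycle.size),
                          constant_values=np.nan)
                for a, m in means.items()}
        pd.DataFrame(cols).to_csv(os.path.join(d, "mean_cycles.csv"),
                                  index=False)
    seg_doc = {
        "fused": _seg_dict(res.fused),
        "candidates": [_seg_dict(c) for c in res.candidates],
    }
    with open(os.path.join(d, "segmentation.json"), "w") as fh:
        json.dump(seg_doc, fh, indent=1, sort_keys=True)
    qrow = {"recording_id": res.recording_id,
            "stage1_pass": res.quality.stage1_pass,
            "stage2_pass": res.quality.stage2_pass,
            "hr_bpm": res.hr_bpm,
            "ecg_coherent_pct": res.quality.ecg_coherent_pct,
            **{f"snr_{k}": v for k, v in res.quality.snr.items()}}
    pd.DataFrame([qrow]).to_csv(os.path.join(d, "quality.csv"), index=False)
    if res.markers is not None:
        m = res.markers
        row = {k: v for k, v in asdict(m).items()
               if not isinstance(v, (dict, tuple))}
        row.update({f"p2p_s1_{a}": v for a, v in m.p2p_s1.items()})
        row.update({f"p2p_s2_{a}": v for a, v in m.p2p_s2.items()})
        pd.DataFrame([row]).to_csv(os.path.join(d, "markers.csv"),
                                   index=False)


def _seg_dict(seg: SoundSegmentation | None):
    if seg is None:
        return None
    d = {k: getattr(seg, k) for k in
         ("t0", "t1", "t2", "t3", "t4", "t5", "source",
          "s1_contrast", "s2_contrast")}
    return d


@dataclass
class CohortResult:
    results: list
    keep_mask: np.ndarray            # over stage-1&2 survivors
    table: pd.DataFrame              # per-recording quality rows
    counts: dict                     # stage removal counts and percentages


def run_cohort(recordings, cfg: PipelineConfig | None = None,
               out_dir: str | None = None) -> CohortResult:
    """Run the chain over a cohort and apply the cohort-wide stage 3.

    ``recordings`` is a directory of CSV recordings or an iterable of
    :class:`Recording`.  Stage 3 flags any stage-1&2 survivor whose
    S1/S2 duration or peak-to-peak norm is a scaled-MAD outlier of the
    cohort.
    """
    cfg = cfg or PipelineConfig()
    if isinstance(recordings, (str, os.PathLike)):
        paths = sorted(f for f in os.listdir(recordings)
                       if f.endswith(".csv"))
        if not paths:
            raise ValueError(f"no recordings found in {recordings!r}")
        recs = (load_recording(os.path.join(recordings, f)) for f in paths)
    else:
        recs = recordings
    results = [run_pipeline(r, cfg, out_dir=out_dir) for r in recs]
    if not results:
        raise ValueError("empty cohort")

    surv = [r for r in results
            if r.quality.stage1_pass and r.quality.stage2_pass
            and r.markers is not None]
    if surv:
        tbl = np.array([[r.markers.s1_duration_ms, r.markers.s2_duration_ms,
                         r.markers.p2p_s1_norm, r.markers.p2p_s2_norm]
                        for r in surv])
        keep = stage3_gate(tbl, cfg.n_mad)
    else:
        keep = np.zeros(0, dtype=bool)
    for r, k in zip(surv, keep):
        r.quality.stage3_pass = bool(k)

    rows = []
    for r in results:
        q = r.quality
        rows.append({
            "recording_id": r.recording_id,
            "hr_bpm": r.hr_bpm,
            "rejection_stage": q.rejection_stage or 0,
            "preserved": q.preserved,
            "ecg_coherent_pct": q.ecg_coherent_pct,
            **{f"snr_{k}": v for k, v in q.snr.items()},
        })
    table = pd.DataFrame(rows)
    n = len(results)
    counts = {"total": n}
    for stage in (1, 2, 3):
        c = sum(1 for r in results if r.quality.rejection_stage == stage)
        counts[f"removed_stage{stage}"] = c
        counts[f"removed_stage{stage}_pct"] = 100.0 * c / n
    c = sum(1 for r in results if r.quality.preserved)
    counts["preserved"] = c
    counts["preserved_pct"] = 100.0 * c / n
    if out_dir is not None:
        table.to_csv(os.path.join(out_dir, "cohort_summary.csv"),
                     index=False)
        with open(os.path.join(out_dir, "cohort_counts.json"), "w") as fh:
            json.dump(counts, fh, indent=1, sort_keys=True)
    return CohortResult(results=results, keep_mask=keep, table=table,
                        counts=counts)
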