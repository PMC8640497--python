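# gastroscg

Signal-processing chain for **gastric-implant cardiac monitoring**:
simultaneous ECG and 3-axis accelerometry (seismocardiography, SCG)
recorded by a small implant fixed at the gastric fundus, a site close
enough to the heart to observe both the electrical (QRS) and mechanical
(S1/S2 heart-sound) activity — but plagued by noise sources of its own:
gastric slow waves, respiration, growls and digestive movements, and a
saturating wake-up transient at the start of every 30-s acquisition.

The package is for researchers and engineers working on implantable or
wearable cardiac-vibration monitoring who need a tested, deterministic
reference chain from raw multichannel recordings to hemodynamic
markers.

## What it computes

For each 30-s recording (ECG at 1000 or 498 Hz, ACC at 4 kHz plus the
derived norm axis N):

- **Denoising** — startup trim, LOWESS baseline removal (4-s span,
  400 Hz grid), zero-phase 5th-order Butterworth band-passes
  (ECG 20–50 / 5–50 Hz, ACC 20–40 Hz).
- **QRS detection** — local min/max normalization (median-clipped
  divisor) plus a multi-feature logistic evidence score; heart rate
  HR = 60 / median(R–R); cycles start 0.05·60/HR s before each R and
  the same onsets segment every axis.
- **Coherent averaging** — cycles padded to the median length,
  S1/S2-windowed phase correction on ACC, dominant group at
  correlation > 0.6, energy-outlier rejection (3 scaled MADs), mean
  cycle with √N noise gain.
- **S1/S2 segmentation and fusion** — Abs/Sqr envelopes, dynamic
  threshold 0.7→0.1, candidate boundaries per axis × envelope fused by
  contrast-weighted averaging (contrast = std(sound)/std(background),
  entries < 2 discarded).
- **Quality gates and SNR** — stage 1: ≥ 3 coherent cycles (ECG and an
  ACC axis); stage 2: both sound contrasts > 2 on some axis; stage 3:
  cohort-level marker-outlier removal. Beat SNR
  `10·log10(S²/mean|x_m|²)` on TP-ECG, QRS-ECG and per-axis S1/S2.
- **Markers** — systole = t3 − t1, diastole = cycle − systole, S1/S2
  durations, per-axis and Euclidean-norm peak-to-peak amplitudes,
  sliding-window duration (4 cycles) and peak-to-peak (2 cycles)
  time-profiles, QRS validation against a reference (±25 ms matching).

A fully seeded **synthetic generator** (`gastroscg.synthetic`) produces
gastric-site-like recordings with ground truth — the test bed for the
whole chain. See `docs/methods.md` for the model and its limits.

## Worked example

```bash
gastroscg simulate --seed 11 --out sim -n 1     # one synthetic recording
gastroscg run --in sim/synthetic_0011.csv --out res
```

prints

```
synthetic_0011: rejection_stage=none hr=90.5 bpm
  systole=274 ms diastole=336 ms S1=165 ms S2=129 ms
```

i.e. the recording passed stages 1–2, heart rate is 90.5 bpm, and the
fused heart-sound boundaries put systole at 274 ms of a 610-ms cycle,
with S1 lasting 165 ms and S2 129 ms. `res/synthetic_0011/` holds the
R-peak list, per-axis mean cycles, candidate and fused segmentations,
quality row and markers as CSV/JSON. The same from Python:

```python
from gastroscg import ScenarioConfig, generate_recording, run_pipeline

rec, truth = generate_recording(ScenarioConfig(seed=11))
res = run_pipeline(rec)
print(res.hr_bpm, res.markers.systole_ms, res.quality.snr["QRS_ECG"])
```

Directories of recordings run as cohorts (`gastroscg run --in dir/`),
which adds the cohort-wide stage-3 gate and a summary table of
rejections per stage.

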