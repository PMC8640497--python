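# Methods

`gastroscg` implements the signal-processing chain for 30-s recordings of
simultaneous ECG and 3-axis accelerometry (seismocardiography, SCG)
acquired by an implant fixed at the gastric fundus. The chain turns a
noisy multichannel recording into beat-timing and heart-sound markers:
heart rate, S1/S2 timing and duration, systole/diastole split,
peak-to-peak vibration amplitudes, per-recording quality gates and SNR.

## Processing chain

1. **Startup trim.** The device wakes from a low-power mode and the
   front-end saturates briefly; the first second is discarded, leaving
   29 s of usable signal.
2. **Baseline removal.** Low-frequency interference (respiration at
   ~0.2–0.4 Hz, gastric slow waves near 0.05 Hz, electrode drift) is
   estimated by locally weighted linear regression (LOWESS, tricube
   weights, first degree) with a 4-s span on a 400 Hz working grid, then
   subtracted at the channel's native rate. The Euclidean norm of the
   three ACC axes ("N-axis") is computed *before* this step and carried
   as a fourth axis: with the constant gravity offset still present,
   |g + s| ≈ |g| + u·s, so the norm behaves as a direction-independent
   projection of the vibration vector.
   A 4-s-span smoother attenuates but cannot cancel 0.3 Hz content (the
   frequency is above its cutoff); the residual respiration is removed
   by the subsequent band-passes, which is why the baseline stage is
   judged on drift *reduction* and on leaving in-band morphology intact,
   not on perfect cancellation.
3. **Band-pass filtering.** Independent high-pass and low-pass
   fifth-order Butterworth stages, each applied forward and backward
   (zero phase), in three presets: **QRS-ECG** 20–50 Hz (emphasizes R
   peaks for detection), **TP-ECG** 5–50 Hz (keeps P/T waves, used only
   for SNR reporting), **ACC** 20–40 Hz (the band holding most cardiac
   vibration energy). ACC channels are carried at a 400 Hz analysis rate
   after baseline removal; ECG stays at its native rate to preserve QRS
   timing precision.
4. **ECG normalization and QRS detection.** The QRS-band ECG is divided
   by its sliding 2-s local range, clipped from below at the *median*
   range so noise-only stretches are not amplified (the median resists
   the high-amplitude artifacts this site is prone to). Candidate peaks
   (refractory 0.2 s) are scored on three features — normalized
   amplitude, derivative energy, local SNR — through a fixed logistic
   weighting with a 0.5 threshold. Candidates within 0.3 s of either
   record edge are discarded: the local-SNR feature needs its full
   background window there and zero-phase filtering leaves edge
   transients. Heart rate is 60 / median(R–R).
5. **Cycle segmentation.** Each cycle starts `0.05·60/HR` s before its R
   peak — a heart-rate-scaled margin that keeps the whole QRS inside the
   cycle — and the identical onset times segment every ACC axis
   (channels are synchronous).
6. **Coherent averaging.** Cycles are padded/truncated to the median
   cycle length. For ACC, the S1 and S2 sub-windows of each cycle are
   independently phase-shifted (bounded by ±50 ms) to maximize
   correlation with a template cycle — valve-sound latencies vary beat
   to beat with loading conditions, independently of the R peak; a shift
   is kept only if it does not lower the cycle's full-length correlation
   with the template, so alignment can never reduce coherence. The
   template is the cycle with the best median lagged correlation to all
   others; the *dominant group* is every cycle correlating > 0.6 with it
   (zero-normalized correlation, non-padded support only). ACC cycles —
   which keep physical amplitude and cannot be normalized — additionally
   drop energy outliers (> 3 scaled MADs from the median). The coherent
   mean is the sample-wise average of the survivors; residual noise
   falls as σ/√N.
7. **S1/S2 segmentation.** The mean ACC cycle is peak-normalized and
   smoothed (20-ms moving average) into absolute ("Abs") and squared
   ("Sqr") envelopes, each rescaled to unit peak. A dynamic threshold
   scanned downward from 0.7 to 0.1 (step 0.05) finds the dominant S1
   lobe in the first half of the cycle, with the R peak as the earliest
   admissible onset; S2 is found the same way between the end of S1 and
   the end of the cycle. Boundaries are then refined outward to the 0.1
   floor crossings of the accepted lobe: crossing points at a high
   threshold sit near the envelope peak and would systematically
   underestimate the sound extent (reported S1 durations of ~160 ms
   could never emerge from a 0.7-level crossing). The pure
   highest-threshold boundaries remain available via
   `refine_floor=None`.
8. **Fusion.** Every axis × envelope candidate is replicated on all four
   axes and its contrast — std inside the sound over std of the
   background (t2–t3 ∪ t4–t5) — re-evaluated there. Entries with
   contrast < 2 are discarded; surviving contrasts form S1 and S2
   relevance vectors, and the fused t1–t4 are the relevance-weighted
   averages of the candidate instants. A sound visible on one axis can
   therefore define the global timing even if invisible on another.
9. **Quality gates.** Stage 1: ≥ 3 coherent cycles on the ECG *and* on
   at least one ACC axis (the laxer "any coherent ACC cycle" reading of
   this rule is available via `stage1_acc_reading="any"`). Stage 2: some
   axis with both S1 and S2 contrast strictly above 2. Stage 3
   (cohort-level): a recording is removed when any of its S1/S2 duration
   or peak-to-peak markers is an outlier of the cohort.
10. **SNR.** Per beat, `SNR = 10·log10(S² / mean(|x_m|²))` in dB, with S
    the R-peak amplitude (ECG, reported on both TP and QRS bands) or the
    peak |amplitude| in the fused S1/S2 window (ACC per axis), and x_m
    the noise-only samples: ECG — the beat minus the QRS (R ± 60 ms), T
    ([R+150, R+400 ms] scaled by RR/0.8) and P ([next R − 200, − 80 ms])
    zones; ACC — the inter-sound gap (t2, t3). Recording SNR is the mean
    over beats; ±inf sentinels (silent noise / zero signal) are excluded
    from means and counted.
11. **Markers and profiles.** Systole = t3 − t1, diastole = cycle −
    systole (the identity holds exactly by construction); S1/S2 duration
    = t2 − t1 / t4 − t3; peak-to-peak per axis = max − min of the
    coherent mean cycle inside the sound window, condensed across axes
    by the Euclidean norm (which also tolerates missing axes).
    Duration time-profiles re-run the averaging + segmentation + fusion
    chain in a sliding window of four cycles; peak-to-peak profiles
    average per-cycle values (measured on the phase-aligned individual
    cycles inside the fused windows — a two-cycle window cannot support
    envelope re-segmentation) over two-cycle windows. Windows advance by
    one cycle and are timestamped at the mean R time of their member
    cycles. Profiles are compared with a reference channel by Pearson
    correlation after nearest-neighbor pairing of window centers
    (Spearman available).
12. **QRS validation.** Detections match reference instants greedily,
    one-to-one, in time order, within a *centered 50-ms window* read as
    ±25 ms (the full-width ±50 ms reading is a config switch); jitter is
    the |Δt| over true positives.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `discard_s` | 1.0 s | startup transient removed |
| `baseline_window_s` / `baseline_work_rate` | 4 s / 400 Hz | LOWESS span and working grid |
| filter presets | 20–50, 5–50, 20–40 Hz, order 5 | QRS-ECG / TP-ECG / ACC bands |
| `norm_window_s` | 2 s | local min/max normalization window (spans ≥ 1 beat at ≥ 30 bpm) |
| `qrs_threshold`, `refractory_s` | 0.5, 0.2 s | detector operating point |
| `rho` | 0.6 | coherent-group correlation threshold |
| `max_lag_s` | 0.05 s | S1/S2 phase-correction search bound |
| `thr_lo`–`thr_hi`, `thr_step` | 0.1–0.7, 0.05 | dynamic envelope threshold scan |
| `refine_floor` | 0.1 | boundary refinement level (None = raw crossings) |
| `min_contrast` | 2.0 | fusion discard / stage-2 level |
| `min_coherent` | 3 | stage-1 floor |
| `n_mad` | 3.0 | scaled-MAD outlier rule |
| `match_tol_s` | 0.05 s | QRS validation window (centered) |
| window sizes | 4 / 2 cycles | duration / peak-to-peak profiles |

## Numerical choices

- Correlations are zero-normalized and restricted to non-padded support,
  so zero padding cannot inflate coherence. Template selection is a
  single pass (best median correlation), with no iterative re-templating
  — deterministic and testable.
- The scaled-MAD outlier threshold is floored at 10% of the median
  magnitude: when a sample of values is nearly identical the raw MAD
  collapses and would flag ordinary fluctuation as outliers. With the
  floor, deviations within 10% of the median are never outliers; all
  degenerate cases (identical values, single large outlier among equals)
  resolve consistently.
- Zero-phase filtering uses reflective padding up to 3 s per end to
  suppress forward–reverse transients. Re-applying a preset changes a
  pass-band-peak sinusoid by 1 − |H|², ≈ 2% for the 20–50 Hz cascade —
  the irreducible cost of real Butterworth edges.
- The inter-wave "noise" zones of the ECG SNR retain the band-pass
  ringing of the QRS itself, which caps the noise-free SNR near 27 dB —
  the same order as SNRs measured on real gastric recordings; the
  estimator is deliberately left faithful to its definition rather than
  tuned to produce arbitrarily high clean-signal values.
- Infinite-contrast sentinels are capped (10⁶) inside fusion weights; a
  background of fewer than 3 samples is treated as a segmentation
  failure rather than evidence of silence.

## The synthetic generator

No public recordings exist for this device, so `gastroscg.synthetic`
generates the study conditions with full ground truth: Gaussian-lobe
P-QRS-T ECG (R = 1 a.u., P/Q/S/T = 0.15/−0.15/−0.25/0.3) with truncated
Gaussian R-R jitter (sd 30 ms); S1/S2 as Tukey-windowed 25 Hz bursts
(durations 150/120 ms, onsets 30/300 ms after R, per-axis amplitudes
(1.0, 0.8, 0.6) and 0.6× for S2, beat-to-beat latency jitter sd 5 ms); a
gravity offset along a fixed implant attitude; respiration (0.3 Hz) and
gastric slow-wave (0.05 Hz) baselines; white noise (sd 0.03 ECG /
0.05 ACC); "growl" artifact bursts (2/min × 2 s, 20× S1 peak on ACC in
5–25 Hz, 1 a.u. on the ECG electrodes in 5–15 Hz — mechanical coupling
into the electrodes is weaker than into the accelerometer); and a
saturating startup transient (amplitude 20, τ = 0.2 s, rails ±15).
Carriers sit at 25 Hz because the analysis band is 20–40 Hz; sound
durations and the systolic interval follow the magnitudes reported for
pigs.

Ground-truth peak-to-peak values are defined on the clean **in-band**
(20–40 Hz) vibration component, because that is the band the amplitude
markers are defined on; the raw burst peak-to-peak (≈ 16% larger for
these burst shapes, purely from spectral truncation of a finite burst)
is stored alongside (`p2p_*_raw`). The norm-axis ground truth uses the
gravity linearization u·s.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: true HRV and autonomic dynamics,
arrhythmia, morphology drift within a recording, electrode-motion
transients correlated with the cardiac cycle, genuinely colored
instrument noise, or the orientation changes of a real implant. The
generator's beats are morphologically identical up to jitter and noise,
which makes coherent percentages higher than on real recordings.

## Problem sizes

Synthetic evaluations use 30-s recordings (~40 beats) in cohorts of 20,
the recording length the device acquires and a cohort size at which the
stage-3 outlier gate is meaningful; the acceptance script reports each
figure with the cohort size it used.

## Known limitations

- The multi-feature QRS detector follows the published contract (robust
  multi-feature probabilistic scoring) but its referenced model is not
  public; the feature set and weights here are this package's own and
  the operating point is exposed as configuration.
- The dynamic-threshold schedule of the referenced envelope segmenter is
  likewise not restated in the literature available; the downward scan
  plus floor refinement is this package's documented choice.
- WFDB support is a minimal format-16 subset (one interleaved `.dat`,
  integer samples-per-frame); channels whose rates are not integer
  multiples of the slowest (e.g. 498 Hz ECG with 4 kHz ACC) must use
  CSV. WFDB round trips are exact only to int16 quantization; CSV round
  trips are bit-exact.
- Stage-1's published wording ("three or more coherent cycles in the ECG
  and at least one of the ACC axis") is grammatically ambiguous; the
  strict reading (≥ 3 coherent cycles on some ACC axis) is the default,
  the lax one a config switch.
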