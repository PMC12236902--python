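# Methods

`lutphysio` implements the quantitative analysis chain used in mouse
lower-urinary-tract (LUT) neurophysiology experiments that combine
fiber photometry with awake cystometry, optogenetic stimulation with
external-urethral-sphincter (EUS) EMG, and overhead thermal imaging of
urine spots.  Because such studies rarely deposit raw traces, the package
pairs every analysis stage with a synthetic-session generator whose ground
truth makes each stage verifiable by recovery.

## Signal models

### Cystometry

Bladder pressure during continuous saline infusion is modeled as

    P(t) = P0 + m (t − t_reset) + Σ voids + Σ NVCs + ε,   m = r · C

with infusion rate `r` (default 25 μL/min, within the 15–30 μL/min range
used experimentally), compliance `C` (0.01 cmH2O/μL), Gaussian voiding
contractions (peak 30 cmH2O, σ = 5 s) and smaller single-peaked
non-voiding contractions (NVCs, default 7 cmH2O, σ = 3 s), and Gaussian
noise (SD 0.5 cmH2O).  The fill ramp resets when the contraction complex
ends (the bladder has emptied).  The ground-truth alignment time of a void
is the inflection of its rising limb (t_peak − σ), the steepest pressure
rise.  Optional double-peaked voids add a narrower sub-peak (0.6×
amplitude, σ/2) 3σ after the main peak, inside the same episode, to
exercise the single-peak inclusion rule.

### Photometry

Raw fluorescence is

    F465(t) = F0_465 · B(t) · (1 + Σ_e a_e k(t − t_e)) + M(t) + ε
    F405(t) = F0_405 · B(t) + g_m M(t) + ε

where `B` is a double-exponential photobleach (fast fraction 0.3,
τ = 300 s / 20 000 s), `k` is a unit-peak difference-of-exponentials
calcium transient (rise 0.5 s, decay 4 s — GCaMP6s-like), `a_e` the
per-event amplitude (default peak ΔF/F0 0.06, lognormal jitter 0.2;
NVC-locked transients attenuated to 0.3× by default, an emulation choice,
not a measured value), and `M` motion artifacts shared by both channels
(Gaussian bumps, σ 0.3 s, amplitude 0.1 a.u., random sign, Poisson rate
0.2/min).  The 405 nm channel is calcium-independent (isosbestic), so it
carries bleach and motion but no transients.

### EMG

Tonic sphincter activity is band-limited Gaussian noise (8–400 Hz at
1 kHz sampling) scaled to a target RMS (0.05 mV).  During a programmed
fraction of stimulation trials (default 0.75) the envelope drops by the
relaxation depth (default 0.5), so epoch power scales exactly with
(1 − depth)².  Stimulations default to 10 s at 40 s spacing (10-ms pulses
at 20 Hz in the logs); 5 s is available via config.  Artifact-flagged
trials receive a 5 ms spike of 20× tonic amplitude inside the flagged
phase.

### Thermography

Frames are 8-bit grayscale: cool background (60), warm elliptical spots
(180), and a brighter rectangular calibration template (250) whose pixel
count is exactly `round(px_per_cm2 × 10)` for the 10 cm² reference.
Ground truth records rasterized pixel areas; volumes come from the same
linear calibration curve the analyzer uses (50 μL/cm² through the origin —
the published calibration curve itself is external, so the slope is an
explicit config shared by generator and analyzer, which closes the
recovery loop without claiming the published coefficients).

## Analysis procedures

- **ΔF/F0** — signals are block-averaged to 0.1 s resolution, then
  F0 is a best-fit curve to the entire trace; the family cascade is
  double-exponential → single-exponential-plus-constant → quadratic
  polynomial, falling through on non-convergence or non-positive fits.
  ΔF/F0 = (F − F0)/F0.
- **Isosbestic correction** — ΔF/F0(405) is rescaled by least-squares
  gain + offset and subtracted from ΔF/F0(465).  The gain is fitted on
  samples where the 405 trace deflects more than 3 robust SDs from its
  baseline: a whole-trace fit is dominated by artifact-free noise and
  shrinks the gain toward zero, leaving most of each artifact behind.
  Raw (gain = 1) subtraction is a config switch.
- **Per-event normalization** — (ΔF/F0 − baseline)/baseline × 100 with
  baseline = mean ΔF/F0 of the 60 s preceding the event.  For a
  zero-centered ΔF/F0 trace this baseline can be ≈ 0; when |baseline| <
  0.005 the division is replaced by subtractive-only normalization and the
  event is flagged rather than dropped.
- **Z-score** — (x − mean)/SD over the full ±60 s window, so heatmap rows
  stay comparable.
- **Event detection** — pressure is downsampled to 10 Hz, detrended by a
  centered 90 s rolling median (absorbing the fill ramp), lightly
  smoothed, and peaks with ≥ 5 cmH2O prominence become candidate episodes.
  Episode bounds extend while the detrended trace exceeds 5% of the peak
  height; sub-peaks with prominence ≥ 20% of the episode rise are counted;
  the rise is measured against the median of the 30 s pre-episode segment.
- **Gating** — externally confirmed contractions are voids, the rest are
  NVCs.  Multi-peak episodes are excluded (`multi_peak`); NVCs rising
  < 5 cmH2O are excluded (`sub_threshold`).  Excluded events always carry
  their reason.
- **Alignment** — voids align to the maximum of dP/dt (centered difference
  of the moving-average-smoothed trace, 3 s span) within 15 s before the
  peak; because the smoothed derivative is flat-topped, the argmax is
  refined by a parabolic vertex fit over ±3 s, which brings the alignment
  error well under half the target tolerance at the default noise.  Exact
  argmax ties break to the earliest sample.  NVCs align to peak pressure.
- **Shuffle null** — pseudo-events drawn uniformly wherever the ±60 s
  window fits, optional exclusion zones, fully seeded.  With per-event
  normalization the chance level is zero by construction.
- **Total power (TTP)** — canonically the sum of squared mean-removed
  samples of an epoch; the periodogram-bin sum is provided as the
  frequency-domain equivalent and must agree to 1e-9 (Parseval).  Mean
  removal keeps a DC offset from dominating TTP; a config switch restores
  the DC bin.  Normalized epoch powers are percent shares of the trial
  total, summing to 100.
- **Response rates** — EMG: percent of trials with TTP_stim ≤ 0.95 ×
  TTP_before.  CMG: percent of trials whose mean stimulation-epoch
  pressure exceeds the baseline mean by ≥ 3 cmH2O after subtracting the
  natural filling rise, predicted by linearly extrapolating the
  baseline-epoch trend across the stimulation epoch.  Baseline-phase
  artifact trials (threshold rule: ≥ 8× the session's MAD scale for
  ≥ 2 ms) are excluded; stimulation/recovery-phase artifacts never cause
  exclusion.  Equal per-animal trial subsampling (e.g. 10) is seeded.
- **MVT** — Otsu (or fixed) threshold, 8-connected components, the
  brightest region is the template; px/cm² = template pixels / 10.
  Void vs leak is a geometric proxy for the behavioral call: area ≥
  0.8 cm² within 8 cm of an arena corner ⇒ void, otherwise leak (mark in
  marking mode).  Touching spots merge — a documented limitation.
- **Dominance screen** — initiation within 5 minutes of the urine stimulus
  AND ≥ 10 marks (corner voids excluded); no marks ⇒ latency censored at
  session end, subordinate.
- **Group comparison** — Kruskal–Wallis omnibus, then Dunn's pairwise rank
  test (tie-corrected) with Holm adjustment, implemented in-house and
  checked against a null-calibration simulation.

## Problem sizes and numerical choices

Sessions are simulated at desk scale: 50 Hz pressure/photometry raw rate
(downsampled to the 0.1 s analysis grid), 1 kHz EMG with an 8–400 Hz band.
All formulas are rate-agnostic; tests use 2-hour cystometry sessions with
6 voids + 4 NVCs, 50-seed photometry batches, a 200-trial optogenetic
cohort, 500 shuffle draws, 200 power-analysis replicates, and 20 thermal
frames.  Seeds are explicit everywhere; rerunning any stage with the same
seed and config yields byte-identical output files (all floats written at
fixed precision).

## What the generator does and does not emulate

It reproduces the statistical structure the analyses rely on: event-locked
transients under bleach and shared motion, ramp-plus-contraction pressure,
envelope-modulated band-limited EMG, rasterized warm spots with a known
template.  It does not model biophysics (detrusor mechanics, motor-unit
recruitment, heat diffusion), behavioral confounds (animal occlusion of
spots, overlapping voids), or hardware effects (demodulation residuals,
sensor drift).  Passing recovery tests therefore shows the pipeline is
correct and well-calibrated under these assumptions, not that it is robust
to every failure mode of in-vivo recordings.

## Known limitations

- The per-event percent normalization is intrinsically unstable when the
  pre-event baseline is near zero; the guard makes this explicit instead
  of silently dropping or inflating events.
- The geometric void/leak proxy misclassifies unusual spots (large
  mid-arena voids, corner leaks); both thresholds are config.
- Contraction detection thresholds (prominence, detrend span, smoothing)
  are not prescribed by any standard; defaults are documented above and
  every one is a config key.
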