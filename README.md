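# lutphysio

Analysis pipeline for mouse lower-urinary-tract (LUT) physiology
experiments: simultaneous fiber photometry + cystometry, optogenetic
stimulation + external-urethral-sphincter (EUS) EMG, and micturition
video thermography (MVT).  Written for labs that record bladder pressure,
pontine calcium signals, sphincter EMG, and urine-spot thermal images and
need the standard quantitative chain — event detection, peri-event
alignment with shuffle nulls, epoch power statistics, and spot
quantification — as tested, scriptable code rather than ad-hoc
spreadsheet steps.

Because raw in-vivo traces are rarely shared, the package includes a
first-class synthetic-session generator with known ground truth; every
analysis stage is validated by recovering what the generator programmed.

## What it computes

- **Photometry** (`lutphysio.photometry`): block-mean downsampling to
  0.1 s; ΔF/F0 = (F − F0)/F0 with F0 a best-fit curve to the entire trace
  (double-exponential cascade); motion correction by subtracting the
  rescaled isosbestic 405 nm ΔF/F0 from the 465 nm signal; per-event
  normalization (ΔF/F0 − baseline)/baseline × 100 with baseline = mean of
  the 60 s preceding the event; Z = (x − mean)/SD.
- **Cystometry** (`lutphysio.cystometry`): contraction detection on the
  detrended pressure trace; void/NVC gating (single-peak inclusion,
  ≥ 5 cmH2O NVC rise); alignment of voids to max dP/dt (steepest pre-void
  rise) and NVCs to peak pressure.
- **Peri-event analysis** (`lutphysio.perievent`): events × lag matrices
  over ±60 s, mean ± SEM traces, seeded shuffle nulls at random time
  points, equally weighted per-animal subsampling, Kruskal–Wallis + Dunn
  (Holm) group comparisons.
- **EMG epoch power** (`lutphysio.emg`): before/stim/after epochs of equal
  duration, Total Power (TTP, sum of power across all frequencies —
  time-domain and Parseval-equivalent frequency-domain forms),
  TTP_p / (TTP_before + TTP_stim + TTP_after) × 100 normalization,
  baseline-phase artifact exclusion, and per-animal response rates
  (≥ 5% EMG drop; ≥ 3 cmH2O pressure rise over the extrapolated filling
  trend).
- **MVT** (`lutphysio.mvt`): thresholding + connected components,
  pixel-to-cm² calibration from a 10 cm² template, linear volume
  estimation, void/leak/mark classification, scent-marking metrics and
  the ≥ 10-mark / first-5-minutes dominance screen.
- **Synthetic sessions** (`lutphysio.synthetic`): everything above with
  programmed ground truth; deterministic given (params, seed).

See `docs/methods.md` for models, defaults, and limitations.

## Worked example

```python
import numpy as np
from lutphysio.synthetic import SimParams, simulate_session
from lutphysio import cystometry, photometry, perievent

params = SimParams(duration_s=3600.0, n_voids=5, n_nvcs=3, seed=42)
bundle, truth = simulate_session(params)

events = cystometry.detect_events(bundle.pressure, truth.void_times,
                                  animal_id="sim01")
print(events[["event_id", "kind", "t_align_s", "included"]].to_string(index=False))

d465 = photometry.compute_dff(photometry.downsample(bundle.photometry465))
d405 = photometry.compute_dff(photometry.downsample(bundle.photometry405))
dff = photometry.isosbestic_correct(d465, d405)

mat = perievent.build_matrix(dff, events, normalization="percent")
mean, sem, n = perievent.average_trace(mat)
print(f"{n} events aligned; signal peaks "
      f"{mat.lags[np.argmax(mean)]:+.1f} s from void onset")

null = perievent.shuffle_null(dff, n_events=n, seed=0, normalization="percent")
nmean, _, _ = perievent.average_trace(null)
print(f"event-locked peak {mean.max():.1f}% vs shuffle peak {nmean.max():.1f}%")
```

Output:

```
event_id kind   t_align_s  included
    c000 void  368.311460         1
    c001  nvc  757.800000         1
    c002 void 1232.816214         1
    c003  nvc 1644.900000         1
    c004 void 1988.862138         1
    c005 void 2528.561934         1
    c006  nvc 2933.100000         1
    c007 void 3357.956463         1

8 events aligned; signal peaks +1.0 s from void onset
event-locked peak 4.9% vs shuffle peak 0.6%
```

All 5 programmed voids and 3 NVCs are detected and gated; the void rows'
alignment times sit at the steepest pre-void pressure rise (about 5 s
before each contraction peak).  The per-event-normalized calcium signal
peaks just after void onset and stands far above the shuffle-null chance
level, which stays near zero.

## Command line

Each stage is also a subcommand of `lut-physio`, reading and writing
plain-text session files, CSV event tables, and PNG frames:

```sh
lut-physio simulate --config sim.toml --seed 5 --out session/
lut-physio dff      --session session/session.txt --out dff.tsv
lut-physio events   --session session/session.txt --confirmations voids.csv --out events.csv
lut-physio align    --dff dff.tsv --events events.csv --out aligned/
lut-physio emgpower --session session/opto_session.txt --stims session/stim_log.csv --out emg/
lut-physio mvt      --frames frames/ --out mvt/
lut-physio report   --events events.csv --trials emg/trials.csv --out report.json
```

Identical inputs, config, and seed give byte-identical outputs.

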