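# ciliabeat

Cilia beat frequency (CBF) quantification from high-speed video microscopy,
and a framerate-adequacy study on synthetic recordings with known ground
truth.

Motile cilia propel mucus across airway epithelia and cerebrospinal fluid
through the brain ventricles; the standard functional readout is the beat
frequency, measured from a kymograph — the position × time image obtained by
reslicing a movie along a line drawn through the beating cilia. Published
acquisition rates for this measurement vary by more than an order of
magnitude, and the naive guidance ("sample at twice the highest expected
frequency", the Nyquist rate) turns out to be unreliable for noisy
biological recordings. This package is for microscopists and image-analysis
developers who want to (a) quantify CBF from kymographs with either of the
two standard estimators and (b) test, on realistic synthetic data, how fast
a camera must run before those estimators can be trusted.

## What it computes

**Peak-spacing (manual-counting) estimator.** The clearest intensity trace
of the kymograph is selected (highest temporal variance), successive wave
crests are detected, and

```
CBF [Hz] = frame rate [fps] / mean inter-peak spacing [frames].
```

**FFT (automated) estimator.** Each position's temporal spectrum is
computed (mean-removed, rectangular window), squared magnitudes are
averaged across positions, and the *dominant frequency* — the most
prominent local maximum above 2 Hz — is reported. When no sufficiently
prominent peak exists the estimate *fails*; failures are counted, not
hidden.

**Aliasing.** A periodic signal at frequency f sampled below 2f appears at
min_k |f − k·fs|; under-sampling therefore systematically *underestimates*
CBF. The study pipeline quantifies this: cilia populations with known
true CBF are simulated at 600 fps, decimated to 300/200/150/100/60/30 fps
(pure frame decimation, as a slower camera would record), measured by both
estimators, and each cilium's estimate is compared pairwise against its
own 300 fps *reference CBF* — per-framerate ordinary least squares within
reference-CBF bands (0–15, 0–30, 0–50 Hz), an ANCOVA-style test of each
fitted line against the idealized identity line (slope 1, zero residual),
and a Nyquist-margin table binning the relative error by fps / CBF.

## Worked example

A single fast ependymal-like cilium (true CBF 34 Hz), simulated for 1 s at
600 fps and measured after decimation:

```python
from ciliabeat import (BeatModel, simulate_kymograph, downsample_kymograph,
                       cbf_fft, cbf_peak_spacing)

model = BeatModel(true_cbf=34.0, seed=4)
kymo = simulate_kymograph(model, fps=600, duration=1.0, n_positions=20)
for fps in (300, 150, 60, 30):
    low = downsample_kymograph(kymo, fps)
    fft, peaks = cbf_fft(low), cbf_peak_spacing(low)
    print(fps, fft.cbf if not fft.failed else "failed", round(peaks.cbf, 2))
```

prints

```
300 34.0 34.26
150 34.0 34.14
60 26.0 26.67
30 2.0 6.0
```

At 300 and 150 fps (≥ 4.4× the beat frequency) both estimators read the
true 34 Hz. At 60 fps — just below the Nyquist rate of 2 × 34 = 68 fps —
the signal aliases and both methods report ~26 Hz. At 30 fps the
measurement collapses entirely. Even rates slightly above Nyquist leave
little margin for noisy biological recordings: in the full study the mean
relative error is −17% at sampling ratios of 2–3× the beat frequency, −5%
at 3–4×, and ≈0 beyond 4× — the quantitative basis for sampling at 3–4×
the fastest expected CBF.

The same pipeline is scriptable from the shell:

```
ciliabeat simulate --cbf 34 --fps 600 --seed 4 --out kymo.tif
ciliabeat cbf --input kymo.tif --method fft --json report.json
ciliabeat study --seed 1 --out study_output/   # full 234-cilium study
```

`ciliabeat study` writes `records.csv` (one row per cilium × framerate ×
method), regression and slope-test tables, group mean ± SD summaries with
failure fractions, the Nyquist-margin table, per-cilium kymographs, scatter
plots, and a manifest that makes the run exactly reproducible.

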