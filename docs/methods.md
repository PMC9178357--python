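# Methods

## The measurement problem

A kymograph of beating cilia — intensity sampled along a fixed line at
every movie frame — renders periodic ciliary motion as waves whose temporal
spacing encodes the beat frequency (CBF). Two estimators are in common
use: counting wave crests by eye and dividing the frame rate by the mean
inter-crest spacing, and taking the dominant peak of the temporal power
spectrum. Both degrade as the frame rate falls; this package measures how
fast that degradation is, using synthetic recordings whose true CBF is
known, and expresses the answer as a required sampling margin (frame rate
over beat frequency).

## Generative model of a recording

No public repository of high-speed ciliated-tissue recordings exists, so
the study runs on a synthetic generator built to emulate the statistical
structure of 1-second DIC recordings of mouse airway and ependymal
epithelia (600 fps, 0.104 µm/px). The intensity at position x along the
line and time t is

    I(x, t) = baseline + a_c · w(φ_c(t) − 2πx/λ)
              + drift(t) + clutter(t) + ε(x, t),

with components:

- **Waveform** w: fundamental cosine plus a 0.5-amplitude second harmonic
  at phase π/2 and a 0.2-amplitude third harmonic at phase π, normalized to
  unit amplitude. The phases are chosen so the wave is strongly skewed
  (fast effective stroke, slow recovery) yet has a single intensity
  maximum per cycle, as kymograph traces of cilia do. A pure-cosine mode
  is retained for analytic tests.
- **Phase** φ_c: integrated per cycle. Every beat cycle runs at
  f_c + N(0, σ_jitter) and contributes exactly 2π, so jitter is integrated
  (no unbounded phase drift, average rate unbiased). Default
  σ_jitter = 12% of the cilium's rate: cycle-period variability scales
  with the rate, and a fixed absolute jitter would make slow cilia
  implausibly irregular.
- **Cilium blocks**: the line crosses one cilium per 0.7 µm; each block c
  beats at f_c = f·(1 + N(0, 0.06)) with its own phase and a contrast
  a_c = a·(1 + N(0, 0.15)). Real spectra of such ROIs are clusters of
  nearby peaks, not single tones; this is what makes "dominant frequency"
  selection unstable when decimation folds structure across the band.
- **Metachronal gradient**: linear phase advance 2πx/λ within a block,
  λ = 20 µm by default (infinite = synchronous; used by analytic tests).
- **Drift**: Brownian common-mode baseline wander, SD 0.2 after 1 s —
  focus/stage/illumination drift. Being common-mode it survives
  position-averaging and concentrates power in the lowest spectral bins,
  which is why the automated estimator searches only above 2 Hz.
- **Clutter**: white common-mode background, SD 0.1 — out-of-focus motion
  and flowing debris. Its above-Nyquist power folds into the analysis band
  differently at every decimated rate.
- **Noise** ε: i.i.d. Gaussian per pixel, SD 0.15.
- Amplitude 0.35 about a baseline of 0.5; intensities clipped to [0, 1]
  (clipping is logged, never rescaled).

Tissue populations draw true CBFs from truncated normal distributions on
[4, 52] Hz using the four reference presets: airway at room temperature
(14.2 ± 2.4 Hz, n = 57), airway at 37 °C (19.2 ± 7.2 Hz, n = 72), ependyma
at room temperature (22.4 ± 4.7 Hz, n = 39) and ependyma at 37 °C
(34.2 ± 9.0 Hz, n = 66). Truncated-normal sampling is by rejection — exact
and trivially cheap at these n.

The nuisance scales were set once by matching the synthetic study's
behaviour to the reference recordings' published summary statistics (the
per-framerate R² ladder, the depression of group means at 30–60 fps, and
the rising failure rate of automated estimation at low rates) and then
frozen; they are defaults of `BeatModel`, overridable per study.

### What the generator does not emulate

Physically realistic DIC optics, 3-D cilium mechanics, fluid coupling and
mucus transport are out of scope. Two observable consequences matter for
interpreting results. First, a real recording's spectrum carries broadband
*non-stationary* content (waveform changes, transient occlusions) that our
stationary model lacks; consequently the synthetic FFT estimator at
≥ 100 fps is more accurate, and more strongly correlated with its own
300 fps reference, than on real data — R² near 0.99 where real data show
0.4–0.9. Second, our manual-counting emulation reads a single
representative trace, whereas a human integrates the whole 2-D wavefront;
the synthetic manual estimator is therefore somewhat weaker at very low
sampling ratios than a human counter. Passing tests demonstrate the
estimators' mechanics and the aliasing physics, not parity with human
performance on real movies.

## Frame-rate conversion

Down-sampling is pure nearest-index frame decimation: output frame j is
source frame round(j·fps_src/fps_target), with round(fps_target·duration)
output frames. This mimics what a slower camera would have captured;
no temporal averaging ("shutter blur") is applied. Decimation commutes
with kymograph extraction, so studies may decimate kymograph columns
directly — exactly equivalent to decimating the movie and re-applying the
identical ROI, without rendering hundreds of gigabytes of frames. The
movie → line-ROI → kymograph route (bilinear interpolation at unit-pixel
spacing along the polyline, perpendicular averaging across the ROI width)
is implemented and verified separately against analytic ramps and the
round trip through the simulator.

Source recordings are standardized to exactly 600 fps so the target grid
(300, 200, 150, 100, 60, 30) consists of near-integer decimations.

## Estimators

**Peak spacing.** The representative trace is the position with the
highest temporal variance (a proxy for a human picking the clearest cilium
edge). The beat period is first read from the trace's autocorrelation: the
strongest positive-lag peak, with parabolic sub-sample refinement of peak
heights and lags, taking the smallest lag within 90% of the best (the
octave guard of pitch detection — raw sampled heights are biased against
non-integer periods, and asymmetric waveforms put a weak bump at the half
period). The trace is then smoothed with a centered moving average whose
window scales with the period (≈ period/8, odd, capped at 5 frames — even
windows shift peaks by half a frame), local maxima are detected and
greedily thinned so surviving peaks are ≥ 0.6 × period apart (highest peak
wins; leftmost on exact ties), and CBF = fps / mean(inter-peak spacing).
Fewer than 3 peaks is a failure, reported as such. All adaptive choices
can be overridden with explicit `min_separation` / `smoothing` arguments.

**FFT dominant frequency.** Per-position temporal mean removal,
rectangular window, no zero padding; squared DFT magnitudes averaged
across positions; one search for the most prominent local maximum in
[2 Hz, fps/2]. The 2 Hz floor keeps drift/DC leakage of 1-s recordings out
of the search band. A peak must reach prominence ≥ 0.1 × max(power) or the
estimate fails — this is the countable "calculation error" of automated
CBF analysis. Estimates are bin frequencies (spacing fps/T, i.e. 1 Hz for
1-s recordings) by default; quadratic sub-bin interpolation is available
behind a flag. Equal-prominence ties resolve to the lower frequency.
Averaging the spectrum across positions (one estimate, at most one failure
per kymograph) is the default; per-position estimation with a consensus is
deliberately not the default because it changes the failure accounting.

## Study statistics

Every cilium is simulated once at 600 fps and measured at each grid rate
by each method; its 300 fps estimate is the *reference CBF*. For each
framerate × method × reference-band (0–15, 0–30, 0–50 Hz; the band filters
on the reference only, never on the low-rate estimate):

- Ordinary least squares of estimate on reference (slope, intercept, R²,
  slope SE). Failed estimates are excluded and the exclusion is counted;
  fewer than 3 usable records is an explicit error, not a silent skip.
- Slope-vs-identity test: the observed points are pooled with an idealized
  companion dataset with the same reference values and y = x exactly, and
  the standard two-group slope-heterogeneity statistic is computed with
  pooled residual variance — the idealized group contributes zero residual
  sum of squares and n − 2 degrees of freedom:

      t = (b − 1) / sqrt(s²·(2/Sxx)),   s² = RSS_obs / (2n − 4),

  referred to t(2n − 4), two-sided. Significance at α = 0.05, per
  framerate, without multiplicity correction — matching per-framerate
  reporting conventions. With n ≈ 234 and synthetic residual SDs of
  ~0.5 Hz this test resolves slope biases below 1%; it is deliberately not
  de-tuned.
- Group summaries: mean ± sample SD per tissue × framerate × method with
  failures excluded from moments but counted in the failure fraction; SD
  is reported as null for singleton groups.
- Nyquist margin: records binned by fps / reference CBF with edges
  (0, 1, 2, 3, 4, ∞); mean and SD of (estimate − reference)/reference per
  bin. The 2–3 bin sits at roughly −17% mean error and the 4+ bin at ≈0,
  which is the quantitative form of the "sample at 3–4× the fastest
  expected CBF" recommendation.

Omnibus two-way ANOVA with post-hoc multiple comparisons across
tissue/temperature groups is routine statistics and is left to standard
packages on the exported CSV tables; the statistics implemented here are
the ones carrying the sampling-rate claim.

## Numerical and design notes

- All generators take explicit seeds; a study is reproducible to the byte
  from its manifest (config + seed + package version).
- Decimation indices are clipped to the valid frame range; the frame-count
  contract |T_out − target_fps·duration| ≤ 1 holds for every target.
- Kymographs are stored position × time in memory; file export transposes
  to the image convention (rows = frames) and says so in the JSON sidecar.
- Coordinates are 0-based pixel centers, x right, y down. ROI width
  samples are averaged perpendicular to the local segment direction with
  edge replication at frame borders.
- AVI I/O is not provided (no codec backend is part of the dependency
  set); multi-page TIFF with fps metadata is the interchange format, and
  AVI paths produce an explicit error saying so.
- Default study sizes (234 cilia, 6 framerates, 2 methods, 20-pixel ROIs,
  1-s recordings) complete in seconds on one CPU; they are the package's
  standard problem size for tests and the acceptance script.

## Known limitations

- The synthetic FFT estimator above 100 fps is nearly exact by
  construction (all 1-s recordings share a 1 Hz bin grid), so
  framerate-accuracy curves for the automated method saturate earlier than
  on real recordings; conclusions about *when it breaks* (≤ 60 fps, and
  ratio < 3) transfer, conclusions about its real-data scatter at high
  rates do not.
- The manual-counting emulation is a single-trace algorithm; treat its
  absolute low-rate accuracy as a lower bound on a human counter's.
- Frequencies at exactly the Nyquist bin (f = fps/2) are not resolvable as
  spectrum-interior peaks; population truncation at 52 Hz keeps this case
  out of the default study at every rate ≥ 150 fps.
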