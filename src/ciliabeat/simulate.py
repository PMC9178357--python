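"""Synthetic beating-cilia recordings with known ground-truth beat frequency.

Real high-speed DIC recordings of ciliated epithelia are not publicly
archived, so every downstream stage of this package is exercised on
synthetic data whose statistical structure emulates such recordings:
1-second movies at 600 fps, 0.104 µm/px, periodic but non-sinusoidal
intensity oscillations, tissue-level beat-frequency distributions
(airway slower than ependyma, both faster at 37 °C), a linear spatial
phase gradient standing in for the metachronal wave, and the nuisance
structure that makes real kymographs hard: cycle-to-cycle frequency
jitter, per-cilium frequency/contrast heterogeneity along the line,
slow common-mode intensity drift, broadband common-mode clutter, and
per-pixel Gaussian noise.

The intensity trace at position ``x`` along the line of cilia is

    I(x, t) = baseline + a_c * w(phi_c(t) - 2*pi*x / lambda)
              + drift(t) + clutter(t) + noise(x, t)

where ``c`` indexes the cilium block containing ``x``, ``w`` is a
unit-amplitude harmonic waveform (fundamental plus overtones, modelling
the asymmetric effective/recovery stroke), ``phi_c`` the block's
integrated beat phase (advancing 2*pi per cycle, with per-cycle frequency
jitter so long recordings stay phase-coherent on average), and ``lambda``
the metachronal wavelength in µm.  Intensities are clipped to [0, 1];
clipping is logged, never rescaled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .video import DEFAULT_PIXEL_SIZE_UM, Kymograph, MovieStack

logger = logging.getLogger(__name__)

__all__ = [
    "BeatModel",
    "PopulationSpec",
    "simulate_kymograph",
    "simulate_movie",
    "preset_population",
    "sample_population",
    "PRESET_LABELS",
]

#: Default overtone content: second and third harmonics phased so the wave
#: is strongly skewed (fast effective stroke, slow recovery) yet has a single
#: intensity maximum per cycle, as DIC traces of beating cilia do.
DEFAULT_HARMONICS: tuple[tuple[float, float], ...] = (
    (0.5, np.pi / 2), (0.2, np.pi))


@dataclass
class BeatModel:
    """Generative parameters for one cilium's intensity oscillation.

    Parameters
    ----------
    true_cbf : float
        Ground-truth beat frequency in Hz (> 0).
    amplitude : float
        Intensity modulation depth in (0, 1].
    baseline : float
        Mean intensity in [0, 1].
    harmonics : sequence of (relative amplitude, phase offset in radians)
        Overtones at integer multiples (2f, 3f, ...) of the fundamental,
        relative to the fundamental's unit amplitude.  Empty = pure sinusoid.
    metachronal_wavelength : float
        Spatial wavelength of the phase gradient in µm; ``inf`` means all
        positions beat synchronously.
    noise_sd : float
        Standard deviation of additive Gaussian intensity noise (>= 0).
    freq_jitter_sd : float or None
        Cycle-to-cycle standard deviation of the instantaneous beat
        frequency, in Hz (>= 0).  None (the default) resolves to 12% of
        ``true_cbf`` — cycle-period variability scales with the beat rate.
    drift_sd : float
        Scale of slow common-mode intensity drift (focus/stage/illumination
        wander), as the standard deviation of a Brownian baseline excursion
        after 1 s (>= 0).  Shared by all positions, so it survives
        position-averaging — the low-frequency background that automated
        spectral analysis must contend with.
    background_sd : float
        SD of temporally broadband, spatially common-mode background
        clutter (out-of-focus motion, flowing debris, shared camera
        artefacts; >= 0).  Because it is coherent across positions it
        survives position-averaging, and because it is broadband its
        above-Nyquist power folds into the analysis band differently at
        every decimated frame rate — the clutter floor that automated
        dominant-frequency picking contends with at low fps.
    freq_spread_rel : float
        Relative SD of per-cilium frequency heterogeneity along the ROI
        (>= 0).  A line ROI crosses several cilia; each contiguous block of
        ``cilium_extent_um`` beats at its own frequency
        true_cbf * (1 + N(0, freq_spread_rel)) with its own phase, so the
        kymograph spectrum is a cluster of nearby peaks rather than a
        single tone — the structure that makes "dominant frequency"
        selection unstable at low sampling rates.
    amplitude_spread_rel : float
        Relative SD of per-cilium modulation depth (>= 0); makes one
        cilium the visibly clearest, as in real fields.
    cilium_extent_um : float
        Extent of one cilium block along the ROI, µm (> 0).
    seed : int
        Seed for the model's private random generator.
    """

    true_cbf: float
    amplitude: float = 0.35
    baseline: float = 0.5
    harmonics: Sequence[tuple[float, float]] = DEFAULT_HARMONICS
    metachronal_wavelength: float = 20.0
    noise_sd: float = 0.15
    freq_jitter_sd: float | None = None
    drift_sd: float = 0.2
    background_sd: float = 0.1
    freq_spread_rel: float = 0.06
    amplitude_spread_rel: float = 0.15
    cilium_extent_um: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_cbf > 0:
            raise ValueError(f"true_cbf must be > 0 Hz, got {self.true_cbf}")
        if not 0 < self.amplitude <= 1:
            raise ValueError(f"amplitude must be in (0, 1], got {self.amplitude}")
        if not 0 <= self.baseline <= 1:
            raise ValueError(f"baseline must be in [0, 1], got {self.baseline}")
        if self.freq_jitter_sd is None:
            self.freq_jitter_sd = 0.12 * self.true_cbf
        if self.noise_sd < 0 or self.freq_jitter_sd < 0 or self.drift_sd < 0 \
                or self.background_sd < 0 or self.freq_spread_rel < 0 \
                or self.amplitude_spread_rel < 0:
            raise ValueError("nuisance SD parameters must be >= 0")
        if not self.cilium_extent_um > 0:
            raise ValueError("cilium_extent_um must be > 0")
        if not self.metachronal_wavelength > 0:
            raise ValueError("metachronal_wavelength must be > 0 (use inf for synchrony)")

    # -- waveform ----------------------------------------------------------
    def waveform(self, phase: np.ndarray) -> np.ndarray:
        """Unit-amplitude periodic waveform w(phase).

        Sum of the fundamental cosine and the configured overtones,
        normalized so max |w| = 1 over one period.
        """
        w = np.cos(phase)
        for k, (rel, off) in enumerate(self.harmonics, start=2):
            w = w + rel * np.cos(k * phase + off)
        return w / self._waveform_peak()

    def _waveform_peak(self) -> float:
        theta = np.linspace(0.0, 2 * np.pi, 4096, endpoint=False)
        w = np.cos(theta)
        for k, (rel, off) in enumerate(self.harmonics, start=2):
            w = w + rel * np.cos(k * theta + off)
        return float(np.max(np.abs(w)))


def _beat_phase(f: float, jitter_sd: float, t: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Integrated beat phase phi(t) with per-cycle frequency jitter.

    Each beat cycle i runs at frequency f_i = f + N(0, jitter_sd) (floored
    at 10% of f) and contributes exactly 2*pi of phase, so the average rate
    stays centred on f and the phase never drifts off by construction — the
    jitter is integrated, not white.
    """
    if jitter_sd == 0:
        return 2 * np.pi * f * t
    duration = float(t[-1]) if len(t) else 0.0
    n_cycles = int(math.ceil(duration * (f + 5 * jitter_sd))) + 5
    f_i = f + rng.normal(0.0, jitter_sd, size=n_cycles)
    f_i = np.maximum(f_i, 0.1 * f)
    cycle_dur = 1.0 / f_i
    starts = np.concatenate([[0.0], np.cumsum(cycle_dur)])
    while starts[-1] < duration:  # jitter made cycles shorter than expected
        extra = f + rng.normal(0.0, jitter_sd, size=16)
        extra = np.maximum(extra, 0.1 * f)
        f_i = np.concatenate([f_i, extra])
        starts = np.concatenate([starts, starts[-1] + np.cumsum(1.0 / extra)])
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(f_i) - 1)
    return 2 * np.pi * (idx + (t - starts[idx]) * f_i[idx])


def _clip_logged(values: np.ndarray, what: str) -> np.ndarray:
    n_out = int(np.sum((values < 0) | (values > 1)))
    if n_out:
        frac = n_out / values.size
        level = logging.WARNING if frac > 0.10 else logging.DEBUG
        logger.log(level, "%s: clipped %d/%d samples (%.1f%%) to [0, 1]",
                   what, n_out, values.size, 100 * frac)
    return np.clip(values, 0.0, 1.0)


def simulate_kymograph(model: BeatModel, fps: float, duration: float,
                       n_positions: int,
                       pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
                       cilium_id: str = "") -> Kymograph:
    """Simulate the kymograph a line ROI through beating cilia would yield.

    Parameters
    ----------
    model : BeatModel
    fps : float
        Sampling rate in frames/s (> 0).
    duration : float
        Recording length in seconds (> 0); round(fps * duration) frames.
    n_positions : int
        Number of pixel positions along the line (>= 1).
    pixel_size : float
        Spacing of positions in µm/px (phase gradient scale).

    Returns
    -------
    Kymograph with shape (n_positions, round(fps * duration)); deterministic
    for a fixed ``model.seed``.
    """
    if not fps > 0:
        raise ValueError(f"fps must be > 0, got {fps}")
    if not duration > 0:
        raise ValueError(f"duration must be > 0 s, got {duration}")
    if n_positions < 1:
        raise ValueError(f"n_positions must be >= 1, got {n_positions}")
    rng = np.random.default_rng(model.seed)
    T = int(round(fps * duration))
    t = np.arange(T) / fps
    x = np.arange(n_positions) * pixel_size
    if np.isinf(model.metachronal_wavelength):
        spatial = np.zeros(n_positions)
    else:
        spatial = 2 * np.pi * x / model.metachronal_wavelength

    # The ROI crosses one cilium per `cilium_extent_um`; each block beats at
    # its own frequency/phase/contrast around the model's central values.
    block_px = max(1, int(round(model.cilium_extent_um / pixel_size)))
    starts = list(range(0, n_positions, block_px))
    heterogeneous = model.freq_spread_rel > 0 or model.amplitude_spread_rel > 0
    values = np.empty((n_positions, T))
    if not heterogeneous:
        phi = _beat_phase(model.true_cbf, model.freq_jitter_sd, t, rng)
        values[:] = model.baseline + model.amplitude * model.waveform(
            phi[None, :] - spatial[:, None])
    else:
        for b, s in enumerate(starts):
            stop = min(s + block_px, n_positions)
            f_b = model.true_cbf * max(
                0.1, 1.0 + rng.normal(0.0, model.freq_spread_rel))
            amp_b = model.amplitude * max(
                0.05, 1.0 + rng.normal(0.0, model.amplitude_spread_rel))
            theta_b = rng.uniform(0.0, 2 * np.pi)
            phi_b = _beat_phase(f_b, model.freq_jitter_sd, t, rng) + theta_b
            values[s:stop] = model.baseline + amp_b * model.waveform(
                phi_b[None, :] - spatial[s:stop, None])
    if model.drift_sd > 0:
        # Brownian baseline wander, common to all positions; scaled so its
        # SD after 1 s of integration equals drift_sd.
        steps = rng.normal(0.0, model.drift_sd / np.sqrt(fps), size=T)
        values = values + np.cumsum(steps)[None, :]
    if model.background_sd > 0:
        values = values + rng.normal(0.0, model.background_sd, size=T)[None, :]
    if model.noise_sd > 0:
        values = values + rng.normal(0.0, model.noise_sd, size=values.shape)
    values = _clip_logged(values, f"kymograph(cbf={model.true_cbf:g} Hz)")
    return Kymograph(values=values, source_fps=float(fps), roi=None,
                     cilium_id=cilium_id)


def simulate_movie(model: BeatModel, fps: float, duration: float,
                   height: int = 240, width: int = 1440,
                   band_height: int | None = None,
                   pixel_size: float = DEFAULT_PIXEL_SIZE_UM) -> MovieStack:
    """Render a movie in which a horizontal ciliated band oscillates.

    The band occupies the middle rows of each frame (default one fifth of
    the height); every column of the band carries the same temporal trace a
    directly simulated kymograph would, with the metachronal phase gradient
    running along x.  Rows outside the band sit at the model baseline.
    Default geometry matches the reference acquisition: 1440 × 240 px at
    0.104 µm/px (a 150 × 25 µm field).
    """
    if height < 1 or width < 1:
        raise ValueError(f"frame dimensions must be >= 1, got {height}x{width}")
    kymo = simulate_kymograph(
        replace(model, noise_sd=0.0), fps, duration, n_positions=width,
        pixel_size=pixel_size)
    T = kymo.n_frames
    if band_height is None:
        band_height = max(1, height // 5)
    band_height = min(band_height, height)
    y0 = (height - band_height) // 2
    frames = np.full((T, height, width), model.baseline, dtype=np.float32)
    frames[:, y0:y0 + band_height, :] = kymo.values.T[:, None, :].astype(np.float32)
    if model.noise_sd > 0:
        # noise rng continues the model stream after the band was generated
        rng = np.random.default_rng((model.seed, 1))
        frames = frames + rng.normal(
            0.0, model.noise_sd, size=frames.shape).astype(np.float32)
    frames = _clip_logged(frames, f"movie(cbf={model.true_cbf:g} Hz)")
    return MovieStack(
        frames=frames, fps=float(fps), pixel_size=pixel_size,
        provenance=(f"synthetic cilia movie: f={model.true_cbf:g} Hz, "
                    f"seed={model.seed}, band rows {y0}..{y0 + band_height - 1}"),
    )


# ---------------------------------------------------------------------------
# Tissue populations
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """A tissue/temperature population of cilia beat frequencies.

    Beat frequencies are drawn from a normal(mean_cbf, sd_cbf) truncated to
    [min_cbf, max_cbf]; all other (nuisance) generator parameters are shared
    across the population via ``noise_profile``.
    """

    label: str
    mean_cbf: float
    sd_cbf: float
    n: int
    min_cbf: float = 4.0
    max_cbf: float = 52.0
    noise_profile: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not self.min_cbf > 0:
            raise ValueError(f"min_cbf must be > 0, got {self.min_cbf}")
        if not self.min_cbf <= self.mean_cbf <= self.max_cbf:
            raise ValueError(
                f"mean_cbf {self.mean_cbf} outside [{self.min_cbf}, {self.max_cbf}]"
            )
        if self.sd_cbf < 0:
            raise ValueError(f"sd_cbf must be >= 0, got {self.sd_cbf}")


# Group means ± SD (Hz) and per-group cilium counts of the four reference
# tissue/temperature populations; overall observed range 4–52 Hz.
_PRESETS: dict[str, tuple[float, float, int]] = {
    "airway_RT": (14.2, 2.4, 57),
    "airway_37C": (19.2, 7.2, 72),
    "ependyma_RT": (22.4, 4.7, 39),
    "ependyma_37C": (34.2, 9.0, 66),
}

PRESET_LABELS: tuple[str, ...] = tuple(_PRESETS)


def preset_population(label: str, n: int | None = None,
                      noise_profile: dict | None = None) -> PopulationSpec:
    """Return one of the four reference tissue/temperature populations.

    Labels: ``airway_RT`` (14.2 ± 2.4 Hz), ``airway_37C`` (19.2 ± 7.2 Hz),
    ``ependyma_RT`` (22.4 ± 4.7 Hz), ``ependyma_37C`` (34.2 ± 9.0 Hz);
    all truncated to the observed 4–52 Hz range.  ``n`` defaults to the
    reference per-group cilium count.
    """
    if label not in _PRESETS:
        raise ValueError(
            f"unknown population label {label!r}; valid labels: {sorted(_PRESETS)}"
        )
    mean, sd, n_default = _PRESETS[label]
    return PopulationSpec(
        label=label, mean_cbf=mean, sd_cbf=sd,
        n=n if n is not None else n_default,
        min_cbf=4.0, max_cbf=52.0,
        noise_profile=dict(noise_profile or {}),
    )


def sample_population(spec: PopulationSpec, seed: int) -> list[BeatModel]:
    """Draw ``spec.n`` beat models with truncated-normal frequencies.

    Sampling is by rejection (exact for the truncated normal at these n);
    each model receives its own child seed so downstream simulation is
    reproducible per cilium.
    """
    rng = np.random.default_rng(seed)
    freqs = np.empty(spec.n)
    filled = 0
    while filled < spec.n:
        draw = rng.normal(spec.mean_cbf, spec.sd_cbf, size=max(spec.n, 64))
        ok = draw[(draw >= spec.min_cbf) & (draw <= spec.max_cbf)]
        take = min(len(ok), spec.n - filled)
        freqs[filled:filled + take] = ok[:take]
        filled += take
    child_seeds = rng.integers(0, 2**31, size=spec.n)
    return [
        BeatModel(true_cbf=float(f), seed=int(s), **spec.noise_profile)
        for f, s in zip(freqs, child_seeds)
    ]
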