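"""Study configuration: a single validated, serializable set of knobs.

A :class:`StudyConfig` fixes everything a full synthetic framerate study
needs — populations, simulation rate and duration, the framerate grid and
reference rate, estimator parameters, the generator noise profile, and the
seed — and is persisted verbatim next to the outputs so every run is
reproducible from its manifest alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .simulate import PRESET_LABELS, PopulationSpec, preset_population

__all__ = ["StudyConfig", "load_config"]

_ESTIMATOR_KEYS = {"min_freq", "min_prominence", "min_separation", "smoothing"}
_NOISE_KEYS = {"amplitude", "baseline", "harmonics", "metachronal_wavelength",
               "noise_sd", "freq_jitter_sd", "drift_sd", "background_sd",
               "freq_spread_rel", "amplitude_spread_rel", "cilium_extent_um"}


@dataclass
class StudyConfig:
    """Validated configuration of one framerate study run."""

    populations: list = field(default_factory=lambda: list(PRESET_LABELS))
    simulation_fps: float = 600.0
    duration: float = 1.0
    fps_grid: list = field(default_factory=lambda: [300, 200, 150, 100, 60, 30])
    reference_fps: float = 300.0
    methods: list = field(default_factory=lambda: ["peak_spacing", "fft"])
    n_positions: int = 20
    estimator: dict = field(default_factory=dict)
    noise_profile: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "study_output"
    write_kymographs: bool = True
    write_movies: bool = False
    write_plots: bool = True

    def __post_init__(self) -> None:
        if self.simulation_fps <= 0 or self.duration <= 0:
            raise ValueError("simulation_fps and duration must be positive")
        if float(self.reference_fps) not in {float(f) for f in self.fps_grid}:
            raise ValueError(
                f"reference_fps {self.reference_fps} not in fps_grid {self.fps_grid}")
        if max(self.fps_grid) > self.simulation_fps:
            raise ValueError("fps_grid rates cannot exceed simulation_fps")
        bad = set(self.estimator) - _ESTIMATOR_KEYS
        if bad:
            raise ValueError(f"unknown estimator keys: {sorted(bad)}; "
                             f"valid: {sorted(_ESTIMATOR_KEYS)}")
        bad = set(self.noise_profile) - _NOISE_KEYS
        if bad:
            raise ValueError(f"unknown noise_profile keys: {sorted(bad)}; "
                             f"valid: {sorted(_NOISE_KEYS)}")
        for m in self.methods:
            if m not in ("peak_spacing", "fft"):
                raise ValueError(f"unknown method {m!r}")

    def population_specs(self) -> list[PopulationSpec]:
        """Resolve population entries (preset labels or explicit dicts)."""
        specs = []
        for p in self.populations:
            if isinstance(p, str):
                specs.append(preset_population(p, noise_profile=self.noise_profile))
            elif isinstance(p, dict):
                d = dict(p)
                d.setdefault("noise_profile", dict(self.noise_profile))
                specs.append(PopulationSpec(**d))
            elif isinstance(p, PopulationSpec):
                specs.append(p)
            else:
                raise ValueError(f"cannot interpret population entry {p!r}")
        return specs

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> StudyConfig:
    """Load a YAML/JSON config file and apply keyword overrides (flags win).

    Unknown keys in the file are rejected with a list of the offenders.
    """
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        valid = {f.name for f in fields(StudyConfig)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; valid keys: {sorted(valid)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return StudyConfig(**data)
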