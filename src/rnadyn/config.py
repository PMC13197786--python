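"""Analysis configuration.

Every numeric rule of the pipeline lives here so that a single flat
key-value file reproduces an analysis end to end.  Defaults encode the
standard operating point of the method: a 300-nm colocalization radius
(the diffraction limit of the imaging system), ON calling at 1.5x local
background sustained for at least 1.5 min, trajectory linking gated at
25 px with gaps shorter than 3 frames, a 14-frame minimum track length,
MSD fitting at lags 2-4 dt, and up to four scoreable alleles per
(tetraploid MEF) cell.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration input."""


@dataclass
class AnalysisConfig:
    #: colocalization radius in micrometres (diffraction limit ~300 nm)
    coloc_radius_um: float = 0.3
    #: a transcription site is ON when intensity > factor x local background
    on_threshold_factor: float = 1.5
    #: minimum sustained duration for an ON call, minutes
    min_on_duration_min: float = 1.5
    #: rolling-mean window (frames) applied to intensity traces
    smooth_window_frames: int = 3
    #: max MSD (um^2) over the fit lags below which a track is stationary
    stationary_msd_um2: float = 0.025
    #: net start-to-end displacement (um) above which a track is directed
    directed_net_disp_um: float = 1.5
    #: minimum mean turning-angle cosine for a directed call; ~2 SD above
    #: zero for tracks of >= 25 steps, so a diffusive excursion with a
    #: large net displacement is not mistaken for unidirectional transport
    directed_min_persistence: float = 0.2
    #: a corralled call requires the late MSD slope (in diffusion units)
    #: to sit this many standard errors below the fitted D, so that the
    #: noisy per-trajectory slope of a freely diffusing molecule does not
    #: fire the rule at random
    corralled_significance_se: float = 2.0
    #: per-frame linking gate in pixels
    max_link_disp_px: float = 25.0
    #: gaps of missed detections must be shorter than this many frames
    max_gap_frames: int = 3
    #: minimum number of (consecutive) frames per analysed trajectory
    min_traj_frames: int = 14
    #: a spot must persist over at least this many consecutive z slices
    min_z_slices: int = 3
    #: maximum number of transcription sites per cell
    max_alleles: int = 4
    #: MSD lags (multiples of dt) used for the diffusion fit
    fit_lags: tuple = (2, 3, 4)
    #: camera pixel size at the sample, micrometres per pixel
    #: (6.5 um camera pixel / 150x magnification)
    pixel_size_um: float = 0.0433
    #: nuclear spots at least this many times the single-molecule
    #: reference intensity are classified as transcription sites
    ts_intensity_factor: float = 2.0
    #: lateral radius (px) for chaining detections across z slices
    z_match_radius_px: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "coloc_radius_um",
            "on_threshold_factor",
            "min_on_duration_min",
            "stationary_msd_um2",
            "directed_net_disp_um",
            "max_link_disp_px",
            "pixel_size_um",
            "ts_intensity_factor",
            "z_match_radius_px",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("smooth_window_frames", "min_traj_frames", "min_z_slices", "max_alleles"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.max_gap_frames < 0:
            raise ConfigError("max_gap_frames must be >= 0")
        lags = tuple(int(x) for x in self.fit_lags)
        if len(lags) < 2 or list(lags) != sorted(lags) or len(set(lags)) != len(lags):
            raise ConfigError("fit_lags must be >= 2 strictly increasing lags")
        self.fit_lags = lags


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a flat ``key: value`` YAML file.

    Unknown keys raise :class:`ConfigError` (fail loud rather than
    silently ignoring a typo that would change an analysis).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain key: value pairs")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    data["fit_lags"] = list(config.fit_lags)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
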