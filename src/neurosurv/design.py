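"""Experiment layout and generative-model parameter containers.

An experiment is a hierarchy of plates (strata), wells (clusters of
neurons sharing transfection conditions), imaging fields within wells,
and neurons within fields.  Fields are imaged at a fixed cadence
(default every 24 h) from time 0 to the end of follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "ExperimentDesign",
    "ReporterDynamics",
    "HazardModel",
    "ImagingModel",
    "ConfigurationError",
]


class ConfigurationError(ValueError):
    """A design or model parameter violates its invariants."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Plate / well / field / neuron layout plus the imaging schedule.

    ``group_of_well`` maps a within-plate well index (0-based) to a group
    label; the same assignment is applied on every plate.  Frame times are
    ``0, frame_interval, ..., end_of_followup``.
    """

    plates: int = 2
    wells_per_plate: int = 8
    fields_per_well: int = 15
    neurons_per_field: int = 10
    group_of_well: Mapping[int, str] = field(
        default_factory=lambda: {w: ("control" if w < 4 else "mutant") for w in range(8)}
    )
    frame_interval: float = 24.0
    end_of_followup: float = 120.0
    image_shape: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        for name in ("plates", "wells_per_plate", "fields_per_well", "neurons_per_field"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be > 0")
        if self.end_of_followup < self.frame_interval:
            raise ConfigurationError("end_of_followup must be >= frame_interval")
        missing = [w for w in range(self.wells_per_plate) if w not in self.group_of_well]
        if missing:
            raise ConfigurationError(f"wells without a group label: {missing}")
        if any(s < 16 for s in self.image_shape):
            raise ConfigurationError("image_shape too small")

    @property
    def frame_times(self) -> np.ndarray:
        """Imaging times in hours, 0 through end_of_followup inclusive."""
        n = int(np.floor(self.end_of_followup / self.frame_interval + 1e-9)) + 1
        return np.arange(n) * self.frame_interval

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for w in range(self.wells_per_plate):
            g = self.group_of_well[w]
            if g not in seen:
                seen.append(g)
        return seen

    @property
    def n_neurons(self) -> int:
        return self.plates * self.wells_per_plate * self.fields_per_well * self.neurons_per_field


@dataclass(frozen=True)
class ReporterDynamics:
    """Per-neuron fluorescence trajectory model.

    Red channel reports construct expression (flat in time, lognormal
    across cells).  Green channel reports stress-pathway activity:
    lognormal basal level, optional group-dependent exponential drift,
    and an anticipatory surge ramping the level up by ``surge_fold``
    over the last ``surge_lead_h`` hours before death in a
    ``responder_fraction`` of dying neurons.
    """

    basal_red: float = 3000.0
    basal_green: float = 2000.0
    cell_sd_log: float = 0.4
    green_rise_per_h: Mapping[str, float] = field(default_factory=dict)
    surge_fold: float = 2.0
    surge_lead_h: float = 48.0
    responder_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.basal_red <= 0 or self.basal_green <= 0:
            raise ConfigurationError("basal intensities must be > 0")
        if self.cell_sd_log <= 0:
            raise ConfigurationError("cell_sd_log must be > 0")
        if self.surge_fold < 1.0:
            raise ConfigurationError("surge_fold must be >= 1")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ConfigurationError("responder_fraction must be in [0, 1]")


@dataclass(frozen=True)
class HazardModel:
    """Proportional-hazards death model h(t|x) = h0(t) * exp(b_group + gamma * z(t)).

    The baseline is Weibull with shape k and scale lam (hours);
    k = 1 recovers the constant-rate exponential with rate 1/lam.
    ``group_log_hr`` holds per-group log hazard ratios (reference group 0).
    ``reporter_log_hr`` (gamma) acts per unit of the standardized
    log-reporter level z(t), held piecewise-constant between frames.
    """

    shape: float = 1.3
    scale: float = 150.0
    group_log_hr: Mapping[str, float] = field(default_factory=dict)
    reporter_log_hr: float = 0.0
    reporter: ReporterDynamics = field(default_factory=ReporterDynamics)
    well_frailty_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ConfigurationError("Weibull shape and scale must be > 0")
        if self.well_frailty_sd < 0:
            raise ConfigurationError("well_frailty_sd must be >= 0")

    @classmethod
    def constant_rate(cls, rate: float, **kw) -> "HazardModel":
        """Exponential baseline with hazard ``rate`` per hour (rate 0 allowed)."""
        if rate < 0:
            raise ConfigurationError("rate must be >= 0")
        if rate == 0.0:
            return cls(shape=1.0, scale=np.inf, **kw)
        return cls(shape=1.0, scale=1.0 / rate, **kw)

    def cumulative_baseline(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.isinf(self.scale):
            return np.zeros_like(t)
        return (t / self.scale) ** self.shape

    def invert_cumulative_baseline(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        return self.scale * h ** (1.0 / self.shape)


@dataclass(frozen=True)
class ImagingModel:
    """Camera / optics model for rendering fields.

    Neurons are isotropic Gaussian blobs of width ``psf_sigma`` on a flat
    background; Poisson shot noise on (signal + background) plus Gaussian
    read noise; multiplicative photobleaching per frame; optional frame-to-
    frame centroid jitter (``motion_sd``) emulating small cell movements.
    """

    psf_sigma: float = 2.0
    background_level: float = 100.0
    photobleach_rate: float = 0.02
    read_noise_sd: float = 2.0
    poisson_noise: bool = True
    min_separation: float = 18.0
    motion_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ConfigurationError("psf_sigma must be > 0")
        if self.background_level < 0:
            raise ConfigurationError("background_level must be >= 0")
        if not 0.0 <= self.photobleach_rate < 1.0:
            raise ConfigurationError("photobleach_rate must be in [0, 1)")
        if self.min_separation < 4 * self.psf_sigma:
            raise ConfigurationError("min_separation must be >= 4 * psf_sigma")
        if self.read_noise_sd < 0 or self.motion_sd < 0:
            raise ConfigurationError("noise parameters must be >= 0")

    @property
    def noise_sd_at_background(self) -> float:
        """Approximate background noise sd (Poisson variance + read noise)."""
        var = (self.background_level if self.poisson_noise else 0.0) + self.read_noise_sd**2
        return float(np.sqrt(var))
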