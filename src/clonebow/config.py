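"""Configuration objects for the generator and the analysis pipeline."""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

from .colors import ColorThresholds

# Recombination outcomes, in the order used by ``recombination_probs``.
# ``default_farred`` is the unrecombined state (far-red reporter, outside the
# RGB simplex); the three recombined fluorophores map onto the RGB axes:
# tdTomato -> R, YFP -> G, mTurquoise -> B.
OUTCOMES = ("default_farred", "yfp", "turquoise", "tdtomato")
OUTCOME_RGB = {
    "yfp": (0.0, 1.0, 0.0),
    "turquoise": (0.0, 0.0, 1.0),
    "tdtomato": (1.0, 0.0, 0.0),
}


class InvalidConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Generative parameters for synthetic multicolor clone cohorts.

    Defaults emulate the hindbrain-boundary time-lapse conditions: hourly
    imaging from 32 to 45 hpf, 44 founder clones, division modes drawn as
    40% PP / 58% PN / 2% NN, sister divisions offset by a zero-clipped
    normal delay of mean 2.8 h (s.d. 1.9 h), and a ventricular zone
    occupying the apical half of the dorsoventral extent.

    ``division_prob_per_frame`` is the per-frame (1 h) division hazard of a
    progenitor whose division is not already scheduled by the sister-delay
    coupling; 0.035 makes roughly half of the progenitors present at t0
    divide within the 13-h window.
    """

    n_founders: int = 44
    copy_number_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.50, 2: 0.35, 3: 0.15}
    )
    recombination_probs: tuple[float, float, float, float] = (0.10, 0.30, 0.30, 0.30)
    red_manipulated_fraction: float = 0.0
    division_prob_per_frame: float = 0.043
    mode_probs: tuple[float, float, float] = (0.40, 0.58, 0.02)
    # When set, founders labeled ``manipulated`` use these instead (models a
    # perturbation carried by the red fluorophore in functional experiments).
    manipulated_mode_probs: Optional[tuple[float, float, float]] = None
    manipulated_division_prob: Optional[float] = None
    sister_delay_mean: float = 2.8
    sister_delay_sd: float = 1.9
    # clone size at t_start (founders divide 0-2 times before the window);
    # default gives mean 2.0 +/- 0.5 cells with two-cell clones dominant
    t0_size_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.10, 2: 0.77, 3: 0.13}
    )
    t_start: float = 32.0
    t_end: float = 45.0
    frame_interval: float = 1.0
    half_frame_jitter: bool = False  # place divisions on half-frame grid
    vz_fraction: float = 0.5
    dv_extent_um: float = 60.0
    channel_noise_sd: float = 0.02
    min_total_intensity: float = 0.2  # below this a cell is unclassifiable
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_founders < 0:
            raise InvalidConfigError("n_founders must be >= 0")
        if not self.copy_number_distribution or \
                sum(self.copy_number_distribution.values()) <= 0:
            raise InvalidConfigError("copy-number distribution has zero weight")
        if any(k < 1 for k in self.copy_number_distribution):
            raise InvalidConfigError("copy counts must be >= 1")
        for p in (*self.recombination_probs, self.red_manipulated_fraction,
                  self.division_prob_per_frame, *self.mode_probs,
                  *self.t0_size_probs.values(), self.vz_fraction):
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"probability {p} outside [0, 1]")
        if not math.isclose(sum(self.mode_probs), 1.0, abs_tol=1e-9):
            raise InvalidConfigError("mode_probs must sum to 1")
        if set(self.t0_size_probs) - {1, 2, 3}:
            raise InvalidConfigError("t0 clone sizes must be 1, 2 or 3")
        if not math.isclose(sum(self.t0_size_probs.values()), 1.0, abs_tol=1e-9):
            raise InvalidConfigError("t0_size_probs must sum to 1")
        if abs(sum(self.recombination_probs) - 1.0) > 1e-9:
            raise InvalidConfigError("recombination_probs must sum to 1")
        if self.manipulated_mode_probs is not None and \
                not math.isclose(sum(self.manipulated_mode_probs), 1.0, abs_tol=1e-9):
            raise InvalidConfigError("manipulated_mode_probs must sum to 1")
        if self.t_end <= self.t_start:
            raise InvalidConfigError("t_end must exceed t_start")
        if self.frame_interval <= 0:
            raise InvalidConfigError("frame_interval must be > 0")
        if self.sister_delay_sd < 0 or self.sister_delay_mean < 0:
            raise InvalidConfigError("sister delay parameters must be >= 0")
        if self.channel_noise_sd < 0:
            raise InvalidConfigError("channel_noise_sd must be >= 0")

    @property
    def frames(self) -> list[float]:
        n = int(round((self.t_end - self.t_start) / self.frame_interval))
        return [self.t_start + i * self.frame_interval for i in range(n + 1)]

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class PipelineConfig:
    """Analysis-side constants.

    ``d_contact`` operationalizes "close contact" (~ one nuclear diameter);
    ``dv_tol`` is the tolerance for "same dorsoventral level";
    ``fate_exclusion_h`` drops division-mode calls for daughters tracked
    less than that many hours after division.  Axis roles (which coordinate
    is mediolateral vs dorsoventral) are declared here because they differ
    between dorsal and transverse views.
    """

    thresholds: ColorThresholds = field(default_factory=ColorThresholds)
    d_contact: float = 12.0
    dv_tol: float = 6.0
    isolation_factor: float = 2.0  # isolation radius = factor * d_contact
    vz_fraction: float = 0.5
    dv_extent_um: float = 60.0
    frame_interval: float = 1.0
    fate_exclusion_h: float = 3.0
    endpoint_convention: str = "literal"  # or "founder_discount"
    nn_rule: str = "paired"  # or "all_even"
    min_total_intensity: float = 0.2
    ml_axis: str = "y_um"
    dv_axis: str = "z_um"
    ap_axis: str = "x_um"
    seed: int = 0

    def validate(self) -> None:
        if self.d_contact <= 0 or self.dv_tol < 0:
            raise InvalidConfigError("contact distances must be positive")
        if not 0 < self.vz_fraction < 1:
            raise InvalidConfigError("vz_fraction must be in (0, 1)")
        if self.endpoint_convention not in ("literal", "founder_discount"):
            raise InvalidConfigError("unknown endpoint convention")
        if self.nn_rule not in ("paired", "all_even"):
            raise InvalidConfigError("unknown NN rule")
        if self.fate_exclusion_h < 0:
            raise InvalidConfigError("fate_exclusion_h must be >= 0")

    @property
    def vz_boundary_um(self) -> float:
        """Dorsoventral position of the VZ/MZ line (apical side is 0)."""
        return self.vz_fraction * self.dv_extent_um

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in data and isinstance(data["thresholds"], dict):
            data = dict(data)
            data["thresholds"] = ColorThresholds(**data["thresholds"])
        cfg = cls(**data)
        cfg.validate()
        return cfg
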