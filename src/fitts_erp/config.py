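"""Generator configuration: every tunable of the synthetic study.

Defaults encode the study conditions the pipeline is meant to recover:
movement times follow MT = 211 + 68*ID ms, the cue-locked posterior
N2/P3b window mean follows -2.3 + 1.6*ID uV, and the post-go lateralized
HEOG follows -133 - 3.8*A uV (A in cm).  Noise magnitudes are chosen as
plausible for averaged scalp ERP work; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

__all__ = ["GeneratorConfig", "ConfigError", "DEFAULT_PROPAGATION", "EEG_CHANNELS", "EOG_CHANNELS"]


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration values."""


#: 10-20 montage subset carrying every analysed site, plus bipolar EOG.
EEG_CHANNELS: tuple[str, ...] = (
    "Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz",
    "C1", "C2", "C3", "C4", "P1", "P2", "PO3", "PO4",
)
EOG_CHANNELS: tuple[str, ...] = ("VEOG", "HEOG")

#: EOG -> EEG propagation (VEOG coefficient, HEOG coefficient).  The
#: vertical coefficients fall off front-to-back; the horizontal ones are
#: antisymmetric about the midline.  They exist to exercise regression
#: based ocular correction, not to model a head.
DEFAULT_PROPAGATION: dict[str, tuple[float, float]] = {
    "Fz": (0.30, 0.0),
    "FCz": (0.25, 0.0),
    "Cz": (0.20, 0.0),
    "CPz": (0.15, 0.0),
    "Pz": (0.10, 0.0),
    "POz": (0.07, 0.0),
    "Oz": (0.05, 0.0),
    "C1": (0.18, 0.05),
    "C2": (0.18, -0.05),
    "C3": (0.15, 0.10),
    "C4": (0.15, -0.10),
    "P1": (0.09, 0.03),
    "P2": (0.09, -0.03),
    "PO3": (0.06, 0.04),
    "PO4": (0.06, -0.04),
}


@dataclass
class GeneratorConfig:
    # study size
    n_subjects: int = 17
    n_blocks: int = 12
    seed: int = 0
    fs_hz: float = 500.0

    # behaviour: Fitts coefficients and noise (ms)
    mt_intercept_ms: float = 211.0
    mt_slope_ms_per_id: float = 68.0
    mt_noise_sd_ms: float = 40.0
    mt_subject_sd_ms: float = 15.0
    rt_mean_ms: float = 355.0
    rt_sd_ms: float = 60.0
    rt_subject_sd_ms: float = 20.0
    # right-hand RT advantage (ms): per-subject offset ~ N(mean, sd)
    rt_hand_offset_ms: float = 15.0
    rt_hand_offset_sd_ms: float = 20.0

    # ERP condition-mean laws (uV)
    erp_intercept_uv: float = -2.3
    erp_slope_uv_per_id: float = 1.6
    erp_subject_sd_uv: float = 0.8
    heog_intercept_uv: float = -133.0
    heog_slope_uv_per_cm: float = -3.8
    heog_subject_sd_uv: float = 8.0
    cnv_amp_uv: float = -5.0
    cnv_subject_sd_uv: float = 1.0
    lrp_amp_uv: float = -2.0
    lrp_subject_sd_uv: float = 0.5

    # per-subject-per-condition measurement noise of the window-mean
    # measures, used by the measure-level simulator (uV)
    measure_noise_sd_uv: dict = field(
        default_factory=lambda: {
            "n2p3b": 0.5, "motor_cnv": 0.8, "lrp": 0.4, "lheog": 4.0,
        }
    )

    # artifacts and noise
    blink_rate_hz: float = 0.15
    blink_amp_uv: float = 200.0
    propagation: dict = field(default_factory=lambda: dict(DEFAULT_PROPAGATION))
    white_sd_uv: float = 4.0
    pink_sd_uv: float = 4.0
    pink_exponent: float = 1.0
    eog_noise_sd_uv: float = 6.0

    # per-(width, rank) miss probabilities; near/middle/far = ascending ID
    error_rates: dict = field(
        default_factory=lambda: {
            "4": {"near": 0.001, "middle": 0.003, "far": 0.003},
            "2": {"near": 0.003, "middle": 0.005, "far": 0.008},
            "1": {"near": 0.007, "middle": 0.020, "far": 0.018},
        }
    )
    # per-rank wrong-target probabilities (arrow size == distance rank)
    wrong_target_rates: dict = field(
        default_factory=lambda: {"near": 0.001, "middle": 0.002, "far": 0.002}
    )

    # preprocessing defaults used by the pipeline
    hp_hz: float = 0.05
    lp_hz: float = 60.0
    reject_uv: float = 100.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_blocks < 1:
            raise ConfigError("n_subjects and n_blocks must be >= 1")
        for name in (
            "mt_noise_sd_ms", "mt_subject_sd_ms", "rt_sd_ms",
            "rt_subject_sd_ms", "rt_hand_offset_sd_ms", "erp_subject_sd_uv",
            "heog_subject_sd_uv", "cnv_subject_sd_uv", "lrp_subject_sd_uv",
            "blink_rate_hz", "white_sd_uv", "pink_sd_uv", "eog_noise_sd_uv",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.fs_hz <= 2 * self.lp_hz:
            raise ConfigError(
                f"fs_hz={self.fs_hz} must exceed twice the low-pass "
                f"cutoff ({self.lp_hz} Hz)"
            )
        if not 0 <= self.seed < 2**31:
            raise ConfigError("seed must lie in [0, 2**31)")
        for table in (self.error_rates,):
            for ranks in table.values():
                for r in ranks.values():
                    if not 0 <= r <= 1:
                        raise ConfigError("error rates must lie in [0, 1]")

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def digest(self) -> str:
        """Stable hash of the configuration, for report provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)
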