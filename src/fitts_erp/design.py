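"""Factorial design of the pre-cued tapping experiment.

The task is a Fitts-style rapid aiming task: on each trial a visual cue
(one of six directional arrows, or a no-go symbol) announces a unimanual
tapping movement to a target of width ``W`` at centre-to-centre distance
(amplitude) ``A``; a go signal follows after a fixed foreperiod.  The
difficulty of the movement is summarised by the index of difficulty

    ID = log2(2 A / W)   [bits]

Target width is held constant within a block, and the three per-block
amplitudes are chosen so the same three ID levels recur at every width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

__all__ = [
    "TrialTiming",
    "ExperimentDesign",
    "DesignError",
    "build_design",
    "amplitude_for",
    "RANKS",
    "HANDS",
    "NOGO",
    "cue_label",
    "condition_label",
    "parse_cue_label",
]

RANKS = ("near", "middle", "far")
HANDS = ("left", "right")
NOGO = "nogo"


class DesignError(ValueError):
    """Raised for physically impossible design parameters."""


@dataclass(frozen=True)
class TrialTiming:
    """Within-trial timing constants, all in milliseconds.

    ``foreperiod_ms`` is cue onset to go onset.  ``trial_period_ms`` is
    the full trial-onset asynchrony; with the default 4 s period a
    4 min 12 s block holds exactly 63 trials.
    """

    fixation_ms: float = 500.0
    cue_ms: float = 150.0
    foreperiod_ms: float = 1000.0
    go_ms: float = 150.0
    trial_period_ms: float = 4000.0
    block_duration_ms: float = 252_000.0

    @property
    def cue_onset_ms(self) -> float:
        return self.fixation_ms

    @property
    def go_onset_ms(self) -> float:
        return self.fixation_ms + self.foreperiod_ms

    @property
    def trials_per_block(self) -> int:
        n = self.block_duration_ms / self.trial_period_ms
        if abs(n - round(n)) > 1e-9:
            raise DesignError(
                f"block duration {self.block_duration_ms} ms is not a "
                f"multiple of the trial period {self.trial_period_ms} ms"
            )
        return int(round(n))


def amplitude_for(width_cm: float, id_bits: float) -> float:
    """Invert ID = log2(2A/W):  A = W * 2**ID / 2."""
    if width_cm <= 0:
        raise DesignError(f"width must be positive, got {width_cm}")
    if id_bits < 0:
        raise DesignError(f"ID must be non-negative, got {id_bits}")
    return width_cm * 2.0**id_bits / 2.0


@dataclass(frozen=True)
class ExperimentDesign:
    """Full trial plan: widths x ID levels x hands, plus no-go cues.

    ``amplitudes_cm[w]`` lists the per-width amplitudes in the order of
    ``id_levels`` (ascending ID == near, middle, far target).
    """

    widths_cm: tuple[float, ...] = (1.0, 2.0, 4.0)
    id_levels: tuple[float, ...] = (2.0, 3.0, 4.0)
    n_blocks: int = 12
    timing: TrialTiming = field(default_factory=TrialTiming)

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.widths_cm):
            raise DesignError("all widths must be positive")
        if any(i <= 0 for i in self.id_levels):
            raise DesignError("all ID levels must be positive")
        if list(self.id_levels) != sorted(self.id_levels):
            raise DesignError("id_levels must be ascending (near..far)")
        if self.n_blocks < 1:
            raise DesignError("need at least one block")
        self.timing.trials_per_block  # validates divisibility

    @property
    def amplitudes_cm(self) -> dict[float, tuple[float, ...]]:
        return {
            w: tuple(amplitude_for(w, i) for i in self.id_levels)
            for w in self.widths_cm
        }

    @property
    def cue_types(self) -> tuple[str, ...]:
        """Six directional cues (hand x distance rank) plus no-go."""
        return tuple(f"{h}_{r}" for h in HANDS for r in RANKS) + (NOGO,)

    @property
    def trials_per_block(self) -> int:
        return self.timing.trials_per_block

    @property
    def reps_per_cue(self) -> int:
        n_cues = len(self.cue_types)
        if self.trials_per_block % n_cues:
            raise DesignError(
                f"{self.trials_per_block} trials per block cannot be "
                f"balanced over {n_cues} cue types"
            )
        return self.trials_per_block // n_cues

    def id_for_rank(self, rank: str) -> float:
        return self.id_levels[RANKS.index(rank)]

    def amplitude(self, width_cm: float, rank: str) -> float:
        return amplitude_for(width_cm, self.id_for_rank(rank))

    def block_widths(self, subject_index: int = 0) -> list[float]:
        """Per-block target widths for one subject.

        Widths cycle across blocks with a per-subject rotation so that a
        reduced study (fewer blocks than widths) still covers every
        design cell at the group level.  With n_blocks a multiple of the
        number of widths this reduces to a balanced assignment.
        """
        k = len(self.widths_cm)
        off = subject_index % k
        return [self.widths_cm[(b + off) % k] for b in range(self.n_blocks)]

    def cells(self) -> list[tuple[float, float, float]]:
        """All (width, amplitude, id) cells, hands pooled."""
        return [
            (w, amplitude_for(w, i), i)
            for w in self.widths_cm
            for i in self.id_levels
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["amplitudes_cm"] = {str(k): list(v) for k, v in self.amplitudes_cm.items()}
        d["cue_types"] = list(self.cue_types)
        d["trials_per_block"] = self.trials_per_block
        return d


def build_design(
    widths: tuple[float, ...] = (1.0, 2.0, 4.0),
    id_levels: tuple[float, ...] = (2.0, 3.0, 4.0),
    timing: TrialTiming | None = None,
    n_blocks: int = 12,
) -> ExperimentDesign:
    """Build the factorial plan, deriving amplitudes from widths and IDs."""
    return ExperimentDesign(
        widths_cm=tuple(float(w) for w in widths),
        id_levels=tuple(float(i) for i in id_levels),
        n_blocks=n_blocks,
        timing=timing or TrialTiming(),
    )


def _fmt(x: float) -> str:
    return f"{x:g}"


def cue_label(width_cm: float, id_bits: float, hand: str) -> str:
    return f"cue_W{_fmt(width_cm)}_ID{_fmt(id_bits)}_{hand}"


def condition_label(width_cm: float, id_bits: float, hand: str | None = None) -> str:
    base = f"W{_fmt(width_cm)}_ID{_fmt(id_bits)}"
    return base if hand is None else f"{base}_{hand}"


def parse_cue_label(label: str) -> dict:
    """Parse ``cue_W{w}_ID{i}_{hand}`` or ``nogo`` into its fields."""
    if label == NOGO:
        return {"is_nogo": True, "width_cm": None, "id_bits": None, "hand": None}
    parts = label.split("_")
    if len(parts) != 4 or parts[0] != "cue":
        raise ValueError(f"unrecognised cue label {label!r}")
    width = float(parts[1][1:])
    id_bits = float(parts[2][2:])
    hand = parts[3]
    if hand not in HANDS:
        raise ValueError(f"unknown hand {hand!r} in {label!r}")
    expected = math.log2(2 * amplitude_for(width, id_bits) / width)
    assert abs(expected - id_bits) < 1e-9
    return {"is_nogo": False, "width_cm": width, "id_bits": id_bits, "hand": hand}
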