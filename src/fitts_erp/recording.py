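"""In-memory container for a continuous multichannel recording."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ContinuousRecording", "EVENT_VOCABULARY", "validate_events"]

#: fixed marker labels; cue markers additionally follow cue_W*_ID*_{hand}
EVENT_VOCABULARY = ("nogo", "go", "lift", "tap")


def _is_known_label(label: str) -> bool:
    return label in EVENT_VOCABULARY or label.startswith("cue_")


def validate_events(events: pd.DataFrame, n_samples: int | None = None) -> pd.DataFrame:
    """Check and normalise an event table (sample_index, label)."""
    required = {"sample_index", "label"}
    if not required.issubset(events.columns):
        raise ValueError(f"event table must have columns {sorted(required)}")
    if len(events) == 0:
        raise ValueError("no events")
    ev = events[["sample_index", "label"]].copy()
    ev["sample_index"] = ev["sample_index"].astype(np.int64)
    if (ev["sample_index"] < 0).any():
        raise ValueError("negative sample_index in event table")
    bad = [l for l in ev["label"].unique() if not _is_known_label(l)]
    if bad:
        raise ValueError(f"labels outside vocabulary: {bad}")
    if n_samples is not None and (ev["sample_index"] >= n_samples).any():
        raise ValueError("event beyond recording end")
    if not ev["sample_index"].is_monotonic_increasing:
        ev = ev.sort_values("sample_index", kind="stable").reset_index(drop=True)
    return ev.reset_index(drop=True)


@dataclass
class ContinuousRecording:
    """Channels x samples time series in microvolts with event markers."""

    fs_hz: float
    channel_labels: list[str]
    data: np.ndarray  # (n_channels, n_samples), uV
    events: pd.DataFrame = field(default_factory=pd.DataFrame)
    subject_id: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel label count does not match data rows")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if len(self.events):
            self.events = validate_events(self.events, self.n_samples)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def eog_labels(self) -> list[str]:
        return [c for c in self.channel_labels if c.upper().endswith("EOG")]

    @property
    def eeg_labels(self) -> list[str]:
        return [c for c in self.channel_labels if c not in self.eog_labels]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def get(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def copy(self) -> "ContinuousRecording":
        return ContinuousRecording(
            fs_hz=self.fs_hz,
            channel_labels=list(self.channel_labels),
            data=self.data.copy(),
            events=self.events.copy(),
            subject_id=self.subject_id,
        )
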