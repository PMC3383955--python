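"""File formats: EDF for continuous data, TSV for events and behaviour.

EDF (European Data Format) stores 16-bit integers against a per-channel
physical range, so write -> read is identity only up to that
quantisation (symmetric integer physical bounds against digital range
-32767..32767 make the mapping exactly proportional).  Writing is done
directly (fixed-layout ASCII header + little-endian int16 records);
reading goes through MNE's independent EDF reader.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd


from .recording import ContinuousRecording, validate_events

__all__ = [
    "write_edf", "read_edf", "write_events", "read_events",
    "read_recording", "write_recording",
    "write_behaviour", "read_behaviour",
    "write_epochs", "read_epochs",
]

log = logging.getLogger("fitts_erp")

BEHAVIOUR_COLUMNS = [
    "subject_id", "block", "trial", "cue_type", "hand", "width_cm",
    "amplitude_cm", "id_bits", "rt_ms", "mt_ms", "miss", "wrong_target",
    "is_nogo",
]

_DIG_MAX = 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(recording: ContinuousRecording, path) -> None:
    """Write a recording as EDF, one 1-second data record per second.

    The trailing partial second, if any, is zero-padded.  Header date
    fields are fixed so identical data give byte-identical files.
    """
    fs = recording.fs_hz
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9 or spr <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch, n_samp = recording.data.shape
    n_rec = math.ceil(n_samp / spr)
    if n_rec * spr != n_samp:
        log.warning("zero-padding %d samples to fill the last EDF record",
                    n_rec * spr - n_samp)

    phys_max = np.maximum(
        1.0, np.ceil(np.max(np.abs(recording.data), axis=1, initial=0.0))
    )
    digital = np.round(recording.data / phys_max[:, None] * _DIG_MAX)
    digital = np.clip(digital, -_DIG_MAX, _DIG_MAX).astype("<i2")
    padded = np.zeros((n_ch, n_rec * spr), dtype="<i2")
    padded[:, :n_samp] = digital

    header = b"".join([
        _pad("0", 8),
        _pad(f"subject {recording.subject_id}" if recording.subject_id is not None
             else "X", 80),
        _pad("synthetic pre-cued tapping study", 80),
        _pad("01.01.01", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (n_ch + 1)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(n_ch), 4),
    ])
    fields = [
        (16, list(recording.channel_labels)),
        (80, [""] * n_ch),
        (8, ["uV"] * n_ch),
        (8, [f"{-int(m)}" for m in phys_max]),
        (8, [f"{int(m)}" for m in phys_max]),
        (8, [str(-_DIG_MAX)] * n_ch),
        (8, [str(_DIG_MAX)] * n_ch),
        (80, [""] * n_ch),
        (8, [str(spr)] * n_ch),
        (32, [""] * n_ch),
    ]
    sig_header = b"".join(
        b"".join(_pad(v, w) for v in values) for w, values in fields
    )
    # records: for each second, all channels' samples back to back
    body = padded.reshape(n_ch, n_rec, spr).transpose(1, 0, 2).tobytes()
    Path(path).write_bytes(header + sig_header + body)


def read_edf(path) -> tuple[float, list[str], np.ndarray]:
    """Read an EDF file via MNE; returns (fs_hz, labels, data_uV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads Volts for uV-dimensioned EDF
    return float(raw.info["sfreq"]), list(raw.ch_names), data


def write_events(events: pd.DataFrame, path) -> None:
    ev = validate_events(events)
    ev.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_events(path, n_samples: int | None = None) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    if len(ev) == 0:
        raise ValueError("no events")
    if not ev["sample_index"].is_monotonic_increasing:
        log.warning("event table %s was unsorted; sorting by sample_index", path)
    return validate_events(ev, n_samples)


KNOWN_CHANNELS = set(
    "Fz FCz Cz CPz Pz POz Oz C1 C2 C3 C4 C5 C6 P1 P2 P3 P4 PO3 PO4 PO7 PO8 "
    "F1 F2 F3 F4 Fp1 Fp2 O1 O2 VEOG HEOG".split()
)


def read_recording(edf_path, events_path) -> ContinuousRecording:
    """Load continuous data plus its event table, with validation."""
    fs, labels, data = read_edf(edf_path)
    for ch in labels:
        if ch not in KNOWN_CHANNELS:
            log.warning("unknown channel label %r passed through", ch)
    events = read_events(events_path, n_samples=data.shape[1])
    return ContinuousRecording(fs_hz=fs, channel_labels=labels, data=data,
                               events=events)


def write_recording(recording: ContinuousRecording, edf_path, events_path) -> None:
    write_edf(recording, edf_path)
    write_events(recording.events, events_path)


# ---------------------------------------------------------------------------
# behaviour tables

def write_behaviour(trials, path) -> None:
    """Write one row per trial; rt/mt are empty for no-go trials."""
    from .simulate import trials_to_frame

    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    df = df[BEHAVIOUR_COLUMNS]
    df.to_csv(path, sep="\t", index=False, lineterminator="\n",
              float_format="%.6g")


def read_behaviour(path) -> pd.DataFrame:
    """Read a behaviour TSV, re-deriving ID from A and W as a check."""
    df = pd.read_csv(path, sep="\t")
    missing = set(BEHAVIOUR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"behaviour table missing columns {sorted(missing)}")
    action = ~df["is_nogo"].astype(bool)
    recomputed = np.log2(
        2.0 * df.loc[action, "amplitude_cm"] / df.loc[action, "width_cm"]
    )
    bad = np.abs(recomputed - df.loc[action, "id_bits"]) > 1e-9
    if bad.any():
        idx = df.loc[action].index[bad][0]
        raise ValueError(
            f"integrity error: row {idx} stores id_bits="
            f"{df.loc[idx, 'id_bits']} but log2(2A/W)="
            f"{float(recomputed.loc[idx]):g}"
        )
    if df.loc[~action, ["rt_ms", "mt_ms"]].notna().any().any():
        raise ValueError("no-go rows must have empty rt_ms/mt_ms")
    return df


# ---------------------------------------------------------------------------
# epoch container (flat npz; see preprocess.EpochSet)

def write_epochs(epochs, path) -> None:
    import json

    meta = {
        "fs_hz": epochs.fs_hz,
        "channel_labels": epochs.channel_labels,
        "conditions": epochs.conditions,
        "lock_event": epochs.lock_event,
        "window_ms": list(epochs.window_ms),
        "baseline_ms": list(epochs.baseline_ms) if epochs.baseline_ms else None,
        "reject_reason": epochs.reject_reason,
    }
    np.savez_compressed(path, data=epochs.data, rejected=epochs.rejected,
                        meta=json.dumps(meta))


def read_epochs(path):
    import json

    from .preprocess import EpochSet

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        return EpochSet(
            data=z["data"], fs_hz=meta["fs_hz"],
            channel_labels=meta["channel_labels"],
            conditions=meta["conditions"], lock_event=meta["lock_event"],
            window_ms=tuple(meta["window_ms"]),
            baseline_ms=tuple(meta["baseline_ms"]) if meta["baseline_ms"] else None,
            rejected=z["rejected"],
            reject_reason=meta["reject_reason"],
        )
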