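"""Trial-level behavioural reduction and the Fitts regressions.

Reaction time is go-signal onset to stylus lift; movement time is lift
to target tap.  Trials with RT or MT below an absolute floor (100 ms)
or more than 2 SD from their condition mean are trimmed, a single pass
with the mean/SD computed on the floor-surviving trials.  Condition-mean
movement times, pooled over hands, are regressed on the index of
difficulty ID = log2(2A/W) and, for comparison, on movement amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import parse_cue_label
from .stats import RegressionResult, TTestResult, ols, paired_ttest

__all__ = [
    "TrimRule", "compute_id", "extract_rt_mt", "trim",
    "cell_summaries", "fitts_regression", "hand_ttest", "error_table",
]


@dataclass(frozen=True)
class TrimRule:
    floor_ms: float = 100.0
    sd_mult: float = 2.0

    def __post_init__(self) -> None:
        if self.floor_ms < 0:
            raise ValueError("floor_ms must be >= 0")
        if self.sd_mult <= 0:
            raise ValueError("sd_mult must be > 0")


def compute_id(amplitude_cm, width_cm):
    """Index of difficulty log2(2A/W) in bits; scalar or elementwise."""
    a = np.asarray(amplitude_cm, dtype=np.float64)
    w = np.asarray(width_cm, dtype=np.float64)
    if np.any(a <= 0) or np.any(w <= 0):
        raise ValueError("amplitude and width must be positive")
    out = np.log2(2.0 * a / w)
    return float(out) if out.ndim == 0 else out


def extract_rt_mt(events: pd.DataFrame, fs_hz: float) -> pd.DataFrame:
    """Per-trial RT/MT from (cue, go, lift, tap) marker sequences.

    A trial is every cue-type marker and the go/lift/tap markers that
    follow it before the next cue.  Trials with missing or disordered
    markers are flagged invalid and excluded from the times.
    """
    rows = []
    current = None
    for sample, label in zip(events["sample_index"], events["label"]):
        if label == "nogo" or label.startswith("cue_"):
            if current is not None:
                rows.append(current)
            current = {"cue_label": label, "cue": int(sample),
                       "go": None, "lift": None, "tap": None}
        elif current is not None and label in ("go", "lift", "tap"):
            if current[label] is None:
                current[label] = int(sample)
    if current is not None:
        rows.append(current)

    out = []
    for k, r in enumerate(rows):
        f = parse_cue_label(r["cue_label"])
        rec = {
            "trial_index": k, "cue_label": r["cue_label"],
            "is_nogo": f["is_nogo"], "hand": f["hand"],
            "width_cm": f["width_cm"], "id_bits": f["id_bits"],
            "amplitude_cm": (
                None if f["is_nogo"]
                else f["width_cm"] * 2.0 ** f["id_bits"] / 2.0
            ),
            "rt_ms": None, "mt_ms": None, "valid": True, "invalid_reason": None,
        }
        if f["is_nogo"]:
            out.append(rec)
            continue
        go, lift, tap = r["go"], r["lift"], r["tap"]
        if go is None or lift is None or tap is None:
            rec["valid"] = False
            rec["invalid_reason"] = "missing marker"
        elif not (r["cue"] < go < lift < tap):
            rec["valid"] = False
            rec["invalid_reason"] = "disordered markers"
        else:
            rec["rt_ms"] = (lift - go) * 1000.0 / fs_hz
            rec["mt_ms"] = (tap - lift) * 1000.0 / fs_hz
        out.append(rec)
    return pd.DataFrame(out)


_CELL_KEYS = ["subject_id", "hand", "width_cm", "id_bits"]


def trim(trials: pd.DataFrame, rule: TrimRule = TrimRule()
         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(kept, removed) after the floor and the single-pass 2-SD rule.

    Conditions are subject x hand x width x ID cells.  The SD rule uses
    the mean/SD of the floor-surviving trials of the condition and
    removes trials deviating strictly more than ``sd_mult`` SDs in RT or
    MT.
    """
    df = trials[~trials["is_nogo"].astype(bool)].copy()
    below = (df["rt_ms"] < rule.floor_ms) | (df["mt_ms"] < rule.floor_ms)
    floor_removed = df[below]
    df = df[~below]

    removed_idx = []
    for _, g in df.groupby(_CELL_KEYS, sort=False):
        for col in ("rt_ms", "mt_ms"):
            mu = g[col].mean()
            sd = g[col].std(ddof=1)
            if not np.isfinite(sd):
                continue
            removed_idx.extend(g.index[(g[col] - mu).abs() > rule.sd_mult * sd])
    removed_idx = sorted(set(removed_idx))
    removed = pd.concat([floor_removed, df.loc[removed_idx]])
    kept = df.drop(index=removed_idx)
    return kept, removed


def cell_summaries(trials: pd.DataFrame,
                   pool_hands: bool = True) -> pd.DataFrame:
    """Per-cell means/SDs of RT and MT over subjects.

    First averages within subject x cell, then over subjects, so every
    subject counts equally; hands are pooled by default.
    """
    df = trials[~trials["is_nogo"].astype(bool)]
    keys = ["width_cm", "id_bits"] + ([] if pool_hands else ["hand"])
    per_subj = (
        df.groupby(["subject_id"] + keys, sort=True)[["rt_ms", "mt_ms"]]
        .mean().reset_index()
    )
    out = (
        per_subj.groupby(keys, sort=True)
        .agg(
            mean_rt_ms=("rt_ms", "mean"), sd_rt_ms=("rt_ms", "std"),
            mean_mt_ms=("mt_ms", "mean"), sd_mt_ms=("mt_ms", "std"),
            n_subjects=("subject_id", "nunique"),
        ).reset_index()
    )
    out["amplitude_cm"] = out["width_cm"] * 2.0 ** out["id_bits"] / 2.0
    return out


def fitts_regression(cells: pd.DataFrame,
                     predictor: str = "id") -> RegressionResult:
    """OLS of condition-mean MT on ID (bits) or amplitude (cm)."""
    col = {"id": "id_bits", "amplitude": "amplitude_cm"}.get(predictor)
    if col is None:
        raise ValueError("predictor must be 'id' or 'amplitude'")
    x = cells[col].to_numpy(dtype=float)
    if np.unique(x).size < 3:
        raise ValueError(f"need >=3 distinct {predictor} values")
    return ols(x, cells["mean_mt_ms"].to_numpy(dtype=float))


def hand_ttest(per_subject_left, per_subject_right) -> TTestResult:
    """Paired two-tailed t-test of per-subject means, left vs right."""
    return paired_ttest(per_subject_left, per_subject_right)


def error_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Miss and wrong-target rates per width x target-distance cell."""
    df = trials[~trials["is_nogo"].astype(bool)].copy()
    rows = []
    for (w, i), g in df.groupby(["width_cm", "id_bits"], sort=True):
        rows.append({
            "width_cm": w, "id_bits": i,
            "amplitude_cm": w * 2.0 ** i / 2.0,
            "n_trials": len(g),
            "miss_rate": float(g["miss"].mean()),
            "wrong_target_rate": float(g["wrong_target"].mean()),
        })
    return pd.DataFrame(rows)
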