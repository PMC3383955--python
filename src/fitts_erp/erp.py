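"""Derived ERP quantities: posterior N2/P3b, motor CNV, LRP, LHEOG.

All four are window means of condition-average waveforms:

* posterior N2/P3b — cue-locked mean over Pz, P1, P2, POz, PO3, PO4 in
  310-370 ms after cue onset;
* motor CNV — (action minus no-go) mean over Cz, FCz, CPz, C1, C2 in
  the last 200 ms before go onset;
* LRP — the double subtraction 0.5*[(L-R)_right-hand + (R-L)_left-hand]
  over the pairs C1/C2 and C3/C4, response-locked, last 200 ms before
  stylus lift (negative = hand-specific motor activation);
* lateralized HEOG — bipolar HEOG sign-aligned across target sides so
  that gaze toward the target is negative, 250-450 ms after go onset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import Evoked
from .stats import RegressionResult, ols

__all__ = [
    "RoiSpec", "N2P3B_ROI", "CNV_ELECTRODES", "LRP_PAIRS",
    "roi_window_mean", "motor_cnv", "lrp", "lateralized_heog",
    "erp_regressions",
]

log = logging.getLogger("fitts_erp")


@dataclass(frozen=True)
class RoiSpec:
    name: str
    electrode_labels: tuple[str, ...]
    window_ms: tuple[float, float]
    lock_event: str


#: parieto-occipital ROI of the cue-locked N2/P3b complex
N2P3B_ROI = RoiSpec(
    name="n2p3b",
    electrode_labels=("Pz", "P1", "P2", "POz", "PO3", "PO4"),
    window_ms=(310.0, 370.0),
    lock_event="cue",
)
#: fronto-central electrodes of the motor CNV
CNV_ELECTRODES = ("Cz", "FCz", "CPz", "C1", "C2")
#: (left-hemisphere, right-hemisphere) electrode pairs for the LRP
LRP_PAIRS = (("C1", "C2"), ("C3", "C4"))


def _pooled_window_mean(evoked: Evoked, electrodes, window_ms) -> float:
    idx = [evoked.channel_index(ch) for ch in electrodes]
    sl = evoked.window_slice(tuple(window_ms))
    return float(evoked.data[idx, sl].mean())


def roi_window_mean(evoked: Evoked, roi: RoiSpec) -> float:
    """Mean over the ROI electrodes, then over the window samples (uV)."""
    return _pooled_window_mean(evoked, roi.electrode_labels, roi.window_ms)


def motor_cnv(
    action_evoked: Evoked,
    nogo_evoked: Evoked,
    electrodes=CNV_ELECTRODES,
    window_ms: tuple[float, float] = (800.0, 1000.0),
) -> float:
    """Action-minus-no-go pooled mean in the pre-go window (uV).

    The default window is the last 200 ms before go onset expressed in
    cue-locked epoch time (go onset 1000 ms after the cue).
    """
    if nogo_evoked is None:
        raise ValueError("no-go condition average is required")
    a = _pooled_window_mean(action_evoked, electrodes, window_ms)
    n = _pooled_window_mean(nogo_evoked, electrodes, window_ms)
    return a - n


def lrp(
    left_hand_evoked: Evoked,
    right_hand_evoked: Evoked,
    pairs=LRP_PAIRS,
    window_ms: tuple[float, float] = (-200.0, 0.0),
) -> float:
    """Double-subtraction lateralized readiness potential (uV).

    For each (left-hemisphere, right-hemisphere) pair:
    0.5 * [(L - R) for right-hand + (R - L) for left-hand], pooled over
    pairs and averaged over the response-locked window.
    """
    if left_hand_evoked is None or right_hand_evoked is None:
        raise ValueError("both hands' response-locked averages are required")
    vals = []
    for lch, rch in pairs:
        r = (_pooled_window_mean(right_hand_evoked, (lch,), window_ms)
             - _pooled_window_mean(right_hand_evoked, (rch,), window_ms))
        l = (_pooled_window_mean(left_hand_evoked, (rch,), window_ms)
             - _pooled_window_mean(left_hand_evoked, (lch,), window_ms))
        vals.append(0.5 * (r + l))
    return float(np.mean(vals))


def lateralized_heog(
    left_target_evoked: Evoked | None,
    right_target_evoked: Evoked | None,
    channel: str = "HEOG",
    window_ms: tuple[float, float] = (250.0, 450.0),
) -> float:
    """Sign-aligned bipolar HEOG window mean (uV), negative toward target.

    With HEOG recorded left-minus-right eye, rightward gaze is negative;
    left-target trials are sign-flipped before averaging the two sides.
    If only one side is available the estimate uses it alone (warned).
    """
    vals = []
    if right_target_evoked is not None:
        vals.append(_pooled_window_mean(right_target_evoked, (channel,),
                                        window_ms))
    if left_target_evoked is not None:
        vals.append(-_pooled_window_mean(left_target_evoked, (channel,),
                                         window_ms))
    if not vals:
        raise ValueError("need at least one target side")
    if len(vals) == 1:
        log.warning("lateralized HEOG computed from a single target side")
    return float(np.mean(vals))


def erp_regressions(
    measures: pd.DataFrame,
    measure: str,
    predictor: str = "id",
) -> RegressionResult:
    """OLS of grand-average condition measures on ID or amplitude.

    ``measures`` holds one row per subject x condition x measure with
    columns measure, value_uv, id_bits, amplitude_cm (hands pooled).
    Values are first averaged over subjects within each condition.
    """
    col = {"id": "id_bits", "amplitude": "amplitude_cm"}.get(predictor)
    if col is None:
        raise ValueError("predictor must be 'id' or 'amplitude'")
    df = measures[measures["measure"] == measure]
    if df.empty:
        raise ValueError(f"no rows for measure {measure!r}")
    grand = df.groupby(["id_bits", "amplitude_cm"], sort=True)["value_uv"].mean()
    grand = grand.reset_index()
    x = grand[col].to_numpy(dtype=float)
    if np.unique(x).size < 3:
        raise ValueError(f"need >=3 distinct {predictor} values")
    return ols(x, grand["value_uv"].to_numpy(dtype=float))
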