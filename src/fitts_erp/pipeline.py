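"""End-to-end orchestration: simulate (or ingest), preprocess, measure.

``run_pipeline`` produces a single JSON-serialisable report holding the
behavioural cell summaries, trim and rejection counts, the error table,
the six condition-mean regressions (MT, posterior N2/P3b and lateralized
HEOG, each on ID and on movement amplitude), the CNV/LRP null checks and
provenance (config hash, seed, package version).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import __version__
from .behaviour import (
    TrimRule, cell_summaries, error_table, extract_rt_mt, fitts_regression,
    hand_ttest, trim,
)
from .config import GeneratorConfig
from .design import ExperimentDesign, NOGO, build_design, condition_label, parse_cue_label
from .erp import (
    CNV_ELECTRODES, N2P3B_ROI, lateralized_heog, lrp, motor_cnv,
    roi_window_mean, erp_regressions,
)
from .preprocess import (
    apply_ocular_model, average, bandpass, baseline_correct, epoch,
    fit_ocular_model, reject_artifacts,
)
from .recording import ContinuousRecording
from .simulate import simulate_behaviour, simulate_recording, trials_to_frame

__all__ = ["run_pipeline", "process_subject_recording", "measure_frame_columns"]

log = logging.getLogger("fitts_erp")

CUE_WINDOW_MS = (-300.0, 1500.0)
CUE_BASELINE_MS = (-200.0, 0.0)
GO_WINDOW_MS = (-200.0, 2000.0)  # long enough that the full gaze
# transient (rise ~300 ms, return ~900 ms post-go) lies inside the
# segment; high-pass filtering a segment that truncates the step
# mid-plateau attenuates the 250-450 ms window mean badly
GO_BASELINE_MS = (-200.0, 0.0)
LIFT_WINDOW_MS = (-800.0, 200.0)
LIFT_BASELINE_MS = (-800.0, -600.0)
CNV_WINDOW_MS = (800.0, 1000.0)  # cue-locked; last 200 ms before go
LRP_WINDOW_MS = (-200.0, 0.0)    # response-locked

measure_frame_columns = [
    "subject_id", "condition", "width_cm", "amplitude_cm", "id_bits",
    "measure", "value_uv",
]


def _pooled_condition_map(events) -> dict[str, str]:
    """Cue label -> condition with hands pooled (W{w}_ID{i} or nogo)."""
    out = {}
    for label in events["label"].unique():
        if label == NOGO:
            out[label] = NOGO
        elif label.startswith("cue_"):
            f = parse_cue_label(label)
            out[label] = condition_label(f["width_cm"], f["id_bits"])
    return out


def _prep(epochs, config):
    ep = bandpass(epochs, config.hp_hz, config.lp_hz)
    return reject_artifacts(ep, config.reject_uv)


def process_subject_recording(
    recording: ContinuousRecording, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """One subject: ocular correction, three epoch sets, all measures.

    Returns (behaviour frame from the event markers, measure frame,
    per-stage counts).
    """
    subject = recording.subject_id
    raw_cue = epoch(recording, "cue", CUE_WINDOW_MS)
    ocular = fit_ocular_model(raw_cue)
    corrected = apply_ocular_model(recording, ocular)

    cue_ep = _prep(
        epoch(corrected, "cue", CUE_WINDOW_MS,
              _pooled_condition_map(corrected.events)),
        config,
    )
    cue_ep = baseline_correct(cue_ep, CUE_BASELINE_MS)
    go_ep = _prep(epoch(corrected, "go", GO_WINDOW_MS), config)
    go_ep = baseline_correct(go_ep, GO_BASELINE_MS)
    lift_ep = _prep(epoch(corrected, "lift", LIFT_WINDOW_MS), config)
    lift_ep = baseline_correct(lift_ep, LIFT_BASELINE_MS)

    counts = {
        "cue_epochs": cue_ep.n_epochs,
        "cue_rejected": int(cue_ep.rejected.sum()),
        "go_rejected": int(go_ep.rejected.sum()),
        "lift_rejected": int(lift_ep.rejected.sum()),
    }

    cue_avg = average(cue_ep)
    go_avg = average(go_ep)
    lift_avg = average(lift_ep)
    nogo_avg = cue_avg.get(NOGO)

    rows = []

    def add(cond_info, measure, value):
        w, a, i = cond_info
        rows.append({
            "subject_id": subject, "condition": condition_label(w, i),
            "width_cm": w, "amplitude_cm": a, "id_bits": i,
            "measure": measure, "value_uv": value,
        })

    cells = sorted(
        {(f["width_cm"],
          f["width_cm"] * 2.0 ** f["id_bits"] / 2.0,
          f["id_bits"])
         for lab in corrected.events["label"].unique() if lab.startswith("cue_")
         for f in [parse_cue_label(lab)]}
    )
    for w, a, i in cells:
        pooled = condition_label(w, i)
        if pooled in cue_avg:
            add((w, a, i), "n2p3b", roi_window_mean(cue_avg[pooled], N2P3B_ROI))
            if nogo_avg is not None:
                add((w, a, i), "motor_cnv",
                    motor_cnv(cue_avg[pooled], nogo_avg, CNV_ELECTRODES,
                              CNV_WINDOW_MS))
        left = condition_label(w, i, "left")
        right = condition_label(w, i, "right")
        if left in lift_avg and right in lift_avg:
            add((w, a, i), "lrp",
                lrp(lift_avg[left], lift_avg[right], window_ms=LRP_WINDOW_MS))
        if left in go_avg or right in go_avg:
            add((w, a, i), "lheog",
                lateralized_heog(go_avg.get(left), go_avg.get(right)))

    beh = extract_rt_mt(corrected.events, corrected.fs_hz)
    beh.insert(0, "subject_id", subject)
    return beh, pd.DataFrame(rows, columns=measure_frame_columns), counts


def _behaviour_report(trials_df: pd.DataFrame, trim_rule: TrimRule) -> dict:
    """Trim, summarise, regress and test the behavioural table."""
    action = trials_df[~trials_df["is_nogo"].astype(bool)]
    kept, removed = trim(trials_df, trim_rule)
    correct = kept[~(kept["miss"] | kept["wrong_target"])]
    cells = cell_summaries(correct)
    mt_id = fitts_regression(cells, "id")
    mt_amp = fitts_regression(cells, "amplitude")
    def hand_test(col):
        per_hand = (
            kept.groupby(["subject_id", "hand"])[col].mean().unstack("hand")
        )
        if len(per_hand) < 2:  # paired test needs >=2 subjects
            return None
        return hand_ttest(per_hand["left"].to_numpy(),
                          per_hand["right"].to_numpy()).to_dict()

    tt = hand_test("rt_ms")
    tt_mt = hand_test("mt_ms")
    return {
        "n_action_trials": int(len(action)),
        "n_trimmed": int(len(removed)),
        "n_kept": int(len(kept)),
        "cell_summaries": cells.to_dict(orient="records"),
        "regressions": {
            "mt_on_id": mt_id.to_dict(),
            "mt_on_amplitude": mt_amp.to_dict(),
        },
        "rt_hand_ttest": tt,
        "mt_hand_ttest": tt_mt,
        "error_table": error_table(trials_df).to_dict(orient="records"),
    }


def _erp_report(measures: pd.DataFrame) -> dict:
    out = {"regressions": {}}
    specs = [
        ("n2p3b", "id"), ("n2p3b", "amplitude"),
        ("lheog", "amplitude"), ("lheog", "id"),
        ("motor_cnv", "id"), ("motor_cnv", "amplitude"),
        ("lrp", "id"), ("lrp", "amplitude"),
    ]
    for measure, predictor in specs:
        if measure not in set(measures["measure"]):
            continue
        r = erp_regressions(measures, measure, predictor)
        d = r.to_dict()
        lo, hi = r.slope_ci()
        d["slope_ci95"] = [lo, hi]
        d["slope_ci_covers_zero"] = bool(lo <= 0.0 <= hi)
        out["regressions"][f"{measure}_on_{predictor}"] = d
    return out


def run_pipeline(
    config: GeneratorConfig,
    design: ExperimentDesign | None = None,
    with_eeg: bool = True,
    trim_rule: TrimRule = TrimRule(),
) -> dict:
    """Simulate the study and run every analysis stage; return the report.

    With ``with_eeg=False`` only the behavioural arm runs (the trial
    table feeds the reductions directly); with EEG the behavioural times
    are re-derived from the recorded event markers, exercising the whole
    marker chain.
    """
    design = design or build_design(n_blocks=config.n_blocks)
    trials = simulate_behaviour(design, config)
    trials_df = trials_to_frame(trials)

    report = {
        "provenance": {
            "seed": int(config.seed),
            "config_digest": config.digest(),
            "version": __version__,
            "n_subjects": int(config.n_subjects),
            "n_blocks": int(config.n_blocks),
        },
        "design": design.to_dict(),
    }

    if with_eeg:
        beh_frames, meas_frames, stage_counts = [], [], []
        for s in range(config.n_subjects):
            subj = [t for t in trials if t.subject_id == s]
            rec = simulate_recording(design, subj, config)
            beh, meas, counts = process_subject_recording(rec, config)
            log.info("subject %d: %s", s, counts)
            # attach the flags the markers cannot carry, by trial order
            flags = (
                trials_df[trials_df["subject_id"] == s]
                .sort_values(["block", "trial"])
                .reset_index(drop=True)
            )
            if len(flags) != len(beh):
                raise RuntimeError(
                    f"subject {s}: {len(beh)} marker trials vs "
                    f"{len(flags)} planned trials"
                )
            beh = beh.assign(
                miss=flags["miss"].to_numpy(),
                wrong_target=flags["wrong_target"].to_numpy(),
                block=flags["block"].to_numpy(),
            )
            beh_frames.append(beh[beh["valid"]])
            meas_frames.append(meas)
            stage_counts.append({"subject_id": s, **counts})
        behaviour_df = pd.concat(beh_frames, ignore_index=True)
        measures = pd.concat(meas_frames, ignore_index=True)
        report["behaviour"] = _behaviour_report(behaviour_df, trim_rule)
        report["erp"] = _erp_report(measures)
        report["preprocessing"] = stage_counts
    else:
        report["behaviour"] = _behaviour_report(trials_df, trim_rule)

    return report
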