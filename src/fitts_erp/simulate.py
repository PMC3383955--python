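"""Synthetic pre-cued tapping study: behaviour, EEG/EOG, and measures.

Three levels of simulation share one set of per-subject parameters:

* :func:`simulate_behaviour` draws per-trial reaction and movement
  times.  MT follows the Fitts law MT = a + b*ID with Gaussian trial
  noise; RT is independent of ID with a right-hand advantage.
* :func:`simulate_recording` renders one subject's continuous EEG/EOG
  in microvolts: 1/f plus white noise, blink and saccade artifacts
  propagated to the scalp, and the four deterministic ERP components
  (posterior N2/P3b bump, fronto-central CNV ramp, lateralized motor
  potential, post-go horizontal EOG step).  Component *shapes* are free;
  only their analysis-window means are contract-bound to the configured
  linear laws.
* :func:`simulate_measures` draws the per-subject condition-mean window
  measures directly from the same statistical model, for studies of the
  regression stage at scale.

Randomness: one master seed spawns per-subject ``SeedSequence`` children
in subject order; each subject spawns four sub-streams in the fixed
order (parameters, behaviour, eeg, measures), so e.g. behavioural draws
never perturb the EEG noise.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .config import GeneratorConfig, ConfigError, EEG_CHANNELS, EOG_CHANNELS
from .design import (
    ExperimentDesign, RANKS, HANDS, NOGO, cue_label, condition_label,
)

__all__ = [
    "BehaviouralTrial",
    "simulate_behaviour",
    "simulate_recording",
    "simulate_measures",
    "simulate_study",
    "trials_to_frame",
    "pink_noise",
]

#: analysis windows the generator is calibrated against (ms)
N2P3B_WINDOW_MS = (310.0, 370.0)
LHEOG_WINDOW_MS = (250.0, 450.0)


@dataclass
class BehaviouralTrial:
    subject_id: int
    block: int
    trial: int
    cue_type: str
    hand: str | None
    width_cm: float | None
    amplitude_cm: float | None
    id_bits: float | None
    rt_ms: float | None
    mt_ms: float | None
    miss: bool = False
    wrong_target: bool = False
    is_nogo: bool = False

    @property
    def condition(self) -> str:
        if self.is_nogo:
            return NOGO
        return condition_label(self.width_cm, self.id_bits, self.hand)


def trials_to_frame(trials: list[BehaviouralTrial]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(t) for t in trials])
    df["condition"] = [t.condition for t in trials]
    return df


# ---------------------------------------------------------------------------
# RNG plumbing

def _subject_streams(config: GeneratorConfig) -> list[list[np.random.SeedSequence]]:
    master = np.random.SeedSequence(config.seed)
    return [child.spawn(4) for child in master.spawn(config.n_subjects)]


@dataclass
class _SubjectParams:
    mt_off: float
    rt_off: float
    hand_adv: float  # right-hand RT advantage, ms
    erp_off: float
    heog_off: float
    cnv_off: float
    lrp_off: float


def _draw_subject_params(config: GeneratorConfig, param_ss) -> _SubjectParams:
    rng = np.random.default_rng(param_ss)
    return _SubjectParams(
        mt_off=rng.normal(0.0, config.mt_subject_sd_ms),
        rt_off=rng.normal(0.0, config.rt_subject_sd_ms),
        hand_adv=rng.normal(config.rt_hand_offset_ms, config.rt_hand_offset_sd_ms),
        erp_off=rng.normal(0.0, config.erp_subject_sd_uv),
        heog_off=rng.normal(0.0, config.heog_subject_sd_uv),
        cnv_off=rng.normal(0.0, config.cnv_subject_sd_uv),
        lrp_off=rng.normal(0.0, config.lrp_subject_sd_uv),
    )


# ---------------------------------------------------------------------------
# behaviour

def simulate_behaviour(
    design: ExperimentDesign, config: GeneratorConfig
) -> list[BehaviouralTrial]:
    """Draw the full per-trial behavioural record for every subject."""
    streams = _subject_streams(config)
    trials: list[BehaviouralTrial] = []
    for s in range(config.n_subjects):
        params = _draw_subject_params(config, streams[s][0])
        rng = np.random.default_rng(streams[s][1])
        widths = design.block_widths(s)[: config.n_blocks]
        for b, width in enumerate(widths):
            seq = np.repeat(np.arange(len(design.cue_types)), design.reps_per_cue)
            seq = rng.permutation(seq)
            for t, cue_idx in enumerate(seq):
                cue = design.cue_types[cue_idx]
                if cue == NOGO:
                    trials.append(BehaviouralTrial(
                        subject_id=s, block=b, trial=t, cue_type=NOGO,
                        hand=None, width_cm=None, amplitude_cm=None,
                        id_bits=None, rt_ms=None, mt_ms=None, is_nogo=True,
                    ))
                    continue
                hand, rank = cue.split("_")
                id_bits = design.id_for_rank(rank)
                amp = design.amplitude(width, rank)
                hand_term = (0.5 if hand == "left" else -0.5) * params.hand_adv
                rt = (config.rt_mean_ms + params.rt_off + hand_term
                      + rng.normal(0.0, config.rt_sd_ms))
                mt = (config.mt_intercept_ms
                      + config.mt_slope_ms_per_id * id_bits
                      + params.mt_off + rng.normal(0.0, config.mt_noise_sd_ms))
                # exact draws are stored; marker placement rounds to the
                # sample grid, so event-derived times differ by <1 sample
                rt = float(max(rt, 2000.0 / config.fs_hz))
                mt = float(max(mt, 2000.0 / config.fs_hz))
                miss_rate = config.error_rates[f"{width:g}"][rank]
                miss = bool(rng.random() < miss_rate)
                wrong = bool(rng.random() < config.wrong_target_rates[rank])
                trials.append(BehaviouralTrial(
                    subject_id=s, block=b, trial=t, cue_type=cue, hand=hand,
                    width_cm=width, amplitude_cm=amp, id_bits=id_bits,
                    rt_ms=rt, mt_ms=mt, miss=miss, wrong_target=wrong,
                ))
    return trials


# ---------------------------------------------------------------------------
# waveform templates

def pink_noise(n: int, rng: np.random.Generator, exponent: float = 1.0,
               sd: float = 1.0) -> np.ndarray:
    """1/f^exponent spectrally shaped Gaussian noise with unit-free RMS sd."""
    if sd == 0.0:
        return np.zeros(n)
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _ms_to_samp(ms: float, fs: float) -> int:
    return int(round(ms * fs / 1000.0))


def _window_slice(t0_ms: float, window_ms: tuple[float, float], fs: float) -> slice:
    """Half-open [start, end) window in samples relative to template start."""
    a = _ms_to_samp(window_ms[0] - t0_ms, fs)
    b = _ms_to_samp(window_ms[1] - t0_ms, fs)
    return slice(a, b)


def _bump_template(fs: float) -> tuple[int, np.ndarray]:
    """Cue-locked posterior component: Gaussian bump, unit window mean.

    Returns (offset in samples from cue onset, waveform).
    """
    t0, t1 = 150.0, 600.0
    t = np.arange(_ms_to_samp(t0, fs), _ms_to_samp(t1, fs)) * 1000.0 / fs
    g = np.exp(-0.5 * ((t - 340.0) / 45.0) ** 2)
    win = _window_slice(t0, N2P3B_WINDOW_MS, fs)
    g /= g[win].mean()
    return _ms_to_samp(t0, fs), g


def _cnv_template(fs: float, foreperiod_ms: float) -> tuple[int, np.ndarray]:
    """Cue-locked ramp 400 ms -> go onset, released over 300 ms after go."""
    t0, t1 = 400.0, foreperiod_ms + 300.0
    t = np.arange(_ms_to_samp(t0, fs), _ms_to_samp(t1, fs)) * 1000.0 / fs
    up = np.clip((t - t0) / (foreperiod_ms - t0), 0.0, 1.0)
    down = np.clip((t - foreperiod_ms) / 300.0, 0.0, 1.0)
    g = np.where(t < foreperiod_ms, up, 1.0 - down)
    return _ms_to_samp(t0, fs), g


def _lrp_template(fs: float) -> tuple[int, np.ndarray]:
    """Response-locked ramp: -300 ms -> movement onset, 200 ms release."""
    t = np.arange(_ms_to_samp(-300.0, fs), _ms_to_samp(200.0, fs)) * 1000.0 / fs
    g = np.where(t < 0.0, (t + 300.0) / 300.0, 1.0 - t / 200.0)
    return _ms_to_samp(-300.0, fs), np.clip(g, 0.0, 1.0)


def _saccade_template(fs: float) -> tuple[int, np.ndarray]:
    """Go-locked gaze step: sigmoid rise at ~300 ms, return at ~900 ms.

    Normalised so the mean over the 250-450 ms analysis window is 1.
    """
    t = np.arange(0, _ms_to_samp(1400.0, fs)) * 1000.0 / fs
    g = 1.0 / (1.0 + np.exp(-(t - 300.0) / 25.0))
    g *= 1.0 / (1.0 + np.exp((t - 900.0) / 50.0))
    win = _window_slice(0.0, LHEOG_WINDOW_MS, fs)
    g /= g[win].mean()
    return 0, g


def _blink_template(fs: float, amp: float) -> np.ndarray:
    t = np.arange(_ms_to_samp(-180.0, fs), _ms_to_samp(180.0, fs)) * 1000.0 / fs
    return amp * np.exp(-0.5 * (t / 60.0) ** 2)


def _add(dst: np.ndarray, start: int, wave: np.ndarray) -> None:
    """Add wave into dst at start, clipping at the edges."""
    a, b = start, start + wave.size
    wa, wb = 0, wave.size
    if a < 0:
        wa, a = -a, 0
    if b > dst.size:
        wb -= b - dst.size
        b = dst.size
    if wb > wa:
        dst[a:b] += wave[wa:wb]


#: channel gains for each deterministic component
_BUMP_GAINS = {"Pz": 1.0, "P1": 1.0, "P2": 1.0, "POz": 1.0, "PO3": 1.0,
               "PO4": 1.0, "CPz": 0.6, "Oz": 0.6, "Cz": 0.3}
_CNV_GAINS = {"Cz": 1.0, "FCz": 1.0, "CPz": 1.0, "C1": 1.0, "C2": 1.0,
              "C3": 0.6, "C4": 0.6, "Fz": 0.5, "Pz": 0.3}
_LRP_GAINS_LEFT_HEM = ("C1", "C3")   # contralateral to the right hand
_LRP_GAINS_RIGHT_HEM = ("C2", "C4")  # contralateral to the left hand


def simulate_recording(
    design: ExperimentDesign,
    trials: list[BehaviouralTrial],
    config: GeneratorConfig,
) -> "ContinuousRecording":
    """Render one subject's continuous EEG/EOG from their trial record."""
    from .recording import ContinuousRecording

    subjects = {t.subject_id for t in trials}
    if len(subjects) != 1:
        raise ValueError("simulate_recording expects one subject's trials")
    subject = subjects.pop()
    fs = config.fs_hz
    if fs <= 2 * config.lp_hz:
        raise ConfigError("sampling rate too low for the requested components")

    streams = _subject_streams(config)
    params = _draw_subject_params(config, streams[subject][0])
    rng = np.random.default_rng(streams[subject][2])

    tp_samp = _ms_to_samp(design.timing.trial_period_ms, fs)
    n_trials = len(trials)
    n_samples = n_trials * tp_samp
    cue_off = _ms_to_samp(design.timing.cue_onset_ms, fs)
    go_off = _ms_to_samp(design.timing.go_onset_ms, fs)

    labels = list(EEG_CHANNELS) + list(EOG_CHANNELS)
    data = np.empty((len(labels), n_samples))
    for i in range(len(labels)):
        data[i] = pink_noise(n_samples, rng, config.pink_exponent,
                             config.pink_sd_uv)
        data[i] += rng.normal(0.0, config.white_sd_uv, n_samples)
    i_veog = labels.index("VEOG")
    i_heog = labels.index("HEOG")
    # EOG channels carry their own (larger) noise floor
    for i in (i_veog, i_heog):
        data[i] *= 0.0
        data[i] += pink_noise(n_samples, rng, config.pink_exponent,
                              config.eog_noise_sd_uv)
        data[i] += rng.normal(0.0, config.eog_noise_sd_uv, n_samples)

    # blink artifacts on VEOG (Poisson process over the whole recording)
    if config.blink_rate_hz > 0 and config.blink_amp_uv != 0:
        n_blinks = rng.poisson(config.blink_rate_hz * n_samples / fs)
        centres = np.sort(rng.integers(0, n_samples, n_blinks))
        blink = _blink_template(fs, config.blink_amp_uv)
        for c in centres:
            _add(data[i_veog], int(c) - blink.size // 2, blink)

    # per-trial components and event markers
    bump_off, bump = _bump_template(fs)
    cnv_off, cnv = _cnv_template(fs, design.timing.foreperiod_ms)
    lrp_off, lrp = _lrp_template(fs)
    sac_off, sac = _saccade_template(fs)

    ev_samples: list[int] = []
    ev_labels: list[str] = []
    trials = sorted(trials, key=lambda t: (t.block, t.trial))
    for k, tr in enumerate(trials):
        start = k * tp_samp
        cue_s = start + cue_off
        go_s = start + go_off
        if tr.is_nogo:
            ev_samples += [cue_s, go_s]
            ev_labels += [NOGO, "go"]
            continue
        ev_samples += [cue_s, go_s]
        ev_labels += [cue_label(tr.width_cm, tr.id_bits, tr.hand), "go"]
        lift_s = go_s + _ms_to_samp(tr.rt_ms, fs)
        tap_s = lift_s + _ms_to_samp(tr.mt_ms, fs)
        ev_samples += [lift_s, tap_s]
        ev_labels += ["lift", "tap"]

        amp_bump = (config.erp_intercept_uv
                    + config.erp_slope_uv_per_id * tr.id_bits
                    + params.erp_off)
        for ch, gain in _BUMP_GAINS.items():
            _add(data[labels.index(ch)], cue_s + bump_off, gain * amp_bump * bump)
        amp_cnv = config.cnv_amp_uv + params.cnv_off
        for ch, gain in _CNV_GAINS.items():
            _add(data[labels.index(ch)], cue_s + cnv_off, gain * amp_cnv * cnv)
        amp_lrp = config.lrp_amp_uv + params.lrp_off
        contra = _LRP_GAINS_LEFT_HEM if tr.hand == "right" else _LRP_GAINS_RIGHT_HEM
        for ch in contra:
            _add(data[labels.index(ch)], lift_s + lrp_off, amp_lrp * lrp)
        # gaze step: bipolar HEOG (left minus right eye) goes negative for
        # rightward gaze, so right-target trials carry the law value with
        # its native (negative) sign and left-target trials its mirror.
        amp_sac = (config.heog_intercept_uv
                   + config.heog_slope_uv_per_cm * tr.amplitude_cm
                   + params.heog_off)
        sign = 1.0 if tr.hand == "right" else -1.0
        _add(data[i_heog], go_s + sac_off, sign * amp_sac * sac)

    # EOG -> scalp propagation of the full EOG signals
    for i, ch in enumerate(labels):
        if ch in EOG_CHANNELS:
            continue
        v_coef, h_coef = config.propagation.get(ch, (0.0, 0.0))
        if v_coef:
            data[i] += v_coef * data[i_veog]
        if h_coef:
            data[i] += h_coef * data[i_heog]

    events = pd.DataFrame({"sample_index": ev_samples, "label": ev_labels})
    return ContinuousRecording(
        fs_hz=fs, channel_labels=labels, data=data, events=events,
        subject_id=subject,
    )


def simulate_study(design: ExperimentDesign, config: GeneratorConfig):
    """Yield ``(subject_trials, recording)`` per subject, lazily."""
    trials = simulate_behaviour(design, config)
    for s in range(config.n_subjects):
        subj = [t for t in trials if t.subject_id == s]
        yield subj, simulate_recording(design, subj, config)


# ---------------------------------------------------------------------------
# measure-level simulation

def simulate_measures(
    design: ExperimentDesign, config: GeneratorConfig
) -> pd.DataFrame:
    """Draw per-subject condition-mean window measures directly.

    Emulates the output of the full pipeline's measurement stage: each
    subject x condition cell gets its generator-law mean, the subject's
    random intercept, and Gaussian measurement noise with the configured
    per-measure SD.  Used to study the regression stage at many seeds
    without rendering continuous EEG.
    """
    streams = _subject_streams(config)
    sd = config.measure_noise_sd_uv
    rows = []
    for s in range(config.n_subjects):
        params = _draw_subject_params(config, streams[s][0])
        rng = np.random.default_rng(streams[s][3])
        for width, amp, id_bits in design.cells():
            cond = condition_label(width, id_bits)
            means = {
                "n2p3b": (config.erp_intercept_uv
                          + config.erp_slope_uv_per_id * id_bits
                          + params.erp_off),
                "motor_cnv": config.cnv_amp_uv + params.cnv_off,
                "lrp": config.lrp_amp_uv + params.lrp_off,
                "lheog": (config.heog_intercept_uv
                          + config.heog_slope_uv_per_cm * amp
                          + params.heog_off),
            }
            for name, mu in means.items():
                rows.append({
                    "subject_id": s, "condition": cond, "width_cm": width,
                    "amplitude_cm": amp, "id_bits": id_bits,
                    "measure": name,
                    "value_uv": mu + rng.normal(0.0, sd[name]),
                })
    return pd.DataFrame(rows)
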