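import numpy as np
import pandas as pd
import pytest

from fitts_erp.config import GeneratorConfig
from fitts_erp.design import build_design
from fitts_erp.simulate import (
    pink_noise, simulate_behaviour, simulate_measures, simulate_recording,
    trials_to_frame,
)


class TestBehaviourGenerator:
    def test_deterministic_under_seed(self, small_design, small_config):
        a = trials_to_frame(simulate_behaviour(small_design, small_config))
        b = trials_to_frame(simulate_behaviour(small_design, small_config))
        pd.testing.assert_frame_equal(a, b)
        c = trials_to_frame(
            simulate_behaviour(small_design, small_config.replace(seed=8))
        )
        assert not a["mt_ms"].equals(c["mt_ms"])

    def test_cue_types_balanced_within_block(self, small_design, small_config):
        df = trials_to_frame(simulate_behaviour(small_design, small_config))
        counts = df.groupby(["subject_id", "block", "cue_type"]).size()
        assert (counts == small_design.reps_per_cue).all()

    def test_noiseless_mt_is_the_fitts_line(self, small_design):
        cfg = GeneratorConfig(
            n_subjects=1, n_blocks=3, seed=0,
            mt_noise_sd_ms=0.0, mt_subject_sd_ms=0.0,
        )
        df = trials_to_frame(simulate_behaviour(small_design, cfg))
        go = df[~df["is_nogo"]]
        # a=211, b=68: every ID-3 trial lasts exactly 415 ms
        assert (go.loc[go["id_bits"] == 3.0, "mt_ms"] == 415.0).all()
        assert (go["mt_ms"] == 211.0 + 68.0 * go["id_bits"]).all()

    def test_flat_generator_when_slope_zero(self, design):
        cfg = GeneratorConfig(n_subjects=2, seed=3, mt_slope_ms_per_id=0.0)
        df = trials_to_frame(simulate_behaviour(design, cfg))
        go = df[~df["is_nogo"]]
        means = go.groupby("id_bits")["mt_ms"].mean()
        assert means.max() - means.min() < 10.0  # noise only

    def test_rt_independent_of_id(self, design):
        cfg = GeneratorConfig(n_subjects=6, seed=4)
        df = trials_to_frame(simulate_behaviour(design, cfg))
        go = df[~df["is_nogo"]]
        means = go.groupby("id_bits")["rt_ms"].mean()
        assert means.max() - means.min() < 10.0

    def test_miss_rate_matches_table_at_large_n(self, design):
        # small-width far target: 1.8% of trials
        cfg = GeneratorConfig(n_subjects=20, seed=5)
        df = trials_to_frame(simulate_behaviour(design, cfg))
        cell = df[(df["width_cm"] == 1.0) & (df["id_bits"] == 4.0)]
        n = len(cell)
        rate = cell["miss"].mean()
        se = np.sqrt(0.018 * 0.982 / n)
        assert abs(rate - 0.018) < 4 * se

    def test_nogo_trials_have_no_times(self, small_design, small_config):
        df = trials_to_frame(simulate_behaviour(small_design, small_config))
        nogo = df[df["is_nogo"]]
        assert len(nogo) == small_design.reps_per_cue * 3 * 2
        assert nogo["rt_ms"].isna().all() and nogo["mt_ms"].isna().all()


class TestRecordingGenerator:
    def test_deterministic_and_well_formed(self, subject_recording):
        cfg, d, trials, rec = subject_recording
        again = simulate_recording(d, trials, cfg)
        assert np.array_equal(rec.data, again.data)
        assert rec.events["sample_index"].is_monotonic_increasing
        assert rec.events["sample_index"].iloc[-1] < rec.n_samples
        assert rec.duration_s == pytest.approx(3 * 252.0)

    def test_marker_chain_matches_trial_times(self, subject_recording):
        cfg, d, trials, rec = subject_recording
        ev = rec.events
        lifts = ev[ev["label"] == "lift"]["sample_index"].to_numpy()
        gos = ev[ev["label"] == "go"]["sample_index"].to_numpy()
        assert len(gos) == 3 * 63  # every trial gets a go marker
        action = [t for t in sorted(trials, key=lambda t: (t.block, t.trial))
                  if not t.is_nogo]
        assert len(lifts) == len(action)

    def test_no_blinks_leaves_veog_at_noise_floor(self, small_design):
        cfg = GeneratorConfig(n_subjects=1, n_blocks=1, seed=2,
                              blink_rate_hz=0.0)
        trials = simulate_behaviour(small_design.__class__(n_blocks=1), cfg)
        rec = simulate_recording(build_design(n_blocks=1), trials, cfg)
        veog = rec.get("VEOG")
        # white + pink noise floor only: RMS ~ sqrt(2)*6 uV, far below
        # what even a single 200 uV blink would produce
        assert veog.std() < 3 * cfg.eog_noise_sd_uv
        assert np.abs(veog).max() < 100.0

    def test_noiseless_roi_mean_equals_erp_law(self):
        """With all noise off, the cue-locked posterior window mean is
        exactly the configured linear law in ID."""
        from fitts_erp.erp import N2P3B_ROI, roi_window_mean
        from fitts_erp.preprocess import average, baseline_correct, epoch

        d = build_design(n_blocks=3)
        cfg = GeneratorConfig(
            n_subjects=1, n_blocks=3, seed=0, white_sd_uv=0.0,
            pink_sd_uv=0.0, eog_noise_sd_uv=0.0, blink_rate_hz=0.0,
            erp_subject_sd_uv=0.0, cnv_subject_sd_uv=0.0,
            lrp_subject_sd_uv=0.0, heog_subject_sd_uv=0.0,
        )
        trials = simulate_behaviour(d, cfg)
        rec = simulate_recording(d, trials, cfg)
        ep = baseline_correct(
            epoch(rec, "cue", (-300.0, 1500.0),
                  {l: l for l in rec.events["label"].unique()}),
            (-200.0, 0.0),
        )
        for id_bits, expected in [(2.0, 0.9), (3.0, 2.5), (4.0, 4.1)]:
            conds = [c for c in set(ep.conditions)
                     if f"ID{id_bits:g}" in c]
            vals = [roi_window_mean(e, N2P3B_ROI)
                    for c, e in average(ep, conds).items()]
            assert np.allclose(vals, expected, atol=1e-9)

    def test_sampling_rate_guard(self):
        from fitts_erp.config import ConfigError

        with pytest.raises(ConfigError):
            GeneratorConfig(fs_hz=100.0)  # below 2x the low-pass cutoff


class TestMeasureSimulator:
    def test_grand_means_track_the_laws(self, design):
        cfg = GeneratorConfig(n_subjects=40, seed=9)
        m = simulate_measures(design, cfg)
        grand = m.groupby(["measure", "id_bits", "amplitude_cm"])[
            "value_uv"].mean().reset_index()
        n2 = grand[grand["measure"] == "n2p3b"]
        pred = -2.3 + 1.6 * n2["id_bits"]
        assert np.allclose(n2["value_uv"], pred, atol=0.5)
        lh = grand[grand["measure"] == "lheog"]
        pred = -133.0 - 3.8 * lh["amplitude_cm"]
        assert np.allclose(lh["value_uv"], pred, atol=5.0)

    def test_deterministic(self, design):
        cfg = GeneratorConfig(seed=12)
        pd.testing.assert_frame_equal(
            simulate_measures(design, cfg), simulate_measures(design, cfg)
        )


class TestPinkNoise:
    def test_rms_and_spectrum(self):
        rng = np.random.default_rng(0)
        x = pink_noise(2**16, rng, exponent=1.0, sd=3.0)
        assert x.std() == pytest.approx(3.0, rel=1e-9)
        f = np.fft.rfftfreq(x.size)
        p = np.abs(np.fft.rfft(x)) ** 2
        lo = p[(f > 0.001) & (f < 0.01)].mean()
        hi = p[(f > 0.1) & (f < 0.5)].mean()
        assert lo > 10 * hi  # power concentrated at low frequencies
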