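import numpy as np
import pandas as pd
import pytest
from conftest import make_epochs

from fitts_erp.config import GeneratorConfig
from fitts_erp.design import build_design
from fitts_erp.preprocess import (
    OcularModel, apply_ocular_model, average, bandpass, baseline_correct,
    epoch, fit_ocular_model, reject_artifacts,
)
from fitts_erp.recording import ContinuousRecording
from fitts_erp.simulate import simulate_behaviour, simulate_recording


def simple_recording(n_samples=5000, fs=500.0, events=None):
    data = np.zeros((2, n_samples))
    ev = events if events is not None else pd.DataFrame(
        {"sample_index": [1000], "label": ["nogo"]}
    )
    return ContinuousRecording(fs_hz=fs, channel_labels=["Cz", "Pz"],
                               data=data, events=ev)


class TestEpoching:
    def test_one_epoch_per_lock_event(self):
        ev = pd.DataFrame({
            "sample_index": np.arange(10) * 400 + 300,
            "label": ["nogo"] * 10,
        })
        rec = simple_recording(events=ev)
        ep = epoch(rec, "cue", (-100.0, 200.0))
        assert ep.n_epochs == 10
        assert ep.data.shape == (10, 2, 150)

    def test_edge_event_dropped(self, caplog):
        ev = pd.DataFrame({"sample_index": [50, 1000], "label": ["nogo"] * 2})
        rec = simple_recording(events=ev)
        ep = epoch(rec, "cue", (-300.0, 200.0))  # first cue 100 ms in
        assert ep.n_epochs == 1

    def test_unmapped_condition_is_an_error(self):
        rec = simple_recording()
        with pytest.raises(ValueError, match="unmapped condition"):
            epoch(rec, "cue", (-100.0, 100.0), condition_map={})

    def test_response_locked_condition_comes_from_cue(self):
        ev = pd.DataFrame({
            "sample_index": [500, 1000, 1200, 1400],
            "label": ["cue_W2_ID3_left", "go", "lift", "tap"],
        })
        rec = simple_recording(events=ev)
        ep = epoch(rec, "lift", (-200.0, 100.0))
        assert ep.conditions == ["W2_ID3_left"]


class TestBaseline:
    def test_constant_epoch_zeroed(self):
        ep = make_epochs(np.full((2, 1, 100), 5.0), window_ms=(-100, 100))
        out = baseline_correct(ep, (-100.0, 0.0))
        assert np.allclose(out.data, 0.0)

    def test_arithmetic(self):
        data = np.zeros((1, 1, 100))
        data[0, 0, :50] = 2.0   # baseline mean 2
        data[0, 0, 75] = 10.0   # peak
        ep = make_epochs(data, window_ms=(-100, 100))
        out = baseline_correct(ep, (-100.0, 0.0))
        assert out.data[0, 0, 75] == pytest.approx(8.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.normal(size=(3, 2, 200)), window_ms=(-200, 200))
        once = baseline_correct(ep, (-200.0, 0.0))
        twice = baseline_correct(once, (-200.0, 0.0))
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_baseline_outside_window_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 100)), window_ms=(0, 200))
        with pytest.raises(ValueError):
            baseline_correct(ep, (-100.0, 0.0))


class TestRejection:
    def make_with_ptp(self, ptp):
        data = np.zeros((1, 2, 100))
        data[0, 0, 10] = ptp / 2
        data[0, 0, 20] = -ptp / 2
        return make_epochs(data, channels=["Cz", "VEOG"])

    def test_boundary_is_strict(self):
        # exceeding 100 uV rejects; exactly 100 uV is kept
        assert reject_artifacts(self.make_with_ptp(101.0)).rejected[0]
        assert not reject_artifacts(self.make_with_ptp(100.0)).rejected[0]

    def test_reason_names_channel(self):
        out = reject_artifacts(self.make_with_ptp(150.0))
        assert "Cz" in out.reject_reason[0]

    def test_all_zero_kept(self):
        out = reject_artifacts(make_epochs(np.zeros((3, 2, 50))))
        assert not out.rejected.any()

    def test_eog_excluded_by_default(self):
        data = np.zeros((1, 2, 100))
        data[0, 1, 10] = 300.0  # huge deflection on VEOG only
        ep = make_epochs(data, channels=["Cz", "VEOG"])
        assert not reject_artifacts(ep).rejected[0]
        assert reject_artifacts(ep, include_eog=True).rejected[0]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        ep = make_epochs(rng.normal(0, 30, size=(50, 3, 100)))
        hi = reject_artifacts(ep, 120.0)
        lo = reject_artifacts(ep, 80.0)
        # lowering the threshold never un-rejects an epoch
        assert (lo.rejected | ~hi.rejected).all()


class TestAveraging:
    def test_identical_epochs(self):
        data = np.tile(np.arange(50.0), (2, 1, 1)).reshape(2, 1, 50)
        ep = make_epochs(data, conditions=["a", "a"])
        assert np.allclose(average(ep)["a"].data[0], np.arange(50.0))

    def test_symmetric_epochs_cancel(self):
        x = np.random.default_rng(0).normal(size=(1, 2, 60))
        ep = make_epochs(np.concatenate([x, -x]), conditions=["a", "a"])
        assert np.allclose(average(ep)["a"].data, 0.0)

    def test_linearity_in_constant_shift(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(6, 2, 40))
        ep = make_epochs(base)
        shifted = make_epochs(base + 3.0)
        assert np.allclose(
            average(shifted)["a"].data, average(ep)["a"].data + 3.0
        )

    def test_rejected_epochs_excluded(self):
        data = np.zeros((2, 1, 10))
        data[1] = 100.0
        ep = make_epochs(data, conditions=["a", "a"])
        ep.rejected[1] = True
        assert np.allclose(average(ep)["a"].data, 0.0)

    def test_empty_condition_error_names_it(self):
        ep = make_epochs(np.zeros((1, 1, 10)), conditions=["a"])
        with pytest.raises(ValueError, match="'b'"):
            average(ep, ["b"])

    def test_monte_carlo_recovery_of_known_erp(self):
        rng = np.random.default_rng(5)
        truth = np.sin(np.linspace(0, 2 * np.pi, 100))
        n = 100
        data = truth + rng.normal(0, 2.0, size=(n, 1, 100))
        av = average(make_epochs(data))["a"].data[0]
        sem = 2.0 / np.sqrt(n)
        assert np.abs(av - truth).max() < 5 * sem


class TestBandpass:
    fs = 500.0

    def sine(self, freq, seconds=20.0):
        t = np.arange(int(seconds * self.fs)) / self.fs
        data = np.sin(2 * np.pi * freq * t)[None, None, :]
        return make_epochs(data, fs_hz=self.fs)

    def rms_mid(self, ep):
        x = ep.data[0, 0]
        mid = x[x.size // 4: -x.size // 4]
        return np.sqrt(np.mean(mid**2))

    def test_stopband_attenuation(self):
        out = bandpass(self.sine(100.0), 0.05, 60.0)
        ratio = self.rms_mid(out) / (1 / np.sqrt(2))
        assert 20 * np.log10(ratio) < -24.0

    def test_passband_preserved(self):
        out = bandpass(self.sine(10.0), 0.05, 60.0)
        assert self.rms_mid(out) == pytest.approx(1 / np.sqrt(2), rel=0.01)

    def test_dc_removed(self):
        data = np.full((1, 1, int(120 * self.fs)), 7.0)
        out = bandpass(make_epochs(data, fs_hz=self.fs), 0.05, 60.0)
        mid = out.data[0, 0, int(30 * self.fs): int(90 * self.fs)]
        assert np.abs(mid).max() < 0.35  # >95% of the 7 uV offset gone

    def test_invalid_cutoffs(self):
        ep = self.sine(10.0, seconds=2.0)
        with pytest.raises(ValueError, match="must exceed"):
            bandpass(ep, 60.0, 0.05)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(ep, 0.05, 300.0)


class TestOcularCorrection:
    def toy_epochs(self, coef_v=0.2, coef_h=0.0, n=200, noise=1.0, seed=0):
        rng = np.random.default_rng(seed)
        veog = rng.normal(0, 50, size=(n, 100))
        heog = rng.normal(0, 40, size=(n, 100))
        eeg = (coef_v * veog + coef_h * heog
               + rng.normal(0, noise, size=(n, 100)))
        data = np.stack([eeg, veog, heog], axis=1)
        return make_epochs(data, channels=["Cz", "VEOG", "HEOG"],
                           conditions=["a", "b"] * (n // 2))

    def test_recovers_known_propagation(self):
        model = fit_ocular_model(self.toy_epochs(coef_v=0.2))
        assert model.coefficients["VEOG"]["Cz"] == pytest.approx(0.2, abs=0.02)

    def test_orthogonal_eog_gives_zero(self):
        model = fit_ocular_model(self.toy_epochs(coef_v=0.0, noise=5.0))
        assert abs(model.coefficients["VEOG"]["Cz"]) < 0.02

    def test_sequential_fit_matches_lstsq_oracle(self):
        """On a 20-epoch toy set both coefficients agree with an
        exhaustive least-squares fit done independently."""
        ep = self.toy_epochs(coef_v=0.3, coef_h=-0.15, n=20, seed=4)
        model = fit_ocular_model(ep)
        # oracle: same sequential scheme, via lstsq on the residuals
        res = ep.data - np.stack(
            [ep.data[np.array(ep.conditions) == c].mean(0)
             for c in ep.conditions])
        eeg = res[:, 0].ravel()
        v = res[:, 1].ravel() - res[:, 1].mean()
        h = res[:, 2].ravel() - res[:, 2].mean()
        eeg = eeg - eeg.mean()
        bv = np.linalg.lstsq(v[:, None], eeg, rcond=None)[0][0]
        bh = np.linalg.lstsq(h[:, None], eeg - bv * v, rcond=None)[0][0]
        assert model.coefficients["VEOG"]["Cz"] == pytest.approx(bv, abs=1e-10)
        assert model.coefficients["HEOG"]["Cz"] == pytest.approx(bh, abs=1e-10)

    def test_flat_eog_rejected(self):
        ep = self.toy_epochs()
        ep.data[:, 1, :] = 0.0
        with pytest.raises(ValueError, match="flat EOG"):
            fit_ocular_model(ep)

    def test_single_sample_epochs_rejected(self):
        ep = make_epochs(np.zeros((4, 3, 1)),
                         channels=["Cz", "VEOG", "HEOG"],
                         conditions=["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="variance undefined"):
            fit_ocular_model(ep)

    def test_too_few_epochs_per_condition(self):
        ep = self.toy_epochs(n=4)
        ep.conditions = ["a", "b", "c", "d"]
        with pytest.raises(ValueError, match=">=2 epochs"):
            fit_ocular_model(ep)

    def test_zero_model_is_identity(self):
        ep = self.toy_epochs(n=10)
        model = OcularModel(
            coefficients={"VEOG": {"Cz": 0.0}, "HEOG": {"Cz": 0.0}},
            order=("VEOG", "HEOG"),
        )
        out = apply_ocular_model(ep, model)
        assert np.array_equal(out.data, ep.data)

    def test_exact_cancellation(self):
        veog = np.random.default_rng(2).normal(size=(5, 80))
        data = np.stack([0.2 * veog, veog], axis=1)
        ep = make_epochs(data, channels=["Cz", "VEOG"])
        model = OcularModel(coefficients={"VEOG": {"Cz": 0.2}},
                            order=("VEOG",))
        out = apply_ocular_model(ep, model)
        assert np.allclose(out.data[:, 0], 0.0, atol=1e-12)
        # EOG channel itself is untouched
        assert np.array_equal(out.data[:, 1], veog)

    def test_channel_mismatch_rejected(self):
        ep = self.toy_epochs(n=4)
        model = OcularModel(coefficients={"XEOG": {"Cz": 0.1}},
                            order=("XEOG",))
        with pytest.raises(ValueError, match="missing"):
            apply_ocular_model(ep, model)

    def test_blink_contamination_reduced_90_percent(self):
        """Blink-locked frontal average shrinks >=90% after correction."""
        cfg = GeneratorConfig(n_subjects=1, n_blocks=1, seed=13,
                              blink_rate_hz=0.4)
        d = build_design(n_blocks=1)
        trials = simulate_behaviour(d, cfg)
        rec = simulate_recording(d, trials, cfg)
        model = fit_ocular_model(epoch(rec, "cue", (-300.0, 1500.0)))
        corrected = apply_ocular_model(rec, model)
        veog = rec.get("VEOG")
        peaks = np.nonzero(
            (veog[1:-1] > 150) & (veog[1:-1] >= veog[:-2])
            & (veog[1:-1] >= veog[2:])
        )[0] + 1
        peaks = peaks[(peaks > 200) & (peaks < rec.n_samples - 200)]
        assert peaks.size >= 20

        def blink_locked_amp(r):
            fz = r.get("Fz")
            segs = np.stack([fz[p - 100: p + 100] for p in peaks])
            seg = segs.mean(0)
            return abs(seg[100] - (seg[:25].mean() + seg[-25:].mean()) / 2)

        before = blink_locked_amp(rec)
        after = blink_locked_amp(corrected)
        assert before > 30.0  # contamination clearly present pre-correction
        assert after <= 0.1 * before

    def test_noop_on_artifact_free_input(self):
        """Fitted coefficients on EOG-uncorrelated data are tiny, so the
        correction leaves the EEG essentially unchanged."""
        ep = self.toy_epochs(coef_v=0.0, coef_h=0.0, noise=5.0, n=400)
        model = fit_ocular_model(ep)
        out = apply_ocular_model(ep, model)
        rms = np.sqrt(np.mean(ep.data[:, 0] ** 2))
        assert np.sqrt(np.mean((out.data[:, 0] - ep.data[:, 0]) ** 2)) < 0.05 * rms
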