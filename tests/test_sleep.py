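"""Sleep staging, band power, normalized delta, spike-wave detection."""

import numpy as np
import pandas as pd
import pytest

from fvpkit import sleep as sl
from fvpkit.errors import MissingChannelError, ScheduleCoverageError, WindowError
from fvpkit.io import Channel, Hypnogram, Recording
from fvpkit.synth import BackgroundSpec, SimConfig, simulate


def recording_from(signals, labels, fs=1000.0):
    return Recording(np.asarray(signals, dtype=float), fs,
                     [Channel.from_label(lab) for lab in labels])


@pytest.fixture(scope="module")
def sleep_sim():
    cfg = SimConfig(
        protocol="freely_behaving", days=3, flashes_per_eye_per_session=50,
        sessions_per_day=2, inter_session_gap_s=400.0, sleep_mode="with_sleep",
        baseline_sleep_s=600.0,
        channels=("V1M_L", "V1M_R", "EEG", "EMG"),
    )
    return simulate(cfg, 40)


class TestStaging:
    def test_agreement_with_planted_schedule(self, sleep_sim):
        hyp = sl.stage_sleep(sleep_sim.recording)
        truth = sleep_sim.hypnogram
        n = min(len(hyp.epochs), len(truth.epochs))
        agree = np.mean(
            hyp.epochs["state"].to_numpy()[:n] == truth.epochs["state"].to_numpy()[:n]
        )
        assert agree >= 0.90

    def test_zero_emg_pure_delta_is_nrem(self):
        t = np.arange(20000) / 1000.0
        eeg = 50 * np.sin(2 * np.pi * 2.0 * t)
        emg = np.zeros_like(eeg)
        rec = recording_from([eeg, emg], ["EEG", "EMG"])
        hyp = sl.stage_sleep(rec, emg_threshold_uV=5.0)
        assert (hyp.epochs["state"] == "nrem").all()

    def test_high_emg_is_wake(self):
        rng = np.random.default_rng(0)
        eeg = rng.normal(0, 20, 20000)
        emg = rng.normal(0, 80, 20000)
        rec = recording_from([eeg, emg], ["EEG", "EMG"])
        hyp = sl.stage_sleep(rec, emg_threshold_uV=10.0)
        assert (hyp.epochs["state"] == "wake").all()

    def test_missing_emg_rejected(self):
        rec = recording_from([np.zeros(8000)], ["EEG"])
        with pytest.raises(MissingChannelError):
            sl.stage_sleep(rec)


class TestBandPower:
    def test_sinusoid_parseval(self):
        """A pure 2 Hz sinusoid of amplitude A has delta power A^2/2."""
        a = 30.0
        t = np.arange(60000) / 1000.0
        rec = recording_from([a * np.sin(2 * np.pi * 2.0 * t)], ["V1M_L"])
        delta = sl.band_power(rec, "V1M_L", "delta", epoch_s=20.0)["power_uV2"]
        theta = sl.band_power(rec, "V1M_L", "theta", epoch_s=20.0)["power_uV2"]
        assert delta.mean() == pytest.approx(a**2 / 2, rel=0.05)
        assert theta.mean() < 0.01 * delta.mean()

    def test_white_noise_power_proportional_to_bandwidth(self):
        rng = np.random.default_rng(1)
        rec = recording_from([rng.normal(0, 25, 120000)], ["V1M_L"])
        p1 = sl.band_power(rec, "V1M_L", (10.0, 30.0), epoch_s=120.0)["power_uV2"].iloc[0]
        p2 = sl.band_power(rec, "V1M_L", (30.0, 70.0), epoch_s=120.0)["power_uV2"].iloc[0]
        assert p2 / p1 == pytest.approx(2.0, rel=0.10)

    def test_zero_signal_zero_power(self):
        rec = recording_from([np.zeros(8000)], ["V1M_L"])
        assert sl.band_power(rec, "V1M_L", "delta")["power_uV2"].max() == 0.0

    def test_band_above_nyquist_rejected(self):
        rec = recording_from([np.zeros(8000)], ["V1M_L"])
        with pytest.raises(WindowError):
            sl.band_power(rec, "V1M_L", (400.0, 600.0))

    def test_additivity_over_disjoint_bands(self):
        rng = np.random.default_rng(2)
        rec = recording_from([rng.normal(0, 25, 120000)], ["V1M_L"])
        p_lo = sl.band_power(rec, "V1M_L", (10.0, 40.0), epoch_s=120.0)["power_uV2"].iloc[0]
        p_hi = sl.band_power(rec, "V1M_L", (40.0, 80.0), epoch_s=120.0)["power_uV2"].iloc[0]
        p_all = sl.band_power(rec, "V1M_L", (10.0, 80.0), epoch_s=120.0)["power_uV2"].iloc[0]
        assert p_lo + p_hi == pytest.approx(p_all, rel=0.05)

    def test_dc_offset_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 25, 60000)
        p0 = sl.band_power(recording_from([x], ["V1M_L"]), "V1M_L", "delta")["power_uV2"]
        p1 = sl.band_power(recording_from([x + 500.0], ["V1M_L"]), "V1M_L", "delta")["power_uV2"]
        assert np.allclose(p0, p1, rtol=1e-6)


class TestNormalizedDelta:
    def test_planted_v1_gain_recovered(self, sleep_sim):
        """Late/baseline normalized-delta ratio recovers the planted 1.3 gain;
        the EEG channel itself stays flat."""
        sim = sleep_sim
        hyp = sl.stage_sleep(sim.recording)
        tc = sl.normalized_delta_timecourse(
            sim.recording, "V1M_L", "EEG", hyp, sim.events
        )
        t_stim0 = sim.events["onset_s"].min()
        t_gain = sim.truth.gain_end_of_day1_s
        base = tc[tc["start_s"] < t_stim0 - 60]
        late = tc[tc["start_s"] > t_gain]
        assert len(base) >= 3 and len(late) >= 3
        ratio = late["norm_delta"].mean() / base["norm_delta"].mean()
        assert ratio == pytest.approx(sim.truth.config.background.v1_delta_gain_post, rel=0.10)
        eeg_ratio = late["eeg_delta"].mean() / base["eeg_delta"].mean()
        assert eeg_ratio == pytest.approx(1.0, abs=0.10)

    def test_rem_theta_and_wake_gamma_stable(self, sleep_sim):
        sim = sleep_sim
        hyp = sl.stage_sleep(sim.recording)
        t_stim0 = sim.events["onset_s"].min()
        t_gain = sim.truth.gain_end_of_day1_s
        end = sim.recording.duration_s
        theta = sl.state_band_contrast(
            sim.recording, "V1M_L", "theta", "rem", hyp, sim.events,
            (0.0, t_stim0 - 60), (t_gain, end),
        )
        gamma = sl.state_band_contrast(
            sim.recording, "V1M_L", "gamma_narrow", "wake", hyp, sim.events,
            (0.0, t_stim0 - 60), (t_gain, end),
        )
        assert theta == pytest.approx(1.0, abs=0.10)
        assert gamma == pytest.approx(1.0, abs=0.10)


@pytest.fixture(scope="module")
def planted():
    bg = BackgroundSpec(sw_event_rate_base_per_min=2.0, sw_event_rate_slope_per_day=0.0)
    cfg = SimConfig(days=1, flashes_per_eye_per_session=2, sessions_per_day=1,
                    inter_session_gap_s=5.0, extra_wake_s=600.0, background=bg,
                    channels=("V1M_L", "V1M_R", "EEG", "EMG"))
    return simulate(cfg, 31)


class TestSwDetection:
    def test_sensitivity_on_planted_events(self, planted):
        det = sl.detect_sw_events(planted.recording, "V1M_L")
        truth = planted.truth.sw_events.query("channel == 'V1M_L'")
        hits = sum(
            ((det["start_s"] < ev.end_s + 0.3) & (det["end_s"] > ev.start_s - 0.3)).any()
            for ev in truth.itertuples()
        )
        assert hits / len(truth) >= 0.95

    def test_no_false_events_on_pink_noise(self):
        bg = BackgroundSpec(sw_event_rate_base_per_min=0.0,
                            sw_event_rate_slope_per_day=0.0, state_oscillations={})
        cfg = SimConfig(days=1, flashes_per_eye_per_session=2, sessions_per_day=1,
                        inter_session_gap_s=5.0, extra_wake_s=600.0, background=bg,
                        channels=("V1M_L", "V1M_R", "EEG", "EMG"))
        sim = simulate(cfg, 32)
        det = sl.detect_sw_events(sim.recording, "V1M_L")
        assert len(det) / (sim.recording.duration_s / 60.0) <= 0.5

    def test_detected_events_satisfy_invariants(self, planted):
        det = sl.detect_sw_events(planted.recording, "V1M_L")
        assert (det["peak_frequency_hz"].between(3.0, 6.0)).all()
        center = 4.5
        assert ((det["end_s"] - det["start_s"]) >= 3.0 / center - 1e-9).all()
        starts, ends = det["start_s"].to_numpy(), det["end_s"].to_numpy()
        assert (starts[1:] >= ends[:-1]).all()  # non-overlapping per channel

    def test_dc_offset_invariance(self, planted):
        rec = planted.recording
        shifted = Recording(rec.signals + 300.0, rec.sample_rate_hz, rec.channels)
        a = sl.detect_sw_events(rec, "V1M_L")
        b = sl.detect_sw_events(shifted, "V1M_L")
        assert np.allclose(a["start_s"], b["start_s"])

    def test_short_span_rejected(self):
        rec = recording_from([np.zeros(300), np.zeros(300)], ["V1M_L", "EMG"])
        with pytest.raises(ScheduleCoverageError):
            sl.detect_sw_events(
                rec, "V1M_L",
                hypnogram=Hypnogram(
                    pd.DataFrame({"start_s": [0.0], "state": ["wake"]}), 0.3
                ),
            )
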