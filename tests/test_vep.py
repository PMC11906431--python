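"""Epoching, averaging, peak/area operators, PSTH."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fvpkit.errors import EmptySelectionError, TooFewEventsError, WindowError

from fvpkit.synth import default_kernel, render_kernel
from fvpkit.synth.simulate import pathway_for
from fvpkit.vep import (
    EpochSet,
    VepWaveform,
    detect_peaks,
    epoch_areas,
    extract_epochs,
    psth,
    triggered_average,
    waveform_area,
)


def make_waveform(trace, pre_ms=100.0, fs=1000.0):
    return VepWaveform(np.asarray(trace, dtype=float), 1, pre_ms, fs)


def kernel_waveform(gains=None, pre_ms=100.0):
    w = render_kernel(default_kernel(), gains)
    return make_waveform(np.concatenate([np.zeros(int(pre_ms)), w]), pre_ms)


class TestExtractEpochs:
    def test_count_oracle(self, noise_free_sim):
        """One epoch per (event, visual channel)."""
        rec, ev = noise_free_sim.recording, noise_free_sim.events
        es = extract_epochs(rec, ev, channels=["V1M_L", "V1M_R"])
        assert len(es) == len(ev) * 2

    def test_pre_zero_starts_at_onset(self, noise_free_sim):
        rec, ev = noise_free_sim.recording, noise_free_sim.events
        es = extract_epochs(rec, ev, pre_ms=0.0, post_ms=600.0, channels=["V1M_L"])
        kernel = render_kernel(default_kernel())
        assert np.allclose(es.traces[0], kernel)

    def test_edge_events_dropped(self, noise_free_sim, caplog):
        rec, ev = noise_free_sim.recording, noise_free_sim.events
        bad = pd.concat(
            [ev, pd.DataFrame([{"onset_s": 0.01, "eye": "left", "duration_ms": 10.0,
                                "session": 1, "day": 1}])],
            ignore_index=True,
        ).sort_values("onset_s").reset_index(drop=True)
        es = extract_epochs(rec, bad, pre_ms=100.0, post_ms=600.0, channels=["V1M_L"])
        assert len(es) == len(ev)

    def test_noise_free_epoch_equals_kernel(self, noise_free_sim):
        """With zero noise, each epoch is exactly the rendered kernel."""
        rec, ev = noise_free_sim.recording, noise_free_sim.events
        es = extract_epochs(rec, ev, channels=["V1M_L"])
        kernel = render_kernel(default_kernel())
        for tr in es.traces:
            assert np.allclose(tr[100:], kernel, atol=1e-9)
            assert np.allclose(tr[:100], 0.0, atol=1e-9)


class TestTriggeredAverage:
    def test_linearity_identical_epochs(self, noise_free_sim):
        rec, ev = noise_free_sim.recording, noise_free_sim.events
        es = extract_epochs(rec, ev, channels=["V1M_L"])
        wf = triggered_average(es)
        assert np.allclose(wf.trace, es.traces[0])
        assert wf.n_events == len(es)

    def test_empty_selection_raises(self, noise_free_sim):
        rec, ev = noise_free_sim.recording, noise_free_sim.events
        es = extract_epochs(rec, ev, channels=["V1M_L"])
        with pytest.raises(EmptySelectionError):
            triggered_average(es, {"day": 99})

    def test_residual_sd_scales_inverse_sqrt_n(self):
        """White-noise epochs: residual SD of the average ~ sigma/sqrt(N)."""
        rng = np.random.default_rng(42)
        sigma, n_samp = 30.0, 700
        for n in (25, 100, 400):
            traces = rng.normal(0, sigma, (n, n_samp))
            meta = pd.DataFrame({"event_id": range(n), "eye": "left"})
            es = EpochSet(traces, meta, 100.0, 600.0, 1000.0)
            resid_sd = triggered_average(es).trace.std()
            assert resid_sd == pytest.approx(sigma / np.sqrt(n), rel=0.20)


class TestDetectPeaks:
    def test_canonical_latencies(self):
        ps = detect_peaks(kernel_waveform())
        assert ps.latencies_ms["N1"] == pytest.approx(30.0, abs=1.0)
        assert ps.latencies_ms["N2"] == pytest.approx(200.0, abs=1.0)
        assert ps.latencies_ms["P1"] == pytest.approx(100.0, abs=1.0)

    def test_amplitude_recovery_within_2pct(self):
        ps = detect_peaks(kernel_waveform())
        planted = {"N1": -80.0, "P1": 60.0, "N2": -100.0, "P2": 50.0, "N3": -40.0}
        for k, v in planted.items():
            assert ps.amplitudes_uV[k] == pytest.approx(v, rel=0.02)

    def test_all_zero_trace(self):
        ps = detect_peaks(make_waveform(np.zeros(700)))
        assert all(v == 0.0 for v in ps.amplitudes_uV.values())

    def test_homogeneity(self):
        wf = kernel_waveform()
        ps1 = detect_peaks(wf)
        ps2 = detect_peaks(make_waveform(2.0 * wf.trace))
        for k in ps1.amplitudes_uV:
            assert ps2.amplitudes_uV[k] == pytest.approx(2 * ps1.amplitudes_uV[k])
            assert ps2.latencies_ms[k] == ps1.latencies_ms[k]

    def test_baseline_referencing(self):
        """A DC offset is removed by the pre-stimulus baseline."""
        wf = kernel_waveform()
        shifted = make_waveform(wf.trace + 55.0)
        ps0, ps1 = detect_peaks(wf), detect_peaks(shifted)
        for k in ps0.amplitudes_uV:
            assert ps1.amplitudes_uV[k] == pytest.approx(ps0.amplitudes_uV[k], abs=1e-9)

    def test_window_outside_trace_raises(self):
        with pytest.raises(WindowError):
            detect_peaks(kernel_waveform(), windows={"N2": (100.0, 2000.0)})


class TestWaveformArea:
    def test_zero_trace(self):
        assert waveform_area(make_waveform(np.zeros(700))) == 0.0

    def test_homogeneity(self):
        wf = kernel_waveform()
        assert waveform_area(make_waveform(3.0 * wf.trace)) == pytest.approx(
            3.0 * waveform_area(wf)
        )

    def test_boxcar_closed_form(self):
        """Unit boxcar of 100 ms over [0, 500) integrates to 100 uV*ms."""
        trace = np.zeros(700)
        trace[100:200] = 1.0  # 100 ms boxcar starting at onset
        assert waveform_area(make_waveform(trace), 0.0, 500.0) == pytest.approx(100.0)

    def test_inverted_window_rejected(self):
        with pytest.raises(WindowError):
            waveform_area(kernel_waveform(), 300.0, 100.0)

    def test_single_epoch_areas_match_waveform_area(self, noise_free_sim):
        rec, ev = noise_free_sim.recording, noise_free_sim.events
        es = extract_epochs(rec, ev, channels=["V1M_L"])
        areas = epoch_areas(es)
        wf_area = waveform_area(triggered_average(es))
        assert np.allclose(areas, wf_area)


class TestPathway:
    @pytest.mark.parametrize(
        "eye,hemi,expected",
        [
            ("right", "L", "contra"),
            ("right", "R", "ipsi"),
            ("left", "R", "contra"),
            ("left", "L", "ipsi"),
            ("both", "L", "binocular"),
            ("both", "R", "binocular"),
        ],
    )
    def test_exhaustive(self, eye, hemi, expected):
        assert pathway_for(eye, hemi) == expected


class TestPsth:
    def test_homogeneous_poisson_flat(self):
        """Uniform spikes give a flat perievent histogram (chi-square)."""
        rng = np.random.default_rng(9)
        spikes = pd.DataFrame(
            {"unit_id": "u1", "spike_time_s": np.sort(rng.uniform(0, 1000, 60000))}
        )
        events = pd.DataFrame({"onset_s": np.arange(10.0, 900.0, 10.0)})
        h = psth(spikes, events, bin_ms=50.0, span_ms=(0.0, 500.0))
        chi2, p = stats.chisquare(h.counts)
        assert p > 0.01

    def test_evoked_modes_at_n1_n2(self):
        """Simulated V1 spikes peak within 15 ms of the N1 and N2 latencies."""
        from conftest import quiet_background
        from fvpkit.synth import SimConfig, simulate

        cfg = SimConfig(
            days=1, flashes_per_eye_per_session=100, sessions_per_day=1,
            inter_session_gap_s=5.0, background=quiet_background(),
            channels=("V1M_L", "V1M_R", "EEG", "EMG"),
            spikes=True, spike_base_rate_hz=2.0, spike_evoked_rate_hz=120.0,
        )
        sim = simulate(cfg, 3)
        h = psth(sim.spikes, sim.events, bin_ms=10.0, span_ms=(0.0, 500.0),
                 unit_ids=["V1M_L_u1"])
        centers = (h.edges_ms[:-1] + h.edges_ms[1:]) / 2
        m1 = centers[np.argmax(h.counts[centers < 100])]
        n2_zone = (centers >= 100) & (centers < 300)
        m2 = centers[n2_zone][np.argmax(h.counts[n2_zone])]
        assert abs(m1 - 30) <= 15
        assert abs(m2 - 200) <= 15

    def test_empty_spikes_zero_histogram(self):
        spikes = pd.DataFrame({"unit_id": [], "spike_time_s": []})
        events = pd.DataFrame({"onset_s": [1.0, 2.0]})
        h = psth(spikes, events)
        assert h.counts.sum() == 0

    def test_zero_events_raises(self):
        spikes = pd.DataFrame({"unit_id": ["u"], "spike_time_s": [1.0]})
        with pytest.raises(TooFewEventsError):
            psth(spikes, pd.DataFrame({"onset_s": []}))
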