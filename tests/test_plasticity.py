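"""Day ratios, rapid-potentiation index, gain recovery, group pooling."""

import numpy as np
import pandas as pd
import pytest

from conftest import quiet_background
from fvpkit import plasticity, vep
from fvpkit.errors import TooFewEventsError
from fvpkit.synth import GainModel, SimConfig, compute_gain, simulate


def visual_epochs(sim):
    return vep.extract_epochs(
        sim.recording, sim.events,
        channels=[c.label for c in sim.recording.visual_channels()],
    )


@pytest.fixture(scope="module")
def noise_free_wt_2day():
    """Noise-free wild-type, 2 days: measured ratios equal planted gain ratios."""
    cfg = SimConfig(
        days=2, flashes_per_eye_per_session=100, sessions_per_day=1,
        inter_session_gap_s=5.0, background=quiet_background(),
        channels=("V1M_L", "V1M_R", "V1L_L", "V1L_R", "EEG", "EMG"),
    )
    return simulate(cfg, 5)


@pytest.fixture(scope="module")
def ko_day1():
    cfg = SimConfig(
        days=1, flashes_per_eye_per_session=100, sessions_per_day=1,
        inter_session_gap_s=5.0, condition="NR2A_KO",
        channels=("V1M_L", "V1M_R", "EEG", "EMG"),
    )
    return simulate(cfg, 6)


class TestDayRatio:
    def test_identical_days_give_unity(self, ko_day1):
        """Plasticity off: duplicating day-1 events as day 2 gives ratio 1."""
        sim = ko_day1
        ev2 = sim.events.copy()
        ev2["day"] = 2
        both = pd.concat([sim.events, ev2], ignore_index=True)
        es = vep.extract_epochs(sim.recording, both, channels=["V1M_L", "V1M_R"])
        tbl = plasticity.day_ratio(es, peak="N2", late_day=2)
        assert np.allclose(tbl["ratio"].dropna(), 1.0)

    def test_noise_free_ratio_matches_planted_gain(self, noise_free_wt_2day):
        """Measured day-2/day-1 contra N2 ratio equals the planted mean-gain
        ratio from the closed-form model (the generator oracle)."""
        es = visual_epochs(noise_free_wt_2day)
        tbl = plasticity.day_ratio(es, peak="N2", late_day=2)
        m = GainModel()
        n_per_day = 200
        g = lambda d: np.mean(
            [compute_gain(m, "N2", d, (d - 1) * n_per_day + i, "contra")
             for i in range(n_per_day)]
        )
        expected = g(2) / g(1)
        got = tbl[tbl["pathway"] == "contra"]["ratio"].mean()
        assert got == pytest.approx(expected, rel=0.03)

    def test_low_day1_amplitude_flagged(self, ko_day1):
        sim = ko_day1
        ev2 = sim.events.copy()
        ev2["day"] = 2
        both = pd.concat([sim.events, ev2], ignore_index=True)
        es = vep.extract_epochs(sim.recording, both, channels=["V1M_L"])
        tbl = plasticity.day_ratio(es, peak="N2", late_day=2, min_day1_uV=1e6)
        assert tbl["flagged"].all() and tbl["ratio"].isna().all()

    def test_ratio_invariant_under_rescaling(self, noise_free_wt_2day):
        sim = noise_free_wt_2day
        es = visual_epochs(sim)
        scaled = vep.EpochSet(es.traces * 3.7, es.meta, es.pre_ms, es.post_ms, es.sample_rate_hz)
        t1 = plasticity.day_ratio(es, peak="N2", late_day=2)
        t2 = plasticity.day_ratio(scaled, peak="N2", late_day=2)
        assert np.allclose(t1["ratio"], t2["ratio"])


class TestRapidIndex:
    def test_plasticity_off_near_unity(self, ko_day1):
        es = vep.extract_epochs(ko_day1.recording, ko_day1.events,
                                channels=["V1M_L", "V1M_R"])
        _, pooled = plasticity.rapid_index(es)
        assert pooled.index == pytest.approx(1.0, abs=0.12)

    def test_wt_matches_planted_gain(self):
        """Measured area index tracks the planted mean rapid gain (+/-15%)."""
        cfg = SimConfig(
            days=1, flashes_per_eye_per_session=100, sessions_per_day=1,
            inter_session_gap_s=5.0,
            channels=("V1M_L", "V1M_R", "V1L_L", "V1L_R", "EEG", "EMG"),
        )
        idx = []
        for seed in (11, 12, 13):
            sim = simulate(cfg, seed)
            es = visual_epochs(sim)
            _, pooled = plasticity.rapid_index(es)
            idx.append(pooled.index)
        m = GainModel()
        g = lambda rng_: np.mean([compute_gain(m, "N2", 1, i, "contra") for i in rng_])
        planted = g(range(190, 200)) / g(range(0, 10))
        assert np.mean(idx) == pytest.approx(planted, rel=0.15)

    def test_too_few_events_raises(self, noise_free_sim):
        es = vep.extract_epochs(noise_free_sim.recording, noise_free_sim.events,
                                channels=["V1M_L"])
        with pytest.raises(TooFewEventsError):
            plasticity.rapid_index(es)


class TestSessionTimecourse:
    def test_monotone_rise_to_plateau(self):
        cfg = SimConfig(days=3, flashes_per_eye_per_session=50, sessions_per_day=3,
                        inter_session_gap_s=10.0,
                        channels=("V1M_L", "V1M_R", "EEG", "EMG"))
        sim = simulate(cfg, 21)
        es = visual_epochs(sim)
        tc = plasticity.session_timecourse(es, peak="N2")
        mags = tc["magnitude_uV"].to_numpy()
        rho = pd.Series(mags).corr(pd.Series(np.arange(mags.size)), method="spearman")
        assert rho > 0.6
        assert mags[-1] > mags[0]

    def test_persistence_across_days(self):
        """With persistent rapid potentiation, day-2 session 1 keeps >= 90%
        of the day-1 final-session amplitude."""
        cfg = SimConfig(days=2, flashes_per_eye_per_session=50, sessions_per_day=3,
                        inter_session_gap_s=10.0, background=quiet_background(),
                        channels=("V1M_L", "V1M_R", "EEG", "EMG"))
        sim = simulate(cfg, 22)
        tc = plasticity.session_timecourse(visual_epochs(sim), peak="N2")
        d1_last = tc[(tc["day"] == 1) & (tc["session"] == 3)]["magnitude_uV"].iloc[0]
        d2_first = tc[(tc["day"] == 2) & (tc["session"] == 1)]["magnitude_uV"].iloc[0]
        assert d2_first >= 0.9 * d1_last

    def test_flat_when_plasticity_off(self, ko_day1):
        tc = plasticity.session_timecourse(
            vep.extract_epochs(ko_day1.recording, ko_day1.events, channels=["V1M_L", "V1M_R"]),
            peak="N2",
        )
        mags = tc["magnitude_uV"].to_numpy()
        assert np.ptp(mags) < 0.1 * mags.mean()


class TestGainRecovery:
    def test_noise_free_recovery_exact(self, noise_free_wt_2day):
        """On noise-free data the linear fit recovers C and R almost exactly."""
        es = visual_epochs(noise_free_wt_2day)
        est = plasticity.estimate_cumulative_gain(es)
        assert est["C_hat"].mean() == pytest.approx(1.5, rel=0.05)
        assert est["R_hat"].mean() == pytest.approx(2.5, rel=0.05)


class TestGroupSummary:
    def test_all_unity_ratios(self):
        ratios = pd.DataFrame(
            {"channel": ["a", "b", "c"], "pathway": ["contra"] * 3, "ratio": [1.0, 1.0, 1.0]}
        )
        out = plasticity.group_summary(ratios, {"a": "m1", "b": "m1", "c": "m2"})
        row = out[out["pathway"] == "contra"].iloc[0]
        assert row["t"] == 0.0 and row["p"] == 1.0

    def test_three_mouse_toy_table(self):
        """Hand-computed pooling: site -> mouse mean -> across-mouse mean."""
        ratios = pd.DataFrame(
            {
                "channel": ["a1", "a2", "b1", "b2", "c1"],
                "pathway": ["contra"] * 5,
                "ratio": [1.2, 1.4, 1.6, 1.0, 1.5],
            }
        )
        mouse = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}
        out = plasticity.group_summary(ratios, mouse)
        row = out.iloc[0]
        # per-mouse means: A=1.3, B=1.3, C=1.5 -> mean 1.3666...
        assert row["mean"] == pytest.approx((1.3 + 1.3 + 1.5) / 3)
        assert row["n_mice"] == 3
        assert row["df"] == 2

    def test_unassigned_sites_dropped(self, caplog):
        ratios = pd.DataFrame(
            {"channel": ["a", "x"], "pathway": ["contra"] * 2, "ratio": [1.2, 9.9]}
        )
        out = plasticity.group_summary(ratios, {"a": "m1"})
        assert out.iloc[0]["n_mice"] == 1
        assert out.iloc[0]["mean"] == pytest.approx(1.2)
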