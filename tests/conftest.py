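
import pytest

from fvpkit.synth import BackgroundSpec, GainModel, SimConfig, simulate


def quiet_background(**overrides) -> BackgroundSpec:
    """Background with every stochastic element switched off."""
    base = dict(
        noise_sd_uV=0.0,
        state_oscillations={},
        sw_event_rate_base_per_min=0.0,
        sw_event_rate_slope_per_day=0.0,
        emg_sd_by_state={"wake": 0.0, "nrem": 0.0, "rem": 0.0},
    )
    base.update(overrides)
    return BackgroundSpec(**base)


@pytest.fixture(scope="session")
def noise_free_sim():
    """One noise-free day: epochs equal the rendered kernel exactly."""
    cfg = SimConfig(
        days=1,
        flashes_per_eye_per_session=10,
        sessions_per_day=1,
        inter_session_gap_s=5.0,
        background=quiet_background(),
        gain=GainModel(plasticity_scale=0.0),
        ipsi_scale=1.0,
        channels=("V1M_L", "V1M_R", "EEG", "EMG"),
    )
    return simulate(cfg, 0)


@pytest.fixture(scope="session")
def wt_sim():
    """Small wild-type experiment with default noise (2 days)."""
    cfg = SimConfig(
        days=2,
        flashes_per_eye_per_session=100,
        sessions_per_day=1,
        inter_session_gap_s=10.0,
    )
    return simulate(cfg, 7)
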