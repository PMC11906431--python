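"""End-to-end synthetic experiment: signals, events, spikes, hypnogram, truth.

`simulate` turns a :class:`SimConfig` into a multichannel recording with
every planted parameter recorded in a serializable :class:`GroundTruth`.
Each flash adds the gained VEP kernel to the visual channels (pathway set
by eye vs channel hemisphere, ipsilateral responses scaled down), a small
static non-potentiating response to ACC, and nothing to the somatosensory
EEG.  The background is 1/f noise plus state oscillations; the EMG channel
is white noise whose amplitude encodes wake / NREM / REM (atonia).  Spike
trains are inhomogeneous Poisson with rate coupled to the negative-going
kernel, so perievent histograms peak at the N1 and N2 latencies.

Identical (config, seed) pairs give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import InvalidParameterError, MissingChannelError, ScheduleCoverageError
from ..io import Channel, Hypnogram, Recording, VISUAL_REGIONS
from .background import BackgroundSpec, draw_sw_events, pink_noise, sw_event_waveform
from .gain import GainModel, apply_condition, compute_gain, get_condition
from .kernel import VepKernelSpec, component_basis, default_kernel
from .schedule import StimSchedule, make_schedule

DEFAULT_CHANNELS = (
    "V1M_L", "V1M_R", "V1L_L", "V1L_R", "V2LM_L", "V2LM_R", "ACC_L", "EEG", "EMG",
)


def pathway_for(eye: str, hemisphere: str) -> str:
    """Eye-of-origin vs recording hemisphere: opposite side is contra."""
    if eye == "both":
        return "binocular"
    if hemisphere not in ("L", "R"):
        raise InvalidParameterError(f"visual channel needs a hemisphere, got {hemisphere!r}")
    return "contra" if (eye == "left") == (hemisphere == "R") else "ipsi"


@dataclass
class StateBlock:
    start_s: float
    end_s: float
    state: str
    day: int  # 0 = pre-stimulation baseline


@dataclass
class SimConfig:
    """Everything needed to regenerate a synthetic experiment (plus a seed)."""

    protocol: str = "head_fixed_alternating"
    days: int = 4
    flashes_per_eye_per_session: int = 100
    sessions_per_day: int = 3
    inter_session_gap_s: float = 300.0
    start_s: float = 10.0
    flash_duration_ms: float = 10.0
    condition: str = "WT"
    kernel: VepKernelSpec = field(default_factory=default_kernel)
    gain: GainModel = field(default_factory=GainModel)
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    ipsi_scale: float = 0.7
    acc_response_scale: float = 0.2
    sleep_mode: str = "stim_only"  # or "with_sleep"
    baseline_sleep_s: float = 600.0
    nrem_s: float = 180.0
    rem_s: float = 60.0
    sleep_wake_s: float = 60.0
    extra_wake_s: float = 0.0
    spikes: bool = False
    units_per_v1_channel: int = 1
    spike_base_rate_hz: float = 5.0
    spike_evoked_rate_hz: float = 80.0
    sample_rate_hz: float = 1000.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel"]["components"] = [
            [c.name, c.latency_ms, c.width_ms, c.amplitude_uV] for c in self.kernel.components
        ]
        return _listify(d)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        from .kernel import KernelComponent

        d = dict(d)
        k = d.pop("kernel")
        kernel = VepKernelSpec(
            tuple(KernelComponent(*c) for c in k["components"]),
            k["sample_rate_hz"],
            k.get("duration_ms", 600.0),
        )
        g = dict(d.pop("gain"))
        g["potentiated_components"] = tuple(g["potentiated_components"])
        b = dict(d.pop("background"))
        b["state_oscillations"] = {
            s: (tuple(v[0]), v[1], v[2]) for s, v in b["state_oscillations"].items()
        }
        b["sw_freq_band"] = tuple(b["sw_freq_band"])
        b["sw_duration_s"] = tuple(b["sw_duration_s"])
        d["channels"] = tuple(d["channels"])
        return cls(kernel=kernel, gain=GainModel(**g), background=BackgroundSpec(**b), **d)


def _listify(obj):
    """Recursively turn tuples into lists (for YAML/JSON serialization)."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


@dataclass
class GroundTruth:
    """Planted parameters: sufficient to regenerate the experiment."""

    config: SimConfig
    seed: int
    day_edges: dict[int, tuple[float, float]]
    gain_end_of_day1_s: float
    sw_events: pd.DataFrame  # channel, start_s, end_s, freq_hz, amplitude_uV, day
    state_blocks: list[StateBlock]

    def to_json(self, path: str | Path) -> None:
        d = {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "day_edges": {str(k): list(v) for k, v in self.day_edges.items()},
            "gain_end_of_day1_s": self.gain_end_of_day1_s,
            "sw_events": self.sw_events.to_dict(orient="list"),
            "state_blocks": [asdict(b) for b in self.state_blocks],
        }
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            config=SimConfig.from_dict(d["config"]),
            seed=int(d["seed"]),
            day_edges={int(k): tuple(v) for k, v in d["day_edges"].items()},
            gain_end_of_day1_s=float(d["gain_end_of_day1_s"]),
            sw_events=pd.DataFrame(d["sw_events"]),
            state_blocks=[StateBlock(**b) for b in d["state_blocks"]],
        )


@dataclass
class SimResult:
    recording: Recording
    events: pd.DataFrame
    spikes: pd.DataFrame
    hypnogram: Hypnogram
    truth: GroundTruth


# ---------------------------------------------------------------------------
# State schedule
# ---------------------------------------------------------------------------

def make_state_schedule(sched: StimSchedule, cfg: SimConfig) -> list[StateBlock]:
    """Contiguous state blocks covering the whole recording span.

    Stimulation sessions sit inside wake blocks.  In ``with_sleep`` mode the
    gaps before the first session and between sessions are filled with
    NREM/REM/wake cycles; in ``stim_only`` mode they are waking throughout.
    """
    ev = sched.events
    sessions = (
        ev.groupby(["day", "session"])["onset_s"]
        .agg(["min", "max"])
        .reset_index()
        .sort_values("min")
    )
    blocks: list[StateBlock] = []
    cursor = 0.0
    prev_day = 0
    margin = 5.0
    for _, row in sessions.iterrows():
        t0 = max(float(row["min"]) - margin, cursor)
        t1 = float(row["max"]) + 2.0
        if t0 > cursor:
            blocks.extend(_fill(cursor, t0, prev_day, cfg))
        blocks.append(StateBlock(t0, t1, "wake", int(row["day"])))
        cursor = t1
        prev_day = int(row["day"])
    tail_end = cursor + max(cfg.extra_wake_s, margin)
    if cfg.sleep_mode == "with_sleep":
        if cfg.extra_wake_s > 0:
            blocks.append(StateBlock(cursor, cursor + cfg.extra_wake_s, "wake", prev_day))
            cursor += cfg.extra_wake_s
        blocks.extend(_fill(cursor, cursor + cfg.inter_session_gap_s, prev_day, cfg))
    else:
        blocks.append(StateBlock(cursor, tail_end, "wake", prev_day))
    return blocks


def _fill(t0: float, t1: float, day: int, cfg: SimConfig) -> list[StateBlock]:
    if cfg.sleep_mode != "with_sleep":
        return [StateBlock(t0, t1, "wake", day)]
    cycle = [("nrem", cfg.nrem_s), ("rem", cfg.rem_s), ("wake", cfg.sleep_wake_s)]
    out: list[StateBlock] = []
    t = t0
    i = 0
    while t < t1 - 1e-9:
        state, dur = cycle[i % 3]
        out.append(StateBlock(t, min(t + dur, t1), state, day))
        t += dur
        i += 1
    return out


def hypnogram_from_blocks(blocks: list[StateBlock], epoch_s: float = 4.0) -> Hypnogram:
    end = blocks[-1].end_s
    starts = np.arange(0.0, end - epoch_s + 1e-9, epoch_s)
    bs = np.array([b.start_s for b in blocks])
    states = [blocks[max(int(np.searchsorted(bs, s + epoch_s / 2, "right")) - 1, 0)].state
              for s in starts]
    return Hypnogram(pd.DataFrame({"start_s": starts, "state": states}), epoch_s)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate(config: SimConfig, seed: int) -> SimResult:
    """Generate a full synthetic experiment from a config and a seed."""
    sched = make_schedule(
        config.protocol,
        config.days,
        config.flashes_per_eye_per_session,
        config.sessions_per_day,
        config.inter_session_gap_s,
        start_s=(config.baseline_sleep_s if config.sleep_mode == "with_sleep" else config.start_s),
        flash_duration_ms=config.flash_duration_ms,
    )
    blocks = make_state_schedule(sched, config)
    return simulate_recording(
        sched,
        kernel=config.kernel,
        gain=config.gain,
        condition=config.condition,
        background=config.background,
        channels=config.channels,
        state_schedule=blocks,
        seed=seed,
        config=config,
    )


def simulate_recording(
    schedule: StimSchedule,
    *,
    kernel: VepKernelSpec,
    gain: GainModel,
    condition: str,
    background: BackgroundSpec,
    channels: tuple[str, ...],
    state_schedule: list[StateBlock],
    seed: int,
    config: SimConfig | None = None,
) -> SimResult:
    cfg = config or SimConfig(
        protocol=schedule.protocol,
        days=schedule.days,
        flashes_per_eye_per_session=schedule.flashes_per_eye_per_session,
        sessions_per_day=schedule.sessions_per_day,
        inter_session_gap_s=schedule.inter_session_gap_s,
        condition=condition,
        kernel=kernel,
        gain=gain,
        background=background,
        channels=tuple(channels),
    )
    fs = cfg.sample_rate_hz
    chans = [Channel.from_label(lab) for lab in channels]
    if not any(c.region in ("V1M", "V1L") and c.hemisphere == "L" for c in chans) or not any(
        c.region in ("V1M", "V1L") and c.hemisphere == "R" for c in chans
    ):
        raise MissingChannelError("need at least one V1 site per hemisphere")
    if not any(c.kind == "eeg" for c in chans):
        raise MissingChannelError("need an EEG channel")

    end_s = state_schedule[-1].end_s
    if schedule.end_s + kernel.duration_ms / 1000.0 > end_s + 1e-9:
        raise ScheduleCoverageError("state schedule does not cover the stimulation span")
    n = int(round(end_s * fs))
    rng = np.random.default_rng(seed)
    model = apply_condition(gain, get_condition(condition))
    gain_t0 = _end_of_day1(schedule)

    # --- background noise, per channel in channel order
    signals = np.empty((len(chans), n))
    for i, ch in enumerate(chans):
        sd = 2.0 if ch.kind == "emg" else background.noise_sd_uV
        signals[i] = pink_noise(n, sd, background.spectral_exponent, rng)

    # --- state oscillations and EMG tone, per block then per channel
    for b in state_schedule:
        i0, i1 = int(round(b.start_s * fs)), int(round(b.end_s * fs))
        if i1 <= i0:
            continue
        t = np.arange(i1 - i0) / fs
        osc = background.state_oscillations.get(b.state)
        if osc is not None:
            (_, f_hz, amp) = osc
            for i, ch in enumerate(chans):
                if ch.kind == "emg":
                    continue
                phase = rng.uniform(0, 2 * np.pi)
                a = amp
                if (
                    b.state == "nrem"
                    and ch.region in VISUAL_REGIONS
                    and b.start_s >= gain_t0 - 1e-9
                    and b.day >= 1
                ):
                    a = amp * np.sqrt(background.v1_delta_gain_post)
                signals[i, i0:i1] += a * np.sin(2 * np.pi * f_hz * t + phase)
        emg_sd = background.emg_sd_by_state.get(b.state, 10.0)
        for i, ch in enumerate(chans):
            if ch.kind == "emg":
                signals[i, i0:i1] += rng.normal(0.0, emg_sd, i1 - i0)

    # --- spontaneous spike-wave events on visual channels during waking
    sw_rows = []
    for i, ch in enumerate(chans):
        if ch.region not in VISUAL_REGIONS:
            continue
        for b in state_schedule:
            if b.state != "wake":
                continue
            for (s, dur, f_ev, amp) in draw_sw_events(
                rng, background, b.start_s, b.end_s - b.start_s, b.day
            ):
                w = sw_event_waveform(f_ev, dur, amp, fs)
                j0 = int(round(s * fs))
                signals[i, j0 : j0 + w.size] += w[: max(n - j0, 0)]
                sw_rows.append((ch.label, s, s + dur, f_ev, amp, b.day))
    sw_events = pd.DataFrame(
        sw_rows, columns=["channel", "start_s", "end_s", "freq_hz", "amplitude_uV", "day"]
    )

    # --- evoked responses
    basis = component_basis(kernel)  # (5, nk)
    amps = np.array([c.amplitude_uV for c in kernel.components])
    names = [c.name for c in kernel.components]
    nk = basis.shape[1]
    ev = schedule.events.copy()
    ev["sess_index"] = ev.groupby(["day", "session"]).cumcount()
    acc_wave = cfg.acc_response_scale * (amps @ basis)
    waves_by_event: dict[int, dict[str, np.ndarray]] = {}
    for row in ev.itertuples(index=False):
        i_eff = int(row.cum_index) if model.rapid_persist else int(row.sess_index)
        gains = {
            pw: np.array(
                [compute_gain(model, nm, int(row.day), i_eff, pw) for nm in names]
            )
            for pw in ("contra", "ipsi")
        }
        w_contra = (amps * gains["contra"]) @ basis
        w_ipsi = cfg.ipsi_scale * ((amps * gains["ipsi"]) @ basis)
        j0 = int(round(row.onset_s * fs))
        seg = slice(j0, j0 + nk)
        per_ch: dict[str, np.ndarray] = {}
        for i, ch in enumerate(chans):
            if ch.region in VISUAL_REGIONS:
                if row.eye == "both":
                    w = w_contra + w_ipsi
                else:
                    w = w_contra if pathway_for(row.eye, ch.hemisphere) == "contra" else w_ipsi
                signals[i, seg] += w[: n - j0]
                per_ch[ch.label] = w
            elif ch.region == "ACC" and cfg.acc_response_scale > 0:
                signals[i, seg] += acc_wave[: n - j0]
        if cfg.spikes:
            waves_by_event[int(row.cum_index)] = per_ch

    # --- spikes (inhomogeneous Poisson coupled to the negative-going kernel)
    spike_rows: list[tuple[str, float]] = []
    if cfg.spikes:
        norm = float(np.max(np.abs(amps[np.array([a < 0 for a in amps])])))
        dt = 1.0 / fs
        for ch in chans:
            if ch.region not in ("V1M", "V1L"):
                continue
            for u in range(cfg.units_per_v1_channel):
                uid = f"{ch.label}_u{u + 1}"
                n_bg = rng.poisson(cfg.spike_base_rate_hz * end_s)
                for t_sp in np.sort(rng.uniform(0.0, end_s, n_bg)):
                    spike_rows.append((uid, float(t_sp)))
                for row in ev.itertuples(index=False):
                    w = waves_by_event[int(row.cum_index)].get(ch.label)
                    if w is None:
                        continue
                    lam = cfg.spike_evoked_rate_hz * np.maximum(-w, 0.0) / norm * dt
                    counts = rng.poisson(lam)
                    hit = np.nonzero(counts)[0]
                    for j in hit:
                        for _ in range(int(counts[j])):
                            spike_rows.append(
                                (uid, float(row.onset_s + (j + rng.uniform()) * dt))
                            )
    spikes = pd.DataFrame(spike_rows, columns=["unit_id", "spike_time_s"]).sort_values(
        "spike_time_s", kind="stable"
    ).reset_index(drop=True)

    rec = Recording(signals, fs, chans, 0.0)
    hyp = hypnogram_from_blocks(state_schedule)
    truth = GroundTruth(
        config=cfg,
        seed=seed,
        day_edges=schedule.day_edges(),
        gain_end_of_day1_s=gain_t0,
        sw_events=sw_events,
        state_blocks=state_schedule,
    )
    return SimResult(rec, ev.copy(), spikes, hyp, truth)


def _end_of_day1(schedule: StimSchedule) -> float:
    d1 = schedule.events[schedule.events["day"] == 1]
    return float(d1["onset_s"].max()) + float(d1["duration_ms"].max()) / 1000.0
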