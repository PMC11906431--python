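"""Epoching, stimulus-triggered averaging, peaks, waveform area, PSTH.

Conventions: time 0 is flash onset; analysis windows are half-open
``[lo, hi)`` in ms post-onset; the baseline is the mean over the
``baseline_ms`` immediately preceding the stimulus; peak amplitudes are
baseline-referenced and signed (minimum for N components, maximum for P
components), with extremum ties broken by the earliest sample.  The
component windows follow the flash-VEP convention: N1 0–100, N2 100–300,
N3 300–500, P1 0–200, P2 200–400 ms, and the waveform-area metric is the
rectified area over 0–500 ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EmptySelectionError,
    InvalidParameterError,
    TooFewEventsError,
    WindowError,
)
from .io import Recording, VISUAL_REGIONS
from .synth.simulate import pathway_for

logger = logging.getLogger(__name__)

PEAK_WINDOWS: dict[str, tuple[float, float]] = {
    "N1": (0.0, 100.0),
    "P1": (0.0, 200.0),
    "N2": (100.0, 300.0),
    "P2": (200.0, 400.0),
    "N3": (300.0, 500.0),
}
AREA_WINDOW = (0.0, 500.0)
POLARITY = {"N1": -1, "P1": 1, "N2": -1, "P2": 1, "N3": -1}


@dataclass
class EpochSet:
    """Single-trial peri-stimulus traces with aligned metadata.

    ``traces`` is (n_epochs, n_samples); ``meta`` has one row per epoch
    with the event fields (event_id, onset_s, eye, day, session,
    trial_index, cum_index) and channel fields (channel, region,
    hemisphere, pathway).
    """

    traces: np.ndarray
    meta: pd.DataFrame
    pre_ms: float
    post_ms: float
    sample_rate_hz: float

    def __len__(self) -> int:
        return self.traces.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        n = self.traces.shape[1]
        return (np.arange(n) - self._pre_samples) / self.sample_rate_hz * 1000.0

    @property
    def _pre_samples(self) -> int:
        return int(round(self.pre_ms / 1000.0 * self.sample_rate_hz))

    def mask(self, **criteria) -> np.ndarray:
        m = np.ones(len(self), dtype=bool)
        for col, val in criteria.items():
            if col not in self.meta.columns:
                raise InvalidParameterError(f"unknown selection column {col!r}")
            vals = val if isinstance(val, (list, tuple, set, np.ndarray)) else [val]
            m &= self.meta[col].isin(list(vals)).to_numpy()
        return m

    def select(self, **criteria) -> "EpochSet":
        m = self.mask(**criteria)
        return EpochSet(
            self.traces[m], self.meta[m].reset_index(drop=True),
            self.pre_ms, self.post_ms, self.sample_rate_hz,
        )


@dataclass
class VepWaveform:
    """Stimulus-triggered average over a selection of epochs."""

    trace: np.ndarray
    n_events: int
    pre_ms: float
    sample_rate_hz: float
    selection: dict = field(default_factory=dict)


@dataclass
class PeakSet:
    """Windowed extrema (signed amplitude, latency) plus rectified area."""

    amplitudes_uV: dict[str, float]
    latencies_ms: dict[str, float]
    area_uV_ms: float
    baseline_uV: float


@dataclass
class Psth:
    edges_ms: np.ndarray
    counts: np.ndarray
    n_events: int


def extract_epochs(
    rec: Recording,
    events: pd.DataFrame,
    pre_ms: float = 100.0,
    post_ms: float = 600.0,
    channels: list[str] | None = None,
) -> EpochSet:
    """One epoch per (event, LFP channel); events clipped by the recording
    edge are dropped with a logged count."""
    if pre_ms < 0 or post_ms <= 0:
        raise WindowError("pre_ms must be >= 0 and post_ms > 0")
    fs = rec.sample_rate_hz
    if channels is None:
        chans = [c for c in rec.channels if c.kind == "lfp"]
    else:
        chans = [rec.channels[rec.channel_index(lab)] for lab in channels]
    npre = int(round(pre_ms / 1000.0 * fs))
    npost = int(round(post_ms / 1000.0 * fs))
    onset_samples = np.round(events["onset_s"].to_numpy(dtype=float) * fs).astype(int)
    ok = (onset_samples - npre >= 0) & (onset_samples + npost <= rec.n_samples)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d events too close to the recording edge", n_dropped)
    ev = events.reset_index(drop=True)
    ev_ok = ev[ok].reset_index(drop=True)
    if len(ev_ok) == 0:
        raise EmptySelectionError("no events fit inside the recording")
    offsets = np.arange(-npre, npost)
    idx = onset_samples[ok][:, None] + offsets[None, :]

    traces_list, meta_list = [], []
    event_id = (
        ev_ok["cum_index"].to_numpy()
        if "cum_index" in ev_ok.columns
        else np.arange(len(ev_ok))
    )
    for ch in chans:
        sig = rec.get(ch.label)
        traces_list.append(sig[idx])
        md = pd.DataFrame(
            {
                "event_id": event_id,
                "cum_index": event_id,
                "onset_s": ev_ok["onset_s"].to_numpy(dtype=float),
                "eye": ev_ok["eye"].to_numpy(),
                "day": ev_ok["day"].to_numpy(dtype=int),
                "session": ev_ok["session"].to_numpy(dtype=int),
                "trial_index": (
                    ev_ok["trial_index"].to_numpy(dtype=int)
                    if "trial_index" in ev_ok.columns
                    else np.arange(len(ev_ok))
                ),
                "channel": ch.label,
                "region": ch.region,
                "hemisphere": ch.hemisphere,
            }
        )
        md["pathway"] = [
            pathway_for(eye, ch.hemisphere) if ch.region in VISUAL_REGIONS else "none"
            for eye in md["eye"]
        ]
        meta_list.append(md)
    return EpochSet(
        np.concatenate(traces_list),
        pd.concat(meta_list, ignore_index=True),
        pre_ms,
        post_ms,
        fs,
    )


def triggered_average(epochs: EpochSet, selection: dict | None = None) -> VepWaveform:
    """Arithmetic per-sample mean over the selected epochs."""
    sub = epochs.select(**selection) if selection else epochs
    if len(sub) == 0:
        raise EmptySelectionError(f"selection {selection!r} matched no epochs")
    return VepWaveform(
        sub.traces.mean(axis=0), len(sub), sub.pre_ms, sub.sample_rate_hz, dict(selection or {})
    )


def _baseline(trace: np.ndarray, npre: int, nbase: int) -> float:
    if nbase == 0:
        return 0.0
    return float(trace[npre - nbase : npre].mean())


def detect_peaks(
    wf: VepWaveform,
    windows: dict[str, tuple[float, float]] | None = None,
    baseline_ms: float = 100.0,
) -> PeakSet:
    """Windowed extremum detection on a triggered average (or any trace)."""
    windows = windows or PEAK_WINDOWS
    fs = wf.sample_rate_hz
    npre = int(round(wf.pre_ms / 1000.0 * fs))
    nbase = int(round(baseline_ms / 1000.0 * fs))
    if nbase > npre:
        raise WindowError("baseline span exceeds the pre-stimulus span")
    base = _baseline(wf.trace, npre, nbase)
    post = wf.trace[npre:]
    amplitudes, latencies = {}, {}
    for name, (lo, hi) in windows.items():
        i0 = int(round(lo / 1000.0 * fs))
        i1 = int(round(hi / 1000.0 * fs))
        if i0 < 0 or i1 > post.size or i0 >= i1:
            raise WindowError(f"window {name}=[{lo},{hi}) outside the epoch span")
        seg = post[i0:i1] - base
        if POLARITY.get(name, -1) < 0:
            j = int(np.argmin(seg))
        else:
            j = int(np.argmax(seg))
        amplitudes[name] = float(seg[j])
        latencies[name] = (i0 + j) / fs * 1000.0
    area = waveform_area(wf, *AREA_WINDOW, baseline_ms=baseline_ms)
    return PeakSet(amplitudes, latencies, area, base)


def waveform_area(
    wf: VepWaveform,
    t_lo_ms: float = 0.0,
    t_hi_ms: float = 500.0,
    baseline_ms: float = 100.0,
) -> float:
    """Rectified area sum(|x - baseline|) * dt over [t_lo, t_hi) ms, in uV*ms."""
    if not (0 <= t_lo_ms < t_hi_ms):
        raise WindowError(f"inverted or negative area window [{t_lo_ms}, {t_hi_ms})")
    fs = wf.sample_rate_hz
    npre = int(round(wf.pre_ms / 1000.0 * fs))
    nbase = int(round(baseline_ms / 1000.0 * fs))
    base = _baseline(wf.trace, npre, nbase)
    post = wf.trace[npre:]
    i0 = int(round(t_lo_ms / 1000.0 * fs))
    i1 = int(round(t_hi_ms / 1000.0 * fs))
    if i1 > post.size:
        raise WindowError("area window extends past the epoch")
    dt_ms = 1000.0 / fs
    return float(np.abs(post[i0:i1] - base).sum() * dt_ms)


def epoch_areas(
    epochs: EpochSet,
    t_lo_ms: float = 0.0,
    t_hi_ms: float = 500.0,
    baseline_ms: float = 100.0,
) -> np.ndarray:
    """Vectorized single-epoch rectified areas (the single-trial workhorse)."""
    if not (0 <= t_lo_ms < t_hi_ms):
        raise WindowError(f"inverted or negative area window [{t_lo_ms}, {t_hi_ms})")
    fs = epochs.sample_rate_hz
    npre = epochs._pre_samples
    nbase = int(round(baseline_ms / 1000.0 * fs))
    base = (
        epochs.traces[:, npre - nbase : npre].mean(axis=1)
        if nbase
        else np.zeros(len(epochs))
    )
    i0 = npre + int(round(t_lo_ms / 1000.0 * fs))
    i1 = npre + int(round(t_hi_ms / 1000.0 * fs))
    if i1 > epochs.traces.shape[1]:
        raise WindowError("area window extends past the epoch")
    dt_ms = 1000.0 / fs
    return np.abs(epochs.traces[:, i0:i1] - base[:, None]).sum(axis=1) * dt_ms


def epoch_features(
    epochs: EpochSet,
    windows: dict[str, tuple[float, float]] | None = None,
    baseline_ms: float = 100.0,
) -> pd.DataFrame:
    """Per-epoch windowed extrema and area, vectorized (one row per epoch)."""
    windows = windows or PEAK_WINDOWS
    fs = epochs.sample_rate_hz
    npre = epochs._pre_samples
    nbase = int(round(baseline_ms / 1000.0 * fs))
    base = (
        epochs.traces[:, npre - nbase : npre].mean(axis=1)
        if nbase
        else np.zeros(len(epochs))
    )
    out = {}
    for name, (lo, hi) in windows.items():
        i0 = npre + int(round(lo / 1000.0 * fs))
        i1 = npre + int(round(hi / 1000.0 * fs))
        seg = epochs.traces[:, i0:i1] - base[:, None]
        out[name] = seg.min(axis=1) if POLARITY.get(name, -1) < 0 else seg.max(axis=1)
    out["area"] = epoch_areas(epochs, *AREA_WINDOW, baseline_ms=baseline_ms)
    return pd.DataFrame(out)


def psth(
    spikes: pd.DataFrame,
    events: pd.DataFrame,
    bin_ms: float = 10.0,
    span_ms: tuple[float, float] = (-100.0, 600.0),
    unit_ids: list[str] | None = None,
) -> Psth:
    """Perievent spike-count histogram pooled over events (and units)."""
    if bin_ms <= 0:
        raise InvalidParameterError("bin_ms must be positive")
    if len(events) == 0:
        raise TooFewEventsError("psth needs at least one event")
    sp = spikes if unit_ids is None else spikes[spikes["unit_id"].isin(unit_ids)]
    lo, hi = span_ms
    edges = np.arange(lo, hi + bin_ms / 2, bin_ms)
    counts = np.zeros(edges.size - 1)
    times = np.sort(sp["spike_time_s"].to_numpy(dtype=float))
    for onset in events["onset_s"].to_numpy(dtype=float):
        rel = (times[np.searchsorted(times, onset + lo / 1000.0):
                     np.searchsorted(times, onset + hi / 1000.0)] - onset) * 1000.0
        counts += np.histogram(rel, edges)[0]
    return Psth(edges, counts, len(events))
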