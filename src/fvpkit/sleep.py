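"""Sleep staging surrogate, band power, normalized delta, spike-wave events.

Staging rule (a stand-in for manual scoring): an epoch is *wake* when the
EMG RMS exceeds a threshold fitted to the bimodal EMG amplitude
distribution, otherwise *REM* when the EEG theta/delta power ratio exceeds
a threshold, otherwise *NREM*.  Band powers are Welch estimates (2 s Hann
segments, 50% overlap) integrated over the band.  The canonical bands are
delta 0.5–4, theta 6–10, beta 20–30, narrow gamma 40–60 and broad gamma
30–100 Hz; the 4–6 Hz gap between delta and theta is deliberate.

The normalized-delta time course divides V1 delta power by the concurrent
EEG delta power per bin, keeping only artifact-free NREM bins without
stimulation, which cancels global fluctuations and isolates the
V1-specific NREM slow-wave enhancement.  Spontaneous 3–6 Hz spike-wave
events are detected on the band-passed analytic envelope with a
mean + k*SD threshold and a minimum-cycles duration rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (
    InvalidParameterError,
    MissingChannelError,
    ScheduleCoverageError,
    WindowError,
)
from .io import Hypnogram, Recording

logger = logging.getLogger(__name__)

BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (6.0, 10.0),
    "beta": (20.0, 30.0),
    "gamma_narrow": (40.0, 60.0),
    "gamma_broad": (30.0, 100.0),
}


def _welch_band_power(
    x: np.ndarray, fs: float, band: tuple[float, float], nperseg: int
) -> float:
    """Welch PSD integrated over [band); total (not density) power in uV^2."""
    if x.size < nperseg:
        nperseg = x.size
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    m = (f >= band[0]) & (f < band[1])
    return float(np.trapezoid(p[m], f[m])) if m.sum() > 1 else float(p[m].sum() * (f[1] - f[0]))


def band_power(
    rec: Recording,
    channel: str,
    band: tuple[float, float] | str,
    epoch_s: float = 4.0,
    welch_seg_s: float = 2.0,
) -> pd.DataFrame:
    """Per-epoch band power for one channel (columns: start_s, power_uV2)."""
    if isinstance(band, str):
        band = BANDS[band]
    fs = rec.sample_rate_hz
    if band[1] > fs / 2:
        raise WindowError(f"band {band} exceeds Nyquist {fs / 2}")
    x = rec.get(channel)
    n_ep = int(x.size // (epoch_s * fs))
    nper = int(round(welch_seg_s * fs))
    rows = []
    for i in range(n_ep):
        seg = x[int(i * epoch_s * fs) : int((i + 1) * epoch_s * fs)]
        rows.append((i * epoch_s, _welch_band_power(seg, fs, band, nper)))
    return pd.DataFrame(rows, columns=["start_s", "power_uV2"])


def band_power_series(
    rec: Recording,
    channel: str,
    hypnogram: Hypnogram | None = None,
    bands: dict[str, tuple[float, float]] | None = None,
    epoch_s: float = 4.0,
) -> pd.DataFrame:
    """All canonical bands per epoch, with the epoch's state label attached."""
    bands = bands or BANDS
    out: pd.DataFrame | None = None
    for name, b in bands.items():
        df = band_power(rec, channel, b, epoch_s).rename(columns={"power_uV2": name})
        out = df if out is None else out.merge(df, on="start_s")
    if hypnogram is not None:
        out["state"] = [hypnogram.state_at(s + epoch_s / 2) for s in out["start_s"]]
    return out


def stage_sleep(
    rec: Recording,
    epoch_s: float = 4.0,
    emg_threshold_uV: float | None = None,
    theta_delta_threshold: float = 1.0,
    eeg_channel: str | None = None,
    emg_channel: str | None = None,
) -> Hypnogram:
    """Three-state staging from EEG band ratios and EMG tone.

    The EMG wake threshold defaults to the midpoint (in log RMS) between
    the two modes of the per-epoch EMG RMS distribution.
    """
    eeg = _find_channel(rec, eeg_channel, "eeg")
    emg = _find_channel(rec, emg_channel, "emg")
    fs = rec.sample_rate_hz
    x_emg = rec.get(emg)
    n_ep = int(x_emg.size // (epoch_s * fs))
    if n_ep == 0:
        raise InvalidParameterError("recording shorter than one epoch")
    emg_rms = np.array(
        [
            np.sqrt(np.mean(x_emg[int(i * epoch_s * fs) : int((i + 1) * epoch_s * fs)] ** 2))
            for i in range(n_ep)
        ]
    )
    if emg_threshold_uV is None:
        emg_threshold_uV = _bimodal_threshold(emg_rms)
    delta = band_power(rec, eeg, BANDS["delta"], epoch_s)["power_uV2"].to_numpy()
    theta = band_power(rec, eeg, BANDS["theta"], epoch_s)["power_uV2"].to_numpy()
    ratio = theta / np.maximum(delta, 1e-12)
    states = np.where(
        emg_rms > emg_threshold_uV, "wake", np.where(ratio > theta_delta_threshold, "rem", "nrem")
    )
    starts = np.arange(n_ep) * epoch_s
    return Hypnogram(pd.DataFrame({"start_s": starts, "state": states}), epoch_s)


def _find_channel(rec: Recording, label: str | None, kind: str) -> str:
    if label is not None:
        return label
    cands = rec.channels_of_kind(kind)
    if not cands:
        raise MissingChannelError(f"recording has no {kind} channel")
    return cands[0].label


def _bimodal_threshold(values: np.ndarray) -> float:
    """Midpoint between the two clusters of a bimodal positive distribution
    (2-means on the log scale, Lloyd iterations from the extremes)."""
    lv = np.log(np.maximum(values, 1e-12))
    c = np.array([lv.min(), lv.max()])
    for _ in range(50):
        assign = np.abs(lv[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([lv[assign == k].mean() if np.any(assign == k) else c[k] for k in (0, 1)])
        if np.allclose(new, c):
            break
        c = new
    return float(np.exp(c.mean()))


def normalized_delta_timecourse(
    rec: Recording,
    v1_channel: str,
    eeg_channel: str,
    hypnogram: Hypnogram,
    events: pd.DataFrame,
    bin_s: float = 60.0,
) -> pd.DataFrame:
    """Per-bin V1/EEG delta-power ratio restricted to stimulation-free NREM.

    A bin is kept only when every staging epoch it contains is NREM and no
    stimulus falls inside it; bins with zero EEG delta are excluded with a
    logged warning.  Columns: start_s, v1_delta, eeg_delta, norm_delta.
    """
    fs = rec.sample_rate_hz
    n_bins = int(rec.n_samples // (bin_s * fs))
    onsets = events["onset_s"].to_numpy(dtype=float) if len(events) else np.array([])
    ep = hypnogram.epochs
    ep_starts = ep["start_s"].to_numpy(dtype=float)
    ep_states = ep["state"].to_numpy()
    rows = []
    for i in range(n_bins):
        t0, t1 = i * bin_s, (i + 1) * bin_s
        m = (ep_starts >= t0 - 1e-9) & (ep_starts < t1 - 1e-9)
        if not m.any() or not np.all(ep_states[m] == "nrem"):
            continue
        if np.any((onsets >= t0) & (onsets < t1)):
            continue
        sl = slice(int(t0 * fs), int(t1 * fs))
        v1 = _welch_band_power(rec.get(v1_channel)[sl], fs, BANDS["delta"], int(2 * fs))
        eeg = _welch_band_power(rec.get(eeg_channel)[sl], fs, BANDS["delta"], int(2 * fs))
        if eeg <= 0:
            logger.warning("bin at %.0f s has zero EEG delta; excluded", t0)
            continue
        rows.append((t0, v1, eeg, v1 / eeg))
    return pd.DataFrame(rows, columns=["start_s", "v1_delta", "eeg_delta", "norm_delta"])


def state_band_contrast(
    rec: Recording,
    channel: str,
    band: tuple[float, float] | str,
    state: str,
    hypnogram: Hypnogram,
    events: pd.DataFrame,
    baseline_span: tuple[float, float],
    late_span: tuple[float, float],
) -> float:
    """Late-over-baseline ratio of mean band power in stimulation-free
    staging epochs of one behavioral state (the specificity control for
    the delta effect; epoch resolution avoids requiring long state bouts)."""
    if isinstance(band, str):
        band = BANDS[band]
    fs = rec.sample_rate_hz
    ep_len = hypnogram.epoch_length_s
    onsets = events["onset_s"].to_numpy(dtype=float) if len(events) else np.array([])
    ep = hypnogram.epochs
    x = rec.get(channel)

    starts = ep["start_s"].to_numpy(dtype=float)
    states = ep["state"].to_numpy()
    # transition epochs (neighbour in a different state) straddle state
    # boundaries and carry mixed power; they are excluded
    interior = np.ones(states.size, dtype=bool)
    interior[1:] &= states[1:] == states[:-1]
    interior[:-1] &= states[:-1] == states[1:]

    def mean_power(span: tuple[float, float]) -> float:
        vals = []
        for t0, st, ok in zip(starts, states, interior):
            t1 = t0 + ep_len
            if st != state or not ok or t0 < span[0] or t1 > span[1]:
                continue
            if np.any((onsets >= t0) & (onsets < t1)):
                continue
            vals.append(_welch_band_power(x[int(t0 * fs) : int(t1 * fs)], fs, band, int(2 * fs)))
        if not vals:
            raise ScheduleCoverageError(f"no clean {state} epochs in span {span}")
        return float(np.mean(vals))

    return mean_power(late_span) / mean_power(baseline_span)


@dataclass
class SwEvent:
    start_s: float
    end_s: float
    peak_frequency_hz: float
    peak_amplitude_uV: float
    channel: str


def detect_sw_events(
    rec: Recording,
    channel: str,
    hypnogram: Hypnogram | None = None,
    band: tuple[float, float] = (3.0, 6.0),
    threshold_sd: float = 3.0,
    min_cycles: float = 3.0,
    merge_gap_s: float = 0.2,
) -> pd.DataFrame:
    """Detect spontaneous 3–6 Hz spike-wave bursts during waking.

    The channel is band-passed (zero-phase 4th-order Butterworth), the
    analytic (Hilbert) envelope is thresholded at mean + ``threshold_sd``
    SD (pooled over the analyzed spans), supra-threshold stretches lasting
    at least ``min_cycles`` periods of the band center are kept, and events
    closer than ``merge_gap_s`` are merged.
    """
    fs = rec.sample_rate_hz
    x = rec.get(channel)
    spans = hypnogram.spans("wake") if hypnogram is not None else [(0.0, x.size / fs)]
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    warmup = int(2 * fs / band[0])
    center = 0.5 * (band[0] + band[1])
    min_dur = min_cycles / center

    pieces = []
    for (t0, t1) in spans:
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        if i1 - i0 < warmup:
            raise ScheduleCoverageError(
                f"wake span [{t0:.1f}, {t1:.1f}) s shorter than filter warm-up"
            )
        bp = sps.sosfiltfilt(sos, x[i0:i1])
        env = np.abs(sps.hilbert(bp))
        pieces.append((t0, bp, env))
    pooled = np.concatenate([e for _, _, e in pieces])
    thr = pooled.mean() + threshold_sd * pooled.std()

    rows = []
    for (t0, bp, env) in pieces:
        above = env > thr
        if not above.any():
            continue
        d = np.diff(above.astype(int))
        starts = list(np.nonzero(d == 1)[0] + 1)
        ends = list(np.nonzero(d == -1)[0] + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(above.size)
        merged: list[list[int]] = []
        for s, e in zip(starts, ends):
            if merged and (s - merged[-1][1]) / fs < merge_gap_s:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            if (e - s) / fs < min_dur:
                continue
            seg = bp[s:e]
            zc = np.nonzero(np.diff(np.signbit(seg)))[0].size
            freq = zc / 2.0 / ((e - s) / fs)
            freq = float(np.clip(freq, band[0], band[1]))
            rows.append(
                (t0 + s / fs, t0 + e / fs, freq, float(np.abs(seg).max()), channel)
            )
    return pd.DataFrame(
        rows, columns=["start_s", "end_s", "peak_frequency_hz", "peak_amplitude_uV", "channel"]
    )
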