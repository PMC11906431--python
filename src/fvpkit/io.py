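"""Recording data model and file I/O.

A :class:`Recording` is a channels x samples matrix of field potentials in
microvolt at a single sampling rate, with per-channel metadata (cortical
region, hemisphere, signal kind).  Channel identity is encoded in the label
with the grammar ``<REGION>_<HEMI>`` (e.g. ``V1L_R`` is the lateral binocular
V1 site in the right hemisphere); labels without a hemisphere suffix
(``EEG``, ``EMG``) map to hemisphere ``none``.

Supported containers:

* native HDF5 layout — ``/signals`` (channels x samples, float64),
  ``/channels`` metadata table, root attributes ``sample_rate_hz`` and
  ``start_time_s``.  Round trips are bit exact.
* EDF — 16-bit European Data Format.  Reading goes through
  :func:`mne.io.read_raw_edf`; writing uses a minimal EDF writer (there is
  no EDF export in the dependency set).  Round trips are exact to one
  16-bit quantization step of the per-channel physical range, and the
  signal is zero-padded to a whole number of 1 s records.

Event, hypnogram and spike tables are plain TSV.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidParameterError, MixedSampleRateError

logger = logging.getLogger(__name__)

REGIONS = ("V1M", "V1L", "V2LM", "ACC", "EEG", "EMG")
HEMISPHERES = ("L", "R", "none")
VISUAL_REGIONS = ("V1M", "V1L", "V2LM")
EYES = ("left", "right", "both")

_KIND_BY_REGION = {
    "V1M": "lfp",
    "V1L": "lfp",
    "V2LM": "lfp",
    "ACC": "lfp",
    "EEG": "eeg",
    "EMG": "emg",
}

EVENT_COLUMNS = ("onset_s", "eye", "duration_ms", "session", "day")


@dataclass(frozen=True)
class Channel:
    """One recorded channel: label plus decoded metadata."""

    label: str
    region: str
    hemisphere: str
    kind: str

    @classmethod
    def from_label(cls, label: str) -> "Channel":
        """Decode ``<REGION>_<HEMI>`` (hemisphere suffix optional)."""
        parts = label.split("_")
        if len(parts) >= 2 and parts[-1] in ("L", "R"):
            region, hemi = "_".join(parts[:-1]), parts[-1]
        else:
            region, hemi = label, "none"
        if region not in _KIND_BY_REGION:
            logger.warning("unknown channel label %r: kind defaults to lfp", label)
            return cls(label, region, hemi, "lfp")
        return cls(label, region, hemi, _KIND_BY_REGION[region])


@dataclass
class Recording:
    """Multichannel continuous recording in microvolt."""

    signals: np.ndarray  # (n_channels, n_samples), float
    sample_rate_hz: float
    channels: list[Channel]
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise InvalidParameterError("signals must be 2-D (channels x samples)")
        if self.signals.shape[0] != len(self.channels):
            raise InvalidParameterError(
                f"{self.signals.shape[0]} signal rows but {len(self.channels)} channels"
            )
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise InvalidParameterError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            from .errors import MissingChannelError

            raise MissingChannelError(f"no channel labelled {label!r}") from None

    def get(self, label: str) -> np.ndarray:
        return self.signals[self.channel_index(label)]

    def channels_of_kind(self, kind: str) -> list[Channel]:
        return [c for c in self.channels if c.kind == kind]

    def visual_channels(self) -> list[Channel]:
        return [c for c in self.channels if c.region in VISUAL_REGIONS]


@dataclass
class Hypnogram:
    """Per-epoch behavioral state sequence (wake / nrem / rem)."""

    epochs: pd.DataFrame  # columns: start_s, state
    epoch_length_s: float

    STATES = ("wake", "nrem", "rem")

    def __post_init__(self) -> None:
        df = self.epochs.reset_index(drop=True)
        bad = set(df["state"]) - set(self.STATES)
        if bad:
            raise InvalidParameterError(f"unknown states: {sorted(bad)}")
        starts = df["start_s"].to_numpy(dtype=float)
        if len(starts) > 1 and not np.allclose(np.diff(starts), self.epoch_length_s):
            raise InvalidParameterError("hypnogram epochs must be contiguous")
        self.epochs = df

    def state_at(self, t: float) -> str:
        starts = self.epochs["start_s"].to_numpy(dtype=float)
        i = int(np.searchsorted(starts, t, side="right")) - 1
        if i < 0 or t >= starts[-1] + self.epoch_length_s:
            raise InvalidParameterError(f"t={t} outside hypnogram span")
        return str(self.epochs["state"].iloc[i])

    def spans(self, state: str) -> list[tuple[float, float]]:
        """Merged (start_s, end_s) spans of a given state."""
        out: list[tuple[float, float]] = []
        for s, st in zip(self.epochs["start_s"], self.epochs["state"]):
            if st != state:
                continue
            if out and abs(out[-1][1] - s) < 1e-9:
                out[-1] = (out[-1][0], s + self.epoch_length_s)
            else:
                out.append((s, s + self.epoch_length_s))
        return out


# ---------------------------------------------------------------------------
# HDF5
# ---------------------------------------------------------------------------

def write_recording_hdf5(rec: Recording, path: str | Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=rec.signals)
        f.attrs["sample_rate_hz"] = float(rec.sample_rate_hz)
        f.attrs["start_time_s"] = float(rec.start_time_s)
        meta = f.create_group("channels")
        enc = lambda xs: np.array([x.encode() for x in xs])  # noqa: E731
        meta.create_dataset("label", data=enc([c.label for c in rec.channels]))
        meta.create_dataset("region", data=enc([c.region for c in rec.channels]))
        meta.create_dataset("hemisphere", data=enc([c.hemisphere for c in rec.channels]))
        meta.create_dataset("kind", data=enc([c.kind for c in rec.channels]))


def read_recording_hdf5(path: str | Path) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        signals = f["signals"][()]
        fs = float(f.attrs["sample_rate_hz"])
        t0 = float(f.attrs.get("start_time_s", 0.0))
        meta = f["channels"]
        chans = [
            Channel(lab.decode(), reg.decode(), hemi.decode(), kind.decode())
            for lab, reg, hemi, kind in zip(
                meta["label"][()], meta["region"][()], meta["hemisphere"][()], meta["kind"][()]
            )
        ]
    return Recording(signals, fs, chans, t0)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF field too long: {value!r} (> {width})")
    return b.ljust(width)


def write_recording_edf(rec: Recording, path: str | Path) -> None:
    """Write a minimal EDF file (16-bit, physical dimension microvolt).

    Record duration is 1 s, so the sampling rate must be an integer; the
    last record is zero-padded.  Header date/time are fixed so identical
    recordings serialize to identical bytes.
    """
    fs = rec.sample_rate_hz
    if abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))
    n_ch = len(rec.channels)
    n_rec = int(np.ceil(rec.n_samples / spr)) if rec.n_samples else 0

    phys_min, phys_max, scaled = [], [], []
    for row in rec.signals:
        amp = max(float(np.max(np.abs(row))) if row.size else 1.0, 1.0)
        lo, hi = -amp, amp
        phys_min.append(lo)
        phys_max.append(hi)
        padded = np.zeros(n_rec * spr)
        padded[: row.size] = row
        dig = np.round((padded - lo) / (hi - lo) * 65535.0 - 32768.0)
        scaled.append(np.clip(dig, -32768, 32767).astype("<i2"))

    header_bytes = 256 * (1 + n_ch)
    with open(path, "wb") as f:
        f.write(_edf_field("0", 8))
        f.write(_edf_field("X X X X", 80))
        f.write(_edf_field("Startdate 01-JAN-2000 X X X", 80))
        f.write(_edf_field("01.01.00", 8))
        f.write(_edf_field("00.00.00", 8))
        f.write(_edf_field(str(header_bytes), 8))
        f.write(_edf_field("", 44))
        f.write(_edf_field(str(n_rec), 8))
        f.write(_edf_field("1", 8))
        f.write(_edf_field(str(n_ch), 4))
        join = lambda w, vals: b"".join(_edf_field(v, w) for v in vals)  # noqa: E731
        f.write(join(16, [c.label for c in rec.channels]))
        f.write(join(80, [""] * n_ch))
        f.write(join(8, ["uV"] * n_ch))
        f.write(join(8, [f"{v:.6g}"[:8] for v in phys_min]))
        f.write(join(8, [f"{v:.6g}"[:8] for v in phys_max]))
        f.write(join(8, ["-32768"] * n_ch))
        f.write(join(8, ["32767"] * n_ch))
        f.write(join(80, [""] * n_ch))
        f.write(join(8, [str(spr)] * n_ch))
        f.write(join(32, [""] * n_ch))
        for r in range(n_rec):
            for ch in range(n_ch):
                f.write(scaled[ch][r * spr : (r + 1) * spr].tobytes())


def _edf_samples_per_record(path: str | Path) -> list[int]:
    """Read the per-signal samples-per-record fields from an EDF header."""
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        n_ch = int(head[252:256].decode("ascii").strip())
        sig = f.read(256 * n_ch)
    off = (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80) * n_ch
    return [
        int(sig[off + 8 * i : off + 8 * (i + 1)].decode("ascii").strip())
        for i in range(n_ch)
    ]


def read_recording_edf(path: str | Path) -> Recording:
    spr = _edf_samples_per_record(path)
    if len(set(spr)) > 1:
        raise MixedSampleRateError(
            f"{path}: channels carry different sampling rates {sorted(set(spr))}"
        )
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    signals = raw.get_data() * 1e6  # volt -> microvolt
    chans = [Channel.from_label(lab) for lab in raw.ch_names]
    return Recording(signals, float(raw.info["sfreq"]), chans, 0.0)


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        write_recording_hdf5(rec, path)
    elif fmt == "edf":
        write_recording_edf(rec, path)
    else:
        raise FormatError(f"unknown recording format {fmt!r}")


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        return read_recording_hdf5(path)
    if fmt == "edf":
        return read_recording_edf(path)
    raise FormatError(f"unknown recording format {fmt!r}")


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    return {"": "hdf5", ".h5": "hdf5", ".hdf5": "hdf5", ".edf": "edf"}.get(suffix, suffix.lstrip("."))


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_events(events: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise FormatError(f"event table missing columns {missing}")
    events.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a stimulus-event TSV; onsets are sorted, eye tokens validated."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: event table missing columns {missing}")
    if len(df) == 0:
        return df
    bad = set(df["eye"]) - set(EYES)
    if bad:
        raise FormatError(f"{path}: bad eye tokens {sorted(bad)} (expected {EYES})")
    onsets = df["onset_s"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) < 0):
        logger.warning("%s: onsets not sorted; sorting", path)
        df = df.sort_values("onset_s", kind="stable").reset_index(drop=True)
    return df


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    df = hyp.epochs.copy()
    df["epoch_length_s"] = hyp.epoch_length_s
    df.to_csv(path, sep="\t", index=False)


def read_hypnogram(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path, sep="\t")
    if "epoch_length_s" not in df.columns:
        raise FormatError(f"{path}: hypnogram TSV missing epoch_length_s column")
    epoch_s = float(df["epoch_length_s"].iloc[0])
    return Hypnogram(df[["start_s", "state"]].copy(), epoch_s)


def write_spikes(spikes: pd.DataFrame, path: str | Path) -> None:
    for c in ("unit_id", "spike_time_s"):
        if c not in spikes.columns:
            raise FormatError(f"spike table missing column {c!r}")
    spikes.to_csv(path, sep="\t", index=False)


def read_spikes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for c in ("unit_id", "spike_time_s"):
        if c not in df.columns:
            raise FormatError(f"{path}: spike table missing column {c!r}")
    return df
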