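"""Background activity: 1/f noise, state oscillations, spike-wave events.

The ongoing signal on every channel is Gaussian noise spectrally shaped as
1/f^alpha, plus state-dependent narrow-band oscillations: a slow (delta
band) oscillation in NREM sleep, a theta oscillation in REM sleep, and a
gamma oscillation in waking.  After the first stimulation day, the NREM
delta oscillation on visual-cortex channels is multiplied in power by
``v1_delta_gain_post`` while the somatosensory EEG channel stays flat —
the regional sleep signature the sleep analyses are built to detect.
Spontaneous 3–6 Hz spike-and-wave events are planted on visual channels
during waking at a rate that grows across stimulation days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import InvalidParameterError

# (band_hz, rendered_freq_hz, amplitude_uV) per state; rendered frequency
# sits inside the band so band-power recovery is exact for a sinusoid.
DEFAULT_OSCILLATIONS: dict[str, tuple[tuple[float, float], float, float]] = {
    "wake": ((40.0, 60.0), 50.0, 15.0),
    "nrem": ((0.5, 4.0), 2.25, 100.0),
    "rem": ((6.0, 10.0), 8.0, 40.0),
}

EMG_SD_BY_STATE = {"wake": 60.0, "nrem": 15.0, "rem": 4.0}


@dataclass
class BackgroundSpec:
    noise_sd_uV: float = 20.0
    spectral_exponent: float = 1.0
    state_oscillations: dict[str, tuple[tuple[float, float], float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OSCILLATIONS)
    )
    v1_delta_gain_post: float = 1.3
    sw_event_rate_base_per_min: float = 1.0
    sw_event_rate_slope_per_day: float = 0.5
    sw_amplitude_uV: float = 150.0
    sw_freq_band: tuple[float, float] = (3.5, 5.5)
    sw_duration_s: tuple[float, float] = (1.0, 2.0)
    emg_sd_by_state: dict[str, float] = field(default_factory=lambda: dict(EMG_SD_BY_STATE))

    def __post_init__(self) -> None:
        if self.noise_sd_uV < 0 or self.v1_delta_gain_post < 1:
            raise InvalidParameterError("noise SD must be >= 0 and delta gain >= 1")
        if self.sw_event_rate_base_per_min < 0 or self.sw_event_rate_slope_per_day < 0:
            raise InvalidParameterError("spike-wave rates must be >= 0")


def pink_noise(n: int, sd: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent amplitude spectrum and SD ``sd``."""
    if n == 0 or sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    if exponent == 0:
        return sd * white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n)
    s = x.std()
    return sd * x / s if s > 0 else x


def sw_event_waveform(
    freq_hz: float, duration_s: float, amplitude_uV: float, fs: float
) -> np.ndarray:
    """One spike-and-wave burst: fundamental plus a phase-shifted harmonic
    under a Tukey taper, giving the sharp-transient-plus-slow-wave shape."""
    from scipy.signal.windows import tukey

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    wave = np.sin(2 * np.pi * freq_hz * t) + 0.4 * np.sin(4 * np.pi * freq_hz * t - np.pi / 2)
    return amplitude_uV * wave * tukey(n, 0.3)


def draw_sw_events(
    rng: np.random.Generator,
    spec: BackgroundSpec,
    block_start_s: float,
    block_dur_s: float,
    day: int,
) -> list[tuple[float, float, float, float]]:
    """Draw (start_s, duration_s, freq_hz, amplitude_uV) events for one wake
    block, at the day-dependent rate, non-overlapping within the block."""
    rate = spec.sw_event_rate_base_per_min + spec.sw_event_rate_slope_per_day * max(day - 1, 0)
    lam = rate * block_dur_s / 60.0
    n = int(rng.poisson(lam))
    if n == 0:
        return []
    starts = np.sort(rng.uniform(0.0, block_dur_s, n))
    out: list[tuple[float, float, float, float]] = []
    t_free = 0.0
    for s in starts:
        dur = float(rng.uniform(*spec.sw_duration_s))
        freq = float(rng.uniform(*spec.sw_freq_band))
        amp = float(rng.uniform(0.8, 1.2)) * spec.sw_amplitude_uV
        if s < t_free or s + dur > block_dur_s:
            continue  # overlapping or truncated draws are dropped
        out.append((block_start_s + s, dur, freq, amp))
        t_free = s + dur + 0.5
    return out
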