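"""Stimulus-triggered averaging and windowed peak detection.

Simulates one noise-free day, averages the epochs and reads off the five
VEP components — the latencies land on the canonical 30/100/200/300/400
ms grid because that is what the kernel plants.
"""

from fvpkit import SimConfig, simulate, extract_epochs, triggered_average, detect_peaks
from fvpkit.synth import BackgroundSpec, GainModel

cfg = SimConfig(
    days=1, flashes_per_eye_per_session=20, sessions_per_day=1,
    inter_session_gap_s=5.0,
    background=BackgroundSpec(noise_sd_uV=0.0, state_oscillations={},
                              sw_event_rate_base_per_min=0.0,
                              sw_event_rate_slope_per_day=0.0),
    gain=GainModel(plasticity_scale=0.0),
    channels=("V1M_L", "V1M_R", "EEG", "EMG"),
)
sim = simulate(cfg, seed=2)
epochs = extract_epochs(sim.recording, sim.events, channels=["V1M_L"])
wf = triggered_average(epochs, {"pathway": "contra"})
peaks = detect_peaks(wf)

print(f"average of {wf.n_events} contralateral epochs on V1M_L")
for name in ("N1", "P1", "N2", "P2", "N3"):
    print(f"  {name}: {peaks.amplitudes_uV[name]:8.1f} uV at "
          f"{peaks.latencies_ms[name]:5.0f} ms")
print(f"  rectified area 0-500 ms: {peaks.area_uV_ms:.0f} uV*ms")
# Negative components report negative baseline-referenced amplitudes;
# with zero noise the values equal the planted kernel amplitudes within
# the <2% component-overlap bound.
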