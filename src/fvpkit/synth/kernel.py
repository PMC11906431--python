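"""The five-component flash-VEP kernel.

The stimulus-locked response is modelled as a sum of unit-peak Gaussians,
one per component, with the canonical latencies of the flash VEP in mouse
binocular V1: N1 ~30 ms, P1 ~100 ms, N2 ~200 ms, P2 ~300 ms, N3 ~400 ms,
the response decaying within ~600 ms.  Negative components carry negative
amplitudes.  Component widths are generator configuration, not biological
truth; the defaults are narrow enough that neighbouring Gaussians do not
shift each other's windowed extrema by more than one sample at 1 kHz (a
property the peak-recovery tests rely on).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidParameterError

COMPONENT_ORDER = ("N1", "P1", "N2", "P2", "N3")


@dataclass(frozen=True)
class KernelComponent:
    name: str
    latency_ms: float
    width_ms: float  # Gaussian sigma
    amplitude_uV: float


@dataclass
class VepKernelSpec:
    """Parameters of the five-Gaussian VEP kernel."""

    components: tuple[KernelComponent, ...]
    sample_rate_hz: float = 1000.0
    duration_ms: float = 600.0

    def __post_init__(self) -> None:
        names = tuple(c.name for c in self.components)
        if names != COMPONENT_ORDER:
            raise InvalidParameterError(f"components must be {COMPONENT_ORDER}, got {names}")
        lats = [c.latency_ms for c in self.components]
        if not all(np.isfinite(lats)) or sorted(lats) != lats or len(set(lats)) != 5:
            raise InvalidParameterError("latencies must be finite and strictly ordered N1<P1<N2<P2<N3")
        for c in self.components:
            if not (np.isfinite(c.width_ms) and c.width_ms > 0 and np.isfinite(c.amplitude_uV)):
                raise InvalidParameterError(f"non-finite or non-positive parameters in {c}")
            if c.name.startswith("N") and c.amplitude_uV > 0:
                raise InvalidParameterError(f"{c.name} must have negative amplitude")
            if c.name.startswith("P") and c.amplitude_uV < 0:
                raise InvalidParameterError(f"{c.name} must have positive amplitude")

    def by_name(self) -> dict[str, KernelComponent]:
        return {c.name: c for c in self.components}


def default_kernel(sample_rate_hz: float = 1000.0) -> VepKernelSpec:
    """Canonical kernel: latencies 30/100/200/300/400 ms."""
    params = [
        ("N1", 30.0, 8.0, -80.0),
        ("P1", 100.0, 22.0, 60.0),
        ("N2", 200.0, 30.0, -100.0),
        ("P2", 300.0, 30.0, 50.0),
        ("N3", 400.0, 30.0, -40.0),
    ]
    return VepKernelSpec(tuple(KernelComponent(*p) for p in params), sample_rate_hz)


def component_basis(spec: VepKernelSpec) -> np.ndarray:
    """(5, n_samples) matrix of unit-peak component Gaussians."""
    n = int(round(spec.duration_ms / 1000.0 * spec.sample_rate_hz))
    t_ms = np.arange(n) / spec.sample_rate_hz * 1000.0
    return np.stack(
        [np.exp(-0.5 * ((t_ms - c.latency_ms) / c.width_ms) ** 2) for c in spec.components]
    )


def render_kernel(
    spec: VepKernelSpec, gain_per_component: dict[str, float] | None = None
) -> np.ndarray:
    """Render the summed kernel in microvolt at the spec's sampling rate.

    ``gain_per_component`` maps component names to multiplicative gains
    (missing components default to 1); gains must be finite and >= 0.
    """
    gains = np.ones(len(spec.components))
    if gain_per_component:
        names = [c.name for c in spec.components]
        for k, v in gain_per_component.items():
            if k not in names:
                raise InvalidParameterError(f"unknown component {k!r}")
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"gain for {k} must be finite and >= 0, got {v}")
            gains[names.index(k)] = v
    amps = np.array([c.amplitude_uV for c in spec.components])
    return (gains * amps) @ component_basis(spec)
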