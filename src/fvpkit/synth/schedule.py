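"""Stimulus schedules for the flash-stimulation protocols.

Three protocols are supported:

* ``head_fixed_alternating`` — 10 ms flashes alternating between the two
  eyes at 1 s spacing (per-eye rate 0.5 Hz), 100 flashes per eye per
  session, three sessions per day.
* ``sequential_one_eye`` — one eye only (1 Hz) for the first half of the
  experiment days, then the other eye for the second half.
* ``freely_behaving`` — flashes from an overhead LED reach both eyes at
  once (eye label ``both``), 100 pulses per session at 1 Hz.

Events carry absolute onsets plus (day, session) labels, a within-day
presentation index ``trial_index`` and a whole-experiment presentation
index ``cum_index`` (the counter the persistent rapid-potentiation phase
runs on).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import InvalidParameterError, UnknownProtocolError

PROTOCOLS = ("head_fixed_alternating", "sequential_one_eye", "freely_behaving")


@dataclass
class StimSchedule:
    """Flash-event table plus the protocol parameters that generated it."""

    events: pd.DataFrame  # onset_s, eye, duration_ms, session, day, trial_index, cum_index
    protocol: str
    days: int
    flashes_per_eye_per_session: int
    sessions_per_day: int
    inter_session_gap_s: float
    start_s: float = 10.0
    flash_duration_ms: float = 10.0

    def __len__(self) -> int:
        return len(self.events)

    @property
    def end_s(self) -> float:
        if len(self.events) == 0:
            return self.start_s
        last = self.events["onset_s"].iloc[-1]
        return float(last) + self.events["duration_ms"].iloc[-1] / 1000.0

    def day_edges(self) -> dict[int, tuple[float, float]]:
        """Per day: (first onset, last onset + flash duration)."""
        out = {}
        for day, grp in self.events.groupby("day"):
            out[int(day)] = (
                float(grp["onset_s"].min()),
                float(grp["onset_s"].max()) + float(grp["duration_ms"].max()) / 1000.0,
            )
        return out


def make_schedule(
    protocol: str,
    days: int,
    flashes_per_eye_per_session: int = 100,
    sessions_per_day: int = 3,
    inter_session_gap_s: float = 300.0,
    *,
    start_s: float = 10.0,
    flash_duration_ms: float = 10.0,
) -> StimSchedule:
    """Build a stimulus schedule for one of the supported protocols."""
    if protocol not in PROTOCOLS:
        raise UnknownProtocolError(f"unknown protocol {protocol!r}; expected one of {PROTOCOLS}")
    if days < 1 or flashes_per_eye_per_session < 1 or sessions_per_day < 1:
        raise InvalidParameterError("days and per-session counts must be >= 1")
    if inter_session_gap_s < 0 or start_s < 0:
        raise InvalidParameterError("gaps and start time must be non-negative")

    nf = flashes_per_eye_per_session
    rows: list[tuple] = []
    first_half_days = (days + 1) // 2

    if protocol == "head_fixed_alternating":
        session_len = 2 * nf  # 1 s per flash, eyes interleaved
    else:
        session_len = nf
    day_len = sessions_per_day * session_len + sessions_per_day * inter_session_gap_s

    for day in range(1, days + 1):
        trial = 0
        for sess in range(1, sessions_per_day + 1):
            t0 = start_s + (day - 1) * day_len + (sess - 1) * (session_len + inter_session_gap_s)
            if protocol == "head_fixed_alternating":
                for j in range(2 * nf):
                    eye = "left" if j % 2 == 0 else "right"
                    rows.append((t0 + j, eye, flash_duration_ms, sess, day, trial))
                    trial += 1
            elif protocol == "sequential_one_eye":
                eye = "right" if day <= first_half_days else "left"
                for j in range(nf):
                    rows.append((t0 + j, eye, flash_duration_ms, sess, day, trial))
                    trial += 1
            else:  # freely_behaving
                for j in range(nf):
                    rows.append((t0 + j, "both", flash_duration_ms, sess, day, trial))
                    trial += 1

    df = pd.DataFrame(
        rows, columns=["onset_s", "eye", "duration_ms", "session", "day", "trial_index"]
    )
    df["cum_index"] = np.arange(len(df))
    return StimSchedule(
        df,
        protocol,
        days,
        flashes_per_eye_per_session,
        sessions_per_day,
        inter_session_gap_s,
        start_s=start_s,
        flash_duration_ms=flash_duration_ms,
    )


def validate_schedule(sched: StimSchedule) -> None:
    """Check the structural invariants of a schedule; raise on violation."""
    ev = sched.events
    onsets = ev["onset_s"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise InvalidParameterError("onsets must be strictly increasing")
    if sched.protocol == "head_fixed_alternating":
        eyes = ev["eye"].to_numpy()
        for day, grp in ev.groupby("day"):
            g = grp.sort_values("onset_s")
            for sess, s in g.groupby("session"):
                e = s["eye"].to_numpy()
                if np.any(e[1:] == e[:-1]):
                    raise InvalidParameterError("consecutive events must alternate eyes")
                dt = np.diff(s["onset_s"].to_numpy(dtype=float))
                if not np.allclose(dt, 1.0):
                    raise InvalidParameterError("alternating flashes must be 1 s apart")
        counts = ev.groupby(["day", "session", "eye"]).size()
        if not (counts == sched.flashes_per_eye_per_session).all():
            raise InvalidParameterError("per-(day, session, eye) flash count mismatch")
        del eyes
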