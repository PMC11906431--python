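"""Two-phase plasticity quantification.

Cumulative (across-day) potentiation is the ratio of the late-day to the
day-1 baseline-referenced peak magnitude, per recording site and eye
pathway, computed from each day's full stimulus-triggered average.  Rapid
(within-day) potentiation is the ratio of the mean single-trial rectified
waveform area over stimulations 190–200 vs 0–10 on day 1, both eyes pooled
in presentation order.  A model-based estimator recovers the underlying
cumulative gain ceiling from the per-session amplitude time course: the
session mean amplitude is linear in the saturation terms of the two-phase
gain model, so the ceiling falls out of an ordinary least-squares fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptySelectionError, TooFewEventsError
from .vep import AREA_WINDOW, EpochSet, detect_peaks, epoch_areas, triggered_average

logger = logging.getLogger(__name__)


def peaks_by_day(
    epochs: EpochSet,
    windows: dict | None = None,
    baseline_ms: float = 100.0,
    group_cols: tuple[str, ...] = ("channel", "pathway", "day"),
) -> pd.DataFrame:
    """Windowed peak amplitudes/latencies of the triggered average per group."""
    rows = []
    for key, grp in epochs.meta.groupby(list(group_cols)):
        sub = EpochSet(
            epochs.traces[grp.index.to_numpy()], grp.reset_index(drop=True),
            epochs.pre_ms, epochs.post_ms, epochs.sample_rate_hz,
        )
        wf = triggered_average(sub)
        ps = detect_peaks(wf, windows, baseline_ms)
        for comp, amp in ps.amplitudes_uV.items():
            rows.append(
                (*key, comp, amp, ps.latencies_ms[comp], ps.area_uV_ms, len(sub))
            )
    return pd.DataFrame(
        rows,
        columns=[*group_cols, "component", "amplitude_uV", "latency_ms", "area_uV_ms", "n_events"],
    )


def day_ratio(
    epochs: EpochSet,
    peak: str = "N2",
    early_day: int = 1,
    late_day: int | None = None,
    min_day1_uV: float = 1.0,
    windows: dict | None = None,
    baseline_ms: float = 100.0,
) -> pd.DataFrame:
    """Late-day over day-1 peak-magnitude ratio per (channel, pathway).

    Sites whose day-1 magnitude falls below ``min_day1_uV`` are flagged and
    excluded from the returned ratios (``ratio`` = NaN, ``flagged`` True).
    """
    days = sorted(epochs.meta["day"].unique())
    if late_day is None:
        late_day = days[-1]
    for d in (early_day, late_day):
        if d not in days:
            raise EmptySelectionError(f"day {d} has no epochs")
    table = peaks_by_day(
        epochs.select(day=[early_day, late_day]), windows, baseline_ms
    )
    table = table[table["component"] == peak]
    piv = table.pivot_table(
        index=["channel", "pathway"], columns="day", values="amplitude_uV"
    )
    rows = []
    for (ch, pw), r in piv.iterrows():
        early, late = abs(r[early_day]), abs(r[late_day])
        flagged = early < min_day1_uV
        if flagged:
            logger.warning("site %s/%s day-%d magnitude %.2f uV below floor; excluded",
                           ch, pw, early_day, early)
        rows.append((ch, pw, np.nan if flagged else late / early, early, late, flagged))
    return pd.DataFrame(
        rows, columns=["channel", "pathway", "ratio", "early_uV", "late_uV", "flagged"]
    )


@dataclass
class RapidIndex:
    init_area_uV_ms: float
    late_area_uV_ms: float
    index: float


def rapid_index(
    epochs: EpochSet,
    init_range: tuple[int, int] = (0, 10),
    late_range: tuple[int, int] = (190, 200),
    area_window: tuple[float, float] = AREA_WINDOW,
    baseline_ms: float = 100.0,
    day: int = 1,
) -> tuple[pd.DataFrame, RapidIndex]:
    """Rapid-potentiation index from day-1 single-trial areas.

    Both eyes are pooled in presentation order (``trial_index``); the index
    is the mean single-epoch area over ``late_range`` divided by the mean
    over ``init_range``.  Returns the per-channel table and the pooled index.
    """
    d1 = epochs.select(day=day)
    rows = []
    for ch, grp in d1.meta.groupby("channel"):
        order = grp["trial_index"].to_numpy()
        if order.max() + 1 < late_range[1]:
            raise TooFewEventsError(
                f"channel {ch}: day-{day} has {order.max() + 1} stimulations; "
                f"need >= {late_range[1]}"
            )
        sub = EpochSet(
            d1.traces[grp.index.to_numpy()], grp.reset_index(drop=True),
            d1.pre_ms, d1.post_ms, d1.sample_rate_hz,
        )
        areas = epoch_areas(sub, *area_window, baseline_ms=baseline_ms)
        ti = sub.meta["trial_index"].to_numpy()
        init = areas[(ti >= init_range[0]) & (ti < init_range[1])].mean()
        late = areas[(ti >= late_range[0]) & (ti < late_range[1])].mean()
        rows.append((ch, init, late, late / init))
    table = pd.DataFrame(rows, columns=["channel", "init_area", "late_area", "index"])
    pooled = RapidIndex(
        float(table["init_area"].mean()),
        float(table["late_area"].mean()),
        float(table["late_area"].mean() / table["init_area"].mean()),
    )
    return table, pooled


def session_timecourse(
    epochs: EpochSet,
    peak: str = "N2",
    pathway: str | None = "contra",
    windows: dict | None = None,
    baseline_ms: float = 100.0,
) -> pd.DataFrame:
    """Per-(day, session) triggered-average peak magnitude, in order."""
    sel = epochs if pathway is None else epochs.select(pathway=pathway)
    table = peaks_by_day(sel, windows, baseline_ms, group_cols=("channel", "day", "session"))
    table = table[table["component"] == peak].copy()
    table["magnitude_uV"] = table["amplitude_uV"].abs()
    out = (
        table.groupby(["day", "session"])["magnitude_uV"]
        .mean()
        .reset_index()
        .sort_values(["day", "session"])
        .reset_index(drop=True)
    )
    return out


def estimate_cumulative_gain(
    epochs: EpochSet,
    peak: str = "N2",
    pathway: str = "contra",
    tau_days: float = 1.5,
    tau_trials: float = 20.0,
    rapid_persist: bool = True,
    windows: dict | None = None,
    baseline_ms: float = 100.0,
    block_trials: int = 50,
) -> pd.DataFrame:
    """Recover the cumulative gain ceiling (and rapid ceiling) per channel.

    The block-mean amplitude of a potentiated peak is
    ``A * (1 + (C-1) u_d + (R-1) v_b)`` with ``u_d`` the cumulative and
    ``v_b`` the block-mean rapid saturation term, both known given the two
    time constants — so (A, C, R) come from linear least squares on
    block-average amplitudes.  Blocks of ``block_trials`` presentations
    (pooled-eye count) resolve the rapid rise within day 1, which is what
    identifies R and decorrelates it from the across-day term.
    """
    sel = epochs.select(pathway=pathway)
    meta = sel.meta.copy()
    idx_col = "cum_index" if rapid_persist and "cum_index" in meta else "trial_index"
    meta["block"] = meta[idx_col] // block_trials
    rows = []
    for ch, grp in meta.groupby("channel"):
        y, u, v, w = [], [], [], []
        for (_, _), g in grp.groupby(["day", "block"]):
            wf = triggered_average(
                EpochSet(sel.traces[g.index.to_numpy()], g.reset_index(drop=True),
                         sel.pre_ms, sel.post_ms, sel.sample_rate_hz)
            )
            ps = detect_peaks(wf, windows, baseline_ms)
            y.append(abs(ps.amplitudes_uV[peak]))
            u.append(1.0 - math.exp(-(int(g["day"].iloc[0]) - 1) / tau_days))
            v.append(float(np.mean(1.0 - np.exp(-g[idx_col].to_numpy(dtype=float) / tau_trials))))
            w.append(len(g))
        sw = np.sqrt(np.asarray(w, dtype=float))
        X = np.column_stack([np.ones(len(y)), u, v]) * sw[:, None]
        beta, *_ = np.linalg.lstsq(X, np.asarray(y) * sw, rcond=None)
        rows.append((ch, 1.0 + beta[1] / beta[0], 1.0 + beta[2] / beta[0], beta[0]))
    return pd.DataFrame(rows, columns=["channel", "C_hat", "R_hat", "A_hat"])


def group_summary(
    ratios: pd.DataFrame, mouse_of_channel: dict[str, str]
) -> pd.DataFrame:
    """Pool per-site ratios to per-mouse means, then across mice per pathway.

    Within each mouse the ipsilateral site ratios are averaged, as are the
    contralateral ones; the across-mouse mean +/- SE and a one-sample t
    test against 1 (no change) are reported per pathway.
    """
    df = ratios.dropna(subset=["ratio"]).copy()
    df["mouse"] = df["channel"].map(mouse_of_channel)
    dropped = df["mouse"].isna()
    if dropped.any():
        logger.warning("dropping %d sites with no mouse assignment", int(dropped.sum()))
        df = df[~dropped]
    per_mouse = df.groupby(["mouse", "pathway"])["ratio"].mean().reset_index()
    rows = []
    for pw, grp in per_mouse.groupby("pathway"):
        vals = grp["ratio"].to_numpy(dtype=float)
        n = vals.size
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        if n > 1 and np.ptp(vals) > 0:
            t, p = stats.ttest_1samp(vals, 1.0)
        elif n > 1:  # zero variance: t is 0 when mean == 1
            t, p = (0.0, 1.0) if mean == 1.0 else (np.inf, 0.0)
        else:
            t, p = np.nan, np.nan
        rows.append((pw, n, mean, se, float(t), n - 1, float(p), "one-sample t vs 1"))
    return pd.DataFrame(
        rows, columns=["pathway", "n_mice", "mean", "se", "t", "df", "p", "method"]
    )
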