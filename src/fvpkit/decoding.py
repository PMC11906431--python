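"""Single-trial eye-of-origin decoding with a repeated-split linear SVM.

For every stimulation event, windowed peak amplitudes (N1/N2/N3 minima,
P1/P2 maxima) and the 0–500 ms rectified area are extracted per electrode
and stacked into a feature matrix.  Decoding accuracy is estimated with a
repeated random-split protocol: on each of 1000 repetitions a uniform
75% of events trains a linear maximum-margin classifier (features
standardized by the training-set mean/SD) and the held-out 25% is scored;
the reported accuracy is the mean over repetitions.  Chance level is 50%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVC

from .errors import (
    InvalidParameterError,
    MissingEpochError,
    SingleClassError,
    WindowError,
)
from .vep import AREA_WINDOW, EpochSet, PEAK_WINDOWS, epoch_features

DEFAULT_FEATURES = ("N1", "P1", "N2", "P2", "N3", "area")


@dataclass
class FeatureMatrix:
    """Rows = single stimulation events; columns = (electrode, feature)."""

    X: np.ndarray
    y: np.ndarray  # eye label per event
    columns: list[tuple[str, str]]
    event_ids: np.ndarray

    def subset(self, electrodes: list[str]) -> "FeatureMatrix":
        known = {e for e, _ in self.columns}
        unknown = set(electrodes) - known
        if unknown:
            raise InvalidParameterError(f"unknown electrodes {sorted(unknown)}")
        cols = [i for i, (e, _) in enumerate(self.columns) if e in electrodes]
        return FeatureMatrix(
            self.X[:, cols], self.y, [self.columns[i] for i in cols], self.event_ids
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.X, columns=pd.MultiIndex.from_tuples(self.columns, names=["electrode", "feature"])
        )
        df.insert(0, ("label", "eye"), self.y)
        return df


@dataclass
class DecodeResult:
    mean_accuracy: float
    accuracies: np.ndarray


def build_features(
    epochs: EpochSet,
    electrodes: list[str] | None = None,
    features: tuple[str, ...] = DEFAULT_FEATURES,
    windows: dict[str, tuple[float, float]] | None = None,
    area_window: tuple[float, float] = AREA_WINDOW,
    baseline_ms: float = 100.0,
) -> FeatureMatrix:
    """Per-event windowed extrema/areas across electrodes, aligned by event."""
    windows = dict(windows or PEAK_WINDOWS)
    if electrodes is None:
        electrodes = sorted(epochs.meta["channel"].unique())
    ref_ids: np.ndarray | None = None
    cols: list[tuple[str, str]] = []
    mats: list[np.ndarray] = []
    labels: np.ndarray | None = None
    peak_feats = [f for f in features if f != "area"]
    for el in electrodes:
        sub = epochs.select(channel=el)
        if len(sub) == 0:
            raise MissingEpochError(f"no epochs on electrode {el!r}")
        order = np.argsort(sub.meta["event_id"].to_numpy(), kind="stable")
        sub = EpochSet(
            sub.traces[order], sub.meta.iloc[order].reset_index(drop=True),
            sub.pre_ms, sub.post_ms, sub.sample_rate_hz,
        )
        ids = sub.meta["event_id"].to_numpy()
        if ref_ids is None:
            ref_ids = ids
            labels = sub.meta["eye"].to_numpy()
        elif not np.array_equal(ids, ref_ids):
            missing = sorted(set(ref_ids) ^ set(ids))
            raise MissingEpochError(
                f"electrode {el!r} epochs do not align with events {missing[:10]}"
            )
        fw = {k: windows[k] for k in peak_feats}
        feats = epoch_features(sub, fw, baseline_ms) if fw else pd.DataFrame(index=range(len(sub)))
        block = []
        for f in features:
            if f == "area":
                from .vep import epoch_areas

                block.append(epoch_areas(sub, *area_window, baseline_ms=baseline_ms))
            else:
                block.append(feats[f].to_numpy())
            cols.append((el, f))
        mats.append(np.column_stack(block))
    X = np.concatenate(mats, axis=1)
    if not np.all(np.isfinite(X)):
        raise InvalidParameterError("non-finite feature values")
    return FeatureMatrix(X, labels, cols, ref_ids)


def decode_accuracy(
    fm: FeatureMatrix,
    train_frac: float = 0.75,
    reps: int = 1000,
    seed: int = 0,
    C: float = 1.0,
) -> DecodeResult:
    """Repeated-random-split linear-SVM accuracy (mean over repetitions)."""
    classes = np.unique(fm.y)
    if classes.size < 2:
        raise SingleClassError(f"need >= 2 label classes, got {classes}")
    n = fm.X.shape[0]
    if n < 8:
        raise InvalidParameterError("need at least 8 events to split")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_frac * n))
    accs = np.empty(reps)
    y = (fm.y == classes[-1]).astype(int)
    X = fm.X
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for r in range(reps):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if np.unique(y[tr]).size < 2:  # degenerate split; rare at these sizes
                accs[r] = np.mean(y[te] == y[tr][0])
                continue
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            clf = LinearSVC(C=C)
            clf.fit((X[tr] - mu) / sd, y[tr])
            accs[r] = clf.score((X[te] - mu) / sd, y[te])
    return DecodeResult(float(accs.mean()), accs)


def electrode_scan(
    fm: FeatureMatrix,
    combos: list[list[str]],
    **decode_kwargs,
) -> pd.DataFrame:
    """Mean accuracy per electrode subset (same split sequence per combo)."""
    if not combos:
        raise InvalidParameterError("combos must be non-empty")
    rows = []
    for combo in combos:
        if not combo:
            raise InvalidParameterError("empty electrode combo")
        res = decode_accuracy(fm.subset(list(combo)), **decode_kwargs)
        rows.append(("+".join(combo), len(combo), res.mean_accuracy))
    return pd.DataFrame(rows, columns=["combo", "n_electrodes", "mean_accuracy"])


def all_single_and_full(electrodes: list[str]) -> list[list[str]]:
    return [[e] for e in electrodes] + [list(electrodes)]


def window_scan(
    epochs: EpochSet,
    electrodes: list[str] | None = None,
    step_ms: float = 50.0,
    span_ms: tuple[float, float] = (0.0, 500.0),
    mode: str = "anchored",
    baseline_ms: float = 100.0,
    **decode_kwargs,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Decoding accuracy from area features over a grid of time windows.

    ``anchored`` scans windows [0, b); ``all_pairs`` scans every [a, b) with
    a < b on the grid.  Returns the accuracy table and the argmax window.
    """
    lo, hi = span_ms
    if hi <= lo:
        raise WindowError(f"degenerate span {span_ms}")
    n_steps = (hi - lo) / step_ms
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise WindowError(f"step {step_ms} must divide span {span_ms}")
    grid = [lo + k * step_ms for k in range(int(round(n_steps)) + 1)]
    if mode == "anchored":
        wins = [(grid[0], b) for b in grid[1:]]
    elif mode == "all_pairs":
        wins = [(a, b) for a, b in combinations(grid, 2)]
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    rows = []
    for (a, b) in wins:
        fm = build_features(
            epochs, electrodes, features=("area",), area_window=(a, b), baseline_ms=baseline_ms
        )
        res = decode_accuracy(fm, **decode_kwargs)
        rows.append((a, b, res.mean_accuracy))
    table = pd.DataFrame(rows, columns=["t_lo_ms", "t_hi_ms", "mean_accuracy"])
    best = table.iloc[int(table["mean_accuracy"].idxmax())]
    return table, (float(best["t_lo_ms"]), float(best["t_hi_ms"]))
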