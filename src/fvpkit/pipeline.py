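"""End-to-end orchestration: simulate -> analyze -> report.

A :class:`PipelineConfig` (YAML-serializable) plus a seed fully determines
a run: the same pair reproduces byte-identical manifests.  ``run_experiment``
writes the recording, event/hypnogram/spike tables, per-day peak tables,
plasticity report, optional decoding and sleep tables, and a JSON manifest
of headline numbers stamped with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import plasticity, sleep as sleepmod, vep
from .decoding import build_features, decode_accuracy, window_scan
from .errors import ConfigMismatchError, FvpError
from .io import write_events, write_hypnogram, write_recording_hdf5, write_spikes
from .synth import SimConfig, simulate

logger = logging.getLogger(__name__)

DEFAULT_ANALYSIS = {
    "pre_ms": 100.0,
    "post_ms": 600.0,
    "baseline_ms": 100.0,
    "peaks": ["N1", "P1", "N2", "P2", "N3"],
    "late_day": None,  # default: last day
}
DEFAULT_DECODING = {
    "enabled": False,
    "day": None,  # default: last day
    "reps": 1000,
    "train_frac": 0.75,
    "window_scan": False,
    "window_step_ms": 50.0,
}
DEFAULT_SLEEP = {
    "enabled": False,
    "bin_s": 60.0,
    "epoch_s": 4.0,
}


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    analysis: dict = field(default_factory=lambda: dict(DEFAULT_ANALYSIS))
    decoding: dict = field(default_factory=lambda: dict(DEFAULT_DECODING))
    sleep: dict = field(default_factory=lambda: dict(DEFAULT_SLEEP))
    out_dir: str = "fvp_run"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "sim": self.sim.to_dict(),
            "analysis": self.analysis,
            "decoding": self.decoding,
            "sleep": self.sleep,
            "out_dir": self.out_dir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim = _sim_from_partial(d.get("sim", {}))
        analysis = {**DEFAULT_ANALYSIS, **d.get("analysis", {})}
        decoding = {**DEFAULT_DECODING, **d.get("decoding", {})}
        sleep_cfg = {**DEFAULT_SLEEP, **d.get("sleep", {})}
        return cls(sim, analysis, decoding, sleep_cfg, d.get("out_dir", "fvp_run"), int(d.get("seed", 0)))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # where outputs land does not define the run
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]

    def analysis_hash(self) -> str:
        d = {"analysis": self.analysis, "decoding": self.decoding, "sleep": self.sleep}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _sim_from_partial(d: dict) -> SimConfig:
    """Build a SimConfig from a partial dict, filling unset fields with defaults."""
    base = SimConfig()
    full = base.to_dict()
    for k, v in d.items():
        if k in ("kernel", "gain", "background") and isinstance(v, dict):
            merged = dict(full[k])
            merged.update(v)
            full[k] = merged
        else:
            full[k] = v
    return SimConfig.from_dict(full)


def run_experiment(config: PipelineConfig) -> dict:
    """Run the full simulate -> analyze -> report pipeline; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "condition": config.sim.condition,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "analysis_hash": config.analysis_hash(),
    }
    stage = "simulate"
    try:
        sim = simulate(config.sim, config.seed)
        write_recording_hdf5(sim.recording, out / "recording.h5")
        write_events(sim.events, out / "events.tsv")
        write_hypnogram(sim.hypnogram, out / "hypnogram.tsv")
        if len(sim.spikes):
            write_spikes(sim.spikes, out / "spikes.tsv")
        sim.truth.to_json(out / "ground_truth.json")
        manifest["n_events"] = int(len(sim.events))

        stage = "epoch"
        a = config.analysis
        visual = [c.label for c in sim.recording.visual_channels()]
        epochs = vep.extract_epochs(
            sim.recording, sim.events, a["pre_ms"], a["post_ms"], channels=visual
        )

        stage = "vep"
        peak_table = plasticity.peaks_by_day(epochs, baseline_ms=a["baseline_ms"])
        peak_table.to_csv(out / "peaks_by_day.tsv", sep="\t", index=False)

        stage = "plasticity"
        late = a["late_day"] or int(epochs.meta["day"].max())
        ratios = {}
        for pk in a["peaks"]:
            tbl = plasticity.day_ratio(epochs, peak=pk, late_day=late, baseline_ms=a["baseline_ms"])
            tbl.to_csv(out / f"day_ratio_{pk}.tsv", sep="\t", index=False)
            ratios[pk] = {
                pw: round(float(g["ratio"].mean()), 6)
                for pw, g in tbl.dropna(subset=["ratio"]).groupby("pathway")
            }
        manifest["day_ratio"] = ratios
        manifest["late_day"] = late
        n_day1 = int((sim.events["day"] == 1).sum())
        if n_day1 >= 200:
            _, pooled = plasticity.rapid_index(epochs, baseline_ms=a["baseline_ms"])
            manifest["rapid_index"] = round(pooled.index, 6)

        stage = "decode"
        dcfg = config.decoding
        if dcfg["enabled"]:
            day = dcfg["day"] or late
            sel = epochs.select(day=day)
            fm = build_features(sel, baseline_ms=a["baseline_ms"])
            res = decode_accuracy(
                fm, train_frac=dcfg["train_frac"], reps=dcfg["reps"], seed=config.seed
            )
            manifest["decode_mean_accuracy_pct"] = round(100.0 * res.mean_accuracy, 4)
            if dcfg["window_scan"]:
                table, best = window_scan(
                    sel,
                    step_ms=dcfg["window_step_ms"],
                    reps=dcfg["reps"],
                    train_frac=dcfg["train_frac"],
                    seed=config.seed,
                    baseline_ms=a["baseline_ms"],
                )
                table.to_csv(out / "window_scan.tsv", sep="\t", index=False)
                manifest["decode_best_window_ms"] = list(best)
                manifest["decode_best_window_accuracy_pct"] = round(
                    100.0 * float(table["mean_accuracy"].max()), 4
                )

        stage = "sleep"
        scfg = config.sleep
        if scfg["enabled"]:
            hyp = sleepmod.stage_sleep(sim.recording, epoch_s=scfg["epoch_s"])
            write_hypnogram(hyp, out / "hypnogram_scored.tsv")
            v1 = next(c.label for c in sim.recording.visual_channels())
            eeg = sim.recording.channels_of_kind("eeg")[0].label
            tc = sleepmod.normalized_delta_timecourse(
                sim.recording, v1, eeg, hyp, sim.events, bin_s=scfg["bin_s"]
            )
            tc.to_csv(out / "normalized_delta.tsv", sep="\t", index=False)
            sw = sleepmod.detect_sw_events(sim.recording, v1, hypnogram=hyp)
            sw.to_csv(out / "sw_events.tsv", sep="\t", index=False)
            manifest["n_sw_events"] = int(len(sw))
    except FvpError:
        logger.error("pipeline stage %r failed; partial outputs kept in %s", stage, out)
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    config.to_yaml(out / "config.yaml")
    return manifest


def compare_conditions(manifests: list[dict | str | Path]) -> pd.DataFrame:
    """Tabulate headline indices across condition manifests.

    All manifests must share identical analysis settings (hash check).
    """
    loaded = []
    for m in manifests:
        if not isinstance(m, dict):
            m = json.loads(Path(m).read_text())
        loaded.append(m)
    if len(loaded) < 2:
        raise ConfigMismatchError("need at least two manifests to compare")
    hashes = {m.get("analysis_hash") for m in loaded}
    if len(hashes) != 1:
        raise ConfigMismatchError(f"manifests carry different analysis settings: {hashes}")
    rows = []
    for m in loaded:
        ratios = m.get("day_ratio", {})
        rows.append(
            {
                "condition": m.get("condition"),
                "seed": m.get("seed"),
                "N2_ratio_contra": ratios.get("N2", {}).get("contra", np.nan),
                "N2_ratio_ipsi": ratios.get("N2", {}).get("ipsi", np.nan),
                "N1_ratio_contra": ratios.get("N1", {}).get("contra", np.nan),
                "rapid_index": m.get("rapid_index", np.nan),
                "decode_accuracy_pct": m.get("decode_mean_accuracy_pct", np.nan),
            }
        )
    return pd.DataFrame(rows)
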