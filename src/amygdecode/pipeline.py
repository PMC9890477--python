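"""End-to-end pipeline: simulate -> screen -> Friedman time course ->
population decoding -> weight analysis -> SF shift analysis, with seeded
substreams per stage, delimited-text outputs and a provenance manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from . import decoding, screening, sfshift, synthetic, timecourse, weights
from .data_model import EXPRESSIONS, SpikeDataset, WindowSpec, write_spike_dataset


@dataclass
class RunConfig:
    """Defaults follow the recorded-data analysis settings: 50-ms windows at
    1-ms steps, alphas 0.05/0.01, 1,000 shuffles, 100 decoding repetitions,
    SVM cost 0.125, 80/20 train/test split, early-peak reference 55 ms."""

    out_dir: str = "results"
    window: WindowSpec = field(default_factory=WindowSpec)
    alphas: tuple[float, float] = (0.05, 0.01)
    n_shuffles: int = 1000
    n_reps: int = 100
    cost: float = 0.125
    train_frac: float = 0.8
    early_reference_center: float = 55.0
    seed: int = 0
    population: synthetic.PopulationConfig | None = None  # None -> default preset
    stages: tuple[str, ...] = ("simulate", "screen", "timecourse", "decode", "weights", "sfshift")
    latency_sustained_ms: float = 0.0

    def stage_seed(self, stage: str) -> int:
        """Fixed per-stage substream derivation from the global seed."""
        order = ("simulate", "screen", "timecourse", "decode", "weights", "sfshift")
        state = np.random.SeedSequence([self.seed, order.index(stage)]).generate_state(1)
        return int(state[0] % (2**31))


@dataclass
class PeakSummary:
    early_peak: float | None
    trough: float | None
    global_peak: float | None
    delay: float | None  # global peak center - early peak center


def find_peaks_and_trough(centers, accuracy, min_prominence: float = 0.02) -> PeakSummary:
    """Locate the early peak, trough, and global peak of a decoding-accuracy
    time course.

    The global peak is the argmax (later center on an exact tie).  The early
    peak is the highest local maximum preceding the global peak that is
    separated from it by a local minimum (the trough = the lowest point
    between them); on a tie between equal local maxima the earlier wins.
    Local maxima with topographic prominence below ``min_prominence`` are
    treated as noise wiggles, not peaks.  A unimodal or flat curve has no
    early peak.
    """
    centers = np.asarray(centers, dtype=float)
    acc = np.asarray(accuracy, dtype=float)
    if centers.size < 3:
        raise ValueError("curve must be defined on at least 3 centers")
    if np.ptp(acc) == 0:
        return PeakSummary(None, None, None, None)
    g = int(acc.size - 1 - np.argmax(acc[::-1]))  # last argmax -> later on ties
    cand, _ = signal.find_peaks(acc[:g], prominence=min_prominence)
    if cand.size == 0:
        return PeakSummary(None, None, float(centers[g]), None)
    e = int(cand[np.argmax(acc[cand])])  # earliest wins on ties via argmax
    t = e + 1 + int(np.argmin(acc[e + 1 : g]))
    if acc[t] >= min(acc[e], acc[g]):
        return PeakSummary(None, None, float(centers[g]), None)
    return PeakSummary(
        early_peak=float(centers[e]),
        trough=float(centers[t]),
        global_peak=float(centers[g]),
        delay=float(centers[g] - centers[e]),
    )


@dataclass
class PipelineReport:
    config: RunConfig
    tables: dict[str, pd.DataFrame]
    peaks: PeakSummary | None
    out_dir: Path


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute the toggled stages in order and write one CSV per table plus
    a YAML manifest to ``config.out_dir``.  Deterministic under a fixed
    seed.  Later stages depend on earlier ones (e.g. weights needs decode)
    and fail with a clear error if the dependency was disabled."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}
    dataset: SpikeDataset | None = None
    peaks = None
    tc = None
    weight_records = None
    pop = config.population or synthetic.PopulationConfig(seed=config.stage_seed("simulate"))

    def require(stage: str, obj, needed: str):
        if obj is None:
            raise StageError(stage, RuntimeError(f"requires the {needed!r} stage"))
        return obj

    for stage in config.stages:
        try:
            if stage == "simulate":
                dataset = synthetic.simulate_population(config=pop)
                write_spike_dataset(dataset, out / "dataset.csv")
            elif stage == "screen":
                ds = require(stage, dataset, "simulate")
                res = screening.screen_dataset(ds, alpha=config.alphas[0])
                tables["screening"] = pd.DataFrame(
                    {
                        "neuron_id": [r.neuron_id for r in res],
                        "responsive": [r.responsive for r in res],
                        "excluded": [r.excluded for r in res],
                        "min_p": [min(r.per_image_p.values()) if r.per_image_p else np.nan for r in res],
                        "best_image": [
                            min(r.per_image_p, key=r.per_image_p.get) if r.per_image_p else -1
                            for r in res
                        ],
                    }
                )
            elif stage == "timecourse":
                ds = require(stage, dataset, "simulate")
                counts = timecourse.significant_neuron_counts(ds, config.window, config.alphas)
                null = timecourse.shuffle_null_percentiles(
                    ds,
                    config.window,
                    config.alphas,
                    n_shuffles=config.n_shuffles,
                    seed=config.stage_seed("timecourse"),
                )
                tables["timecourse"] = pd.DataFrame(
                    {
                        "center": counts.centers,
                        "count_p05": counts.counts[config.alphas[0]],
                        "count_p01": counts.counts[config.alphas[1]],
                        "null_p95": null.p95[config.alphas[0]],
                        "null_p99": null.p99[config.alphas[0]],
                    }
                )
            elif stage == "decode":
                ds = require(stage, dataset, "simulate")
                tc = decoding.decode_timecourse(
                    ds,
                    config.window,
                    n_reps=config.n_reps,
                    train_frac=config.train_frac,
                    seed=config.stage_seed("decode"),
                    cost=config.cost,
                    store_weights_at=config.early_reference_center,
                )
                peaks = find_peaks_and_trough(tc.centers, tc.mean_accuracy)
                per_class = tc.mean_per_class
                tables["decoding"] = pd.DataFrame(
                    {
                        "center": tc.centers,
                        "accuracy": tc.mean_accuracy,
                        **{f"accuracy_{e}": per_class[:, k] for k, e in enumerate(EXPRESSIONS)},
                        "chance": tc.mean_chance,
                    }
                )
                ref = config.early_reference_center if peaks.early_peak is None else peaks.early_peak
                aucs = decoding.pairwise_auc_profile(tc, ref)
                tables["auc_profile"] = pd.DataFrame(
                    {
                        "pair": [f"{a}_vs_{b}" for (a, b) in aucs],
                        "auc": list(aucs.values()),
                        "center": ref,
                    }
                )
            elif stage == "weights":
                ds = require(stage, dataset, "simulate")
                tcx = require(stage, tc, "decode")
                ref_result = tcx.result_at(config.early_reference_center)
                weight_records = weights.extract_weights(ref_result)
                tables["weights"] = pd.DataFrame(
                    {
                        "neuron_id": [r.neuron_id for r in weight_records],
                        "weight": [r.weight for r in weight_records],
                        "group": [r.group for r in weight_records],
                    }
                )
                rows = []
                for group in ("positive", "negative"):
                    if not weights.group_ids(weight_records, group):
                        continue
                    lat = weights.group_latency(
                        ds,
                        weight_records,
                        group,
                        config.window,
                        alpha=config.alphas[0],
                        sustained_ms=config.latency_sustained_ms,
                    )
                    rows.append({"group": group, "latency_ms": lat.latency})
                tables["latency"] = pd.DataFrame(rows)
            elif stage == "sfshift":
                tcx = require(stage, tc, "decode")
                recs = require(stage, weight_records, "weights")
                # simulate tuning surfaces consistent with the generator
                # narrative: excited neurons retina-based, suppressed
                # neurons image-based, nonselective mixed
                rng = np.random.default_rng(config.stage_seed("sfshift"))
                membership = synthetic.group_membership(pop)
                rows = []
                for rec in recs:
                    mem = membership.get(rec.neuron_id, "nonselective")
                    frame = {
                        "positive": "retina_based",
                        "negative": "image_based",
                    }.get(mem, rng.choice(["retina_based", "image_based"]))
                    preferred = 0.8 if frame == "retina_based" else 5.7
                    surf = synthetic.simulate_tuning_surface(
                        frame, preferred, noise_sd=2.0, seed=int(rng.integers(2**31))
                    )
                    res = sfshift.shift_index(surf, neuron_id=rec.neuron_id)
                    rows.append(
                        {
                            "neuron_id": rec.neuron_id,
                            "shift_index": res.shift_index,
                            "weight": rec.weight,
                        }
                    )
                df = pd.DataFrame(rows)
                tables["sfshift"] = df
                corr = sfshift.shift_weight_correlation(df["shift_index"], df["weight"])
                tables["sfshift_correlation"] = pd.DataFrame(
                    [
                        {
                            "rs": corr.correlation.rs,
                            "p": corr.correlation.pvalue,
                            "slope": corr.slope,
                            "intercept": corr.intercept,
                        }
                    ]
                )
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except StageError:
            raise
        except Exception as exc:  # preserve partial outputs, name the stage
            _write_outputs(tables, peaks, config, out)
            raise StageError(stage, exc) from exc

    _write_outputs(tables, peaks, config, out)
    return PipelineReport(config=config, tables=tables, peaks=peaks, out_dir=out)


def _write_outputs(tables, peaks, config: RunConfig, out: Path) -> None:
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "window": dataclasses.asdict(config.window),
        "alphas": list(config.alphas),
        "n_shuffles": config.n_shuffles,
        "n_reps": config.n_reps,
        "cost": config.cost,
        "train_frac": config.train_frac,
        "early_reference_center": config.early_reference_center,
        "tables": sorted(tables),
        "peaks": dataclasses.asdict(peaks) if peaks is not None else None,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(manifest)), fh)
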