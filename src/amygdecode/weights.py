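"""Analysis of the early-peak open-mouth classifier weights.

Neurons are grouped by the sign of their mean open-mouth classifier weight
at the early-peak reference window (positive = early excited by open-mouth
faces, negative = early suppressed; an exactly zero mean weight excludes
the neuron).  The module provides weight-response correlations, the
weighted-sum and group-mean firing-rate time courses, and group response
latency estimated as the first window whose across-neuron firing-rate
distribution differs from the prestimulus baseline (-50 to 0 ms) at
p < 0.05 (paired Wilcoxon signed-rank test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import EXPRESSIONS, SpikeDataset, WindowSpec, count_in_window
from .decoding import DecodeWindowResult, normalize_responses
from .stats import CorrelationResult, spearman, wilcoxon_signed_rank
from .timecourse import windowed_counts

BASELINE_WINDOW = (-50.0, 0.0)


@dataclass(frozen=True)
class WeightRecord:
    neuron_id: int
    weight: float  # mean across the repetitions that included the neuron
    group: str  # positive | negative | excluded_zero


@dataclass
class LatencyResult:
    group: str
    latency: float | None  # ms (window center of first p < alpha), None if never
    centers: np.ndarray
    pvalues: np.ndarray


def extract_weights(result: DecodeWindowResult) -> list[WeightRecord]:
    """Per-neuron mean open-mouth weight across repetitions (repetitions
    where the neuron was not subsampled are excluded from the mean) and the
    sign-based group assignment."""
    if result.weights_open_mouth is None:
        raise ValueError("decode result was run without store_weights")
    records = []
    for col, nid in enumerate(result.neuron_ids):
        w = result.weights_open_mouth[:, col]
        w = w[~np.isnan(w)]
        if w.size == 0:
            warnings.warn(f"neuron {nid} was never subsampled; no weight record")
            continue
        mean_w = float(w.mean())
        if mean_w > 0:
            group = "positive"
        elif mean_w < 0:
            group = "negative"
        else:
            group = "excluded_zero"
        records.append(WeightRecord(int(nid), mean_w, group))
    return records


def group_ids(records: list[WeightRecord], group: str) -> list[int]:
    return [r.neuron_id for r in records if r.group == group]


def _mean_fr(neuron, lo: float, hi: float, expressions, catalog) -> float:
    """Mean firing rate (sp/s) over the neuron's trials of the given
    expressions in [lo, hi)."""
    dur_s = (hi - lo) / 1000.0
    rates = [
        count_in_window(t.spike_times, lo, hi) / dur_s
        for t in neuron.trials
        if catalog.expression_of(t.image_id) in expressions
    ]
    return float(np.mean(rates))


def weight_response_correlation(
    records: list[WeightRecord],
    dataset: SpikeDataset,
    center: float,
    spec: WindowSpec,
    mode: str = "preference",
) -> CorrelationResult:
    """Spearman correlation between the classifier weight and a firing-rate
    difference at the reference window.

    mode "preference": mean FR for open-mouth faces minus mean FR for the
    other faces.  mode "excitation": mean FR for open-mouth faces at the
    window minus in the prestimulus baseline (-50 to 0 ms).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 neurons")
    lo, hi = spec.bounds(center)
    cat = dataset.catalog
    w, d = [], []
    for rec in records:
        neuron = dataset.neuron(rec.neuron_id)
        if mode == "preference":
            diff = _mean_fr(neuron, lo, hi, {"open_mouth"}, cat) - _mean_fr(
                neuron, lo, hi, {"neutral", "pout_lips"}, cat
            )
        elif mode == "excitation":
            diff = _mean_fr(neuron, lo, hi, {"open_mouth"}, cat) - _mean_fr(
                neuron, *BASELINE_WINDOW, {"open_mouth"}, cat
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        w.append(rec.weight)
        d.append(diff)
    return spearman(w, d)


def weighted_sum_timecourse(
    dataset: SpikeDataset,
    records: list[WeightRecord],
    group: str,
    spec: WindowSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Time course of the open-mouth classifier output restricted to one
    weight-sign group: per window, sum of weight x max-normalized count over
    the group's neurons, averaged over trials of each expression.

    Weights are the fixed early-peak means; because the weighted sum is
    linear in the weights, using mean weights equals averaging per-repetition
    weighted sums.  Returns (centers, (n_centers, 3) series ordered as
    EXPRESSIONS).
    """
    ids = group_ids(records, group)
    if not ids:
        raise ValueError(f"empty group {group!r}")
    wmap = {r.neuron_id: r.weight for r in records}
    centers = spec.centers
    cat = dataset.catalog
    series = np.zeros((centers.size, 3))
    # all group neurons share the trial layout of the simulated dataset
    neurons = [dataset.neuron(i) for i in ids]
    exprs = np.array([cat.expression_of(t.image_id) for t in neurons[0].trials])
    total = np.zeros((centers.size, len(exprs)))
    for n in neurons:
        counts = windowed_counts(n, spec).astype(float)  # (n_centers, n_trials)
        norm = normalize_responses(counts.T, counts.T).T
        total += wmap[n.neuron_id] * norm
    for k, e in enumerate(EXPRESSIONS):
        series[:, k] = total[:, exprs == e].mean(axis=1)
    return centers, series


def group_mean_fr_timecourse(
    dataset: SpikeDataset,
    records: list[WeightRecord],
    group: str,
    spec: WindowSpec,
    expression: str = "open_mouth",
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted mean firing rate (sp/s) across the group's neurons and the
    selected expression's trials at every window."""
    ids = group_ids(records, group)
    if not ids:
        raise ValueError(f"empty group {group!r}")
    centers = spec.centers
    acc = np.zeros(centers.size)
    for nid in ids:
        n = dataset.neuron(nid)
        mask = np.array(
            [dataset.catalog.expression_of(t.image_id) == expression for t in n.trials]
        )
        counts = windowed_counts(n, spec)
        acc += counts[:, mask].mean(axis=1) / (spec.width / 1000.0)
    return centers, acc / len(ids)


def group_latency(
    dataset: SpikeDataset,
    records: list[WeightRecord],
    group: str,
    spec: WindowSpec,
    alpha: float = 0.05,
    expression: str = "open_mouth",
    baseline: tuple[float, float] = BASELINE_WINDOW,
    sustained_ms: float = 0.0,
) -> LatencyResult:
    """Group response latency: first window center whose across-neuron
    firing-rate distribution differs from the prestimulus baseline at
    p < alpha (paired two-sided signed-rank across neurons).

    ``sustained_ms`` > 0 requires significance to persist over a run of
    consecutive windows spanning at least that many ms (robustness variant;
    the default is the single first crossing).
    """
    ids = group_ids(records, group)
    if len(ids) < 6:
        raise ValueError("group too small for a signed-rank latency estimate")
    centers = spec.centers
    cat = dataset.catalog
    lo_b, hi_b = baseline
    base_fr = []
    window_fr = []
    for nid in ids:
        n = dataset.neuron(nid)
        mask = np.array([cat.expression_of(t.image_id) == expression for t in n.trials])
        base_fr.append(
            np.mean(
                [
                    count_in_window(t.spike_times, lo_b, hi_b) / ((hi_b - lo_b) / 1000.0)
                    for t, keep in zip(n.trials, mask)
                    if keep
                ]
            )
        )
        counts = windowed_counts(n, spec)
        window_fr.append(counts[:, mask].mean(axis=1) / (spec.width / 1000.0))
    base_fr = np.array(base_fr)
    window_fr = np.array(window_fr)  # (n_neurons, n_centers)
    pvals = np.array(
        [wilcoxon_signed_rank(window_fr[:, i], base_fr).pvalue for i in range(centers.size)]
    )
    sig = pvals < alpha
    run_needed = max(1, int(np.ceil(sustained_ms / spec.step)))
    latency = None
    run = 0
    for i, s in enumerate(sig):
        run = run + 1 if s else 0
        if run >= run_needed:
            latency = float(centers[i - run_needed + 1])
            break
    return LatencyResult(group=group, latency=latency, centers=centers, pvalues=pvals)
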