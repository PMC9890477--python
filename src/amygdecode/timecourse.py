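"""Per-neuron sliding-window Friedman analysis of expression sensitivity
and its shuffle-based false-positive calibration.

For every window center, each neuron contributes a blocks x 3 table
(treatments = the 3 facial expressions).  By default a block is one
repetition index and the cell value is the spike count averaged across the
3 identities at that repetition ("identity_mean"); the alternative
"identity_blocks" mode uses one block per identity x repetition.  Unequal
repetition counts across images are truncated to the per-image minimum in
presentation order; neurons with fewer than 6 repetitions are excluded.

The shuffle null permutes image labels across each neuron's trials
(preserving the neuron's count marginal), recomputes the number of
significant neurons per window, and reports the 95th/99th percentiles of
that count distribution averaged across windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .data_model import NeuronRecord, SpikeDataset, StimulusCatalog, WindowSpec
from .stats import FriedmanResult, friedman_chi2_batch_k3, friedman_statistic
from .data_model import EXPRESSIONS, IDENTITIES

MIN_REPS = 6
_SHUFFLE_CHUNK = 200


class InsufficientTrialsError(ValueError):
    """Fewer repetitions than the analysis minimum."""


def windowed_counts(neuron: NeuronRecord, spec: WindowSpec) -> np.ndarray:
    """Spike counts of every trial at every window center:
    shape (n_centers, n_trials), trials in stored order."""
    centers = spec.centers
    los = centers - spec.width / 2.0
    his = centers + spec.width / 2.0
    out = np.empty((centers.size, len(neuron.trials)), dtype=np.int64)
    for j, tr in enumerate(neuron.trials):
        t = np.asarray(tr.spike_times, dtype=float)
        out[:, j] = np.searchsorted(t, his, side="left") - np.searchsorted(t, los, side="left")
    return out


def _trial_index(
    neuron: NeuronRecord, catalog: StimulusCatalog, min_reps: int = MIN_REPS
) -> np.ndarray:
    """Index array (3 expressions, 3 identities, m reps) of trial positions,
    truncated to the per-image minimum repetition count m."""
    by_image: dict[int, list[int]] = {iid: [] for iid in catalog.image_ids}
    for j, tr in enumerate(neuron.trials):
        by_image[tr.image_id].append(j)
    m = min(len(v) for v in by_image.values())
    if m < min_reps:
        raise InsufficientTrialsError(
            f"neuron {neuron.neuron_id}: only {m} repetitions per image (need {min_reps})"
        )
    idx = np.empty((3, 3, m), dtype=np.int64)
    for e, expr in enumerate(EXPRESSIONS):
        for i, ident in enumerate(IDENTITIES):
            (iid,) = [
                im.image_id
                for im in catalog.images
                if im.expression == expr and im.identity == ident
            ]
            idx[e, i, :] = by_image[iid][:m]
    return idx


def _tables_from_counts(counts: np.ndarray, idx: np.ndarray, mode: str) -> np.ndarray:
    """Assemble Friedman tables from gathered counts.

    ``counts`` has shape (..., 3 expr, 3 ident, m); returns (..., blocks, 3).
    """
    if mode == "identity_mean":
        t = counts.mean(axis=-2)  # (..., 3 expr, m)
        return np.moveaxis(t, -2, -1)  # (..., m, 3)
    if mode == "identity_blocks":
        t = np.moveaxis(counts, -3, -1)  # (..., 3 ident, m, 3 expr)
        return t.reshape(*t.shape[:-3], -1, 3)  # (..., 3*m, 3)
    raise ValueError(f"unknown block mode {mode!r}")


def expression_table(
    neuron: NeuronRecord,
    catalog: StimulusCatalog,
    center: float,
    spec: WindowSpec,
    mode: str = "identity_mean",
) -> np.ndarray:
    """Blocks x 3 expression table of spike counts for one window."""
    one = WindowSpec(width=spec.width, step=spec.step, center_min=center, center_max=center)
    counts = windowed_counts(neuron, one)[0]  # (n_trials,)
    idx = _trial_index(neuron, catalog)
    return _tables_from_counts(counts[idx][None], idx, mode)[0]


def friedman_timecourse(
    neuron: NeuronRecord,
    catalog: StimulusCatalog,
    spec: WindowSpec,
    mode: str = "identity_mean",
) -> np.ndarray:
    """Friedman p-value at every window center for one neuron."""
    counts = windowed_counts(neuron, spec)  # (n_centers, n_trials)
    idx = _trial_index(neuron, catalog)
    tables = _tables_from_counts(counts[:, idx], idx, mode)  # (n_centers, b, 3)
    chi2 = friedman_chi2_batch_k3(tables)
    p = sps.chi2.sf(chi2, 2)
    return np.where(chi2 > 0, p, 1.0)


def expression_test(
    neuron: NeuronRecord,
    catalog: StimulusCatalog,
    center: float,
    spec: WindowSpec,
    mode: str = "identity_mean",
) -> FriedmanResult:
    """Single-window Friedman test (e.g. the early window, center 55 ms)."""
    return friedman_statistic(expression_table(neuron, catalog, center, spec, mode))


@dataclass
class SignificantCounts:
    centers: np.ndarray
    counts: dict[float, np.ndarray]  # alpha -> per-center neuron counts
    n_neurons: int
    excluded_ids: list[int]


def significant_neuron_counts(
    dataset: SpikeDataset,
    spec: WindowSpec,
    alphas: tuple[float, ...] = (0.05, 0.01),
    mode: str = "identity_mean",
) -> SignificantCounts:
    """Number of expression-differentiating neurons (Friedman p < alpha) at
    every window center, for each alpha."""
    centers = spec.centers
    acc = {a: np.zeros(centers.size, dtype=int) for a in alphas}
    excluded = []
    n_used = 0
    for neuron in dataset.neurons:
        try:
            p = friedman_timecourse(neuron, dataset.catalog, spec, mode)
        except InsufficientTrialsError:
            excluded.append(neuron.neuron_id)
            continue
        n_used += 1
        for a in alphas:
            acc[a] += p < a
    return SignificantCounts(centers, acc, n_used, excluded)


@dataclass
class NullPercentiles:
    """Shuffle-null calibration of the significant-neuron counts.

    ``p95``/``p99`` are the per-window percentiles of the shuffled count
    distribution averaged across windows (keyed by alpha); the per-window
    arrays are kept for diagnostics.
    """

    p95: dict[float, float]
    p99: dict[float, float]
    per_window_p95: dict[float, np.ndarray]
    per_window_p99: dict[float, np.ndarray]
    centers: np.ndarray
    n_shuffles: int


def shuffle_null_percentiles(
    dataset: SpikeDataset,
    spec: WindowSpec,
    alphas: tuple[float, ...] = (0.05, 0.01),
    n_shuffles: int = 1000,
    seed: int | None = None,
    mode: str = "identity_mean",
) -> NullPercentiles:
    """Null distribution of the significant-neuron count built by permuting
    image labels across trials within each neuron (1,000 repetitions by
    default), seeded and deterministic."""
    if n_shuffles < 1:
        raise ValueError("need at least one shuffle")
    rng = np.random.default_rng(seed)
    centers = spec.centers
    sig = {a: np.zeros((centers.size, n_shuffles), dtype=np.int32) for a in alphas}
    for neuron in dataset.neurons:
        try:
            idx = _trial_index(neuron, dataset.catalog)
        except InsufficientTrialsError:
            continue
        counts = windowed_counts(neuron, spec)  # (n_centers, n_trials)
        n_trials = counts.shape[1]
        perms = np.array([rng.permutation(n_trials) for _ in range(n_shuffles)])
        for s0 in range(0, n_shuffles, _SHUFFLE_CHUNK):
            sl = slice(s0, min(s0 + _SHUFFLE_CHUNK, n_shuffles))
            gathered = counts[:, perms[sl][:, idx]]  # (n_centers, chunk, 3, 3, m)
            tables = _tables_from_counts(gathered, idx, mode)
            chi2 = friedman_chi2_batch_k3(tables)
            p = np.where(chi2 > 0, sps.chi2.sf(chi2, 2), 1.0)
            for a in alphas:
                sig[a][:, sl] += p < a
    per95 = {a: np.percentile(sig[a], 95, axis=1) for a in alphas}
    per99 = {a: np.percentile(sig[a], 99, axis=1) for a in alphas}
    return NullPercentiles(
        p95={a: float(per95[a].mean()) for a in alphas},
        p99={a: float(per99[a].mean()) for a in alphas},
        per_window_p95=per95,
        per_window_p99=per99,
        centers=centers,
        n_shuffles=n_shuffles,
    )
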