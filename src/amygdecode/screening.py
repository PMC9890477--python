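"""Face-responsiveness screening.

A neuron is face responsive if at least one of the 9 face images elicits a
significant *increase* in firing between the 500 ms before and the 500 ms
after stimulus onset (two-sided paired Wilcoxon signed-rank test per image,
no correction across the 9 images).  "Increase" requires, besides p < alpha,
a positive median post-minus-pre difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import NeuronRecord, SpikeDataset, StimulusCatalog, count_in_window
from .stats import wilcoxon_signed_rank

PRE_EPOCH = (-500.0, 0.0)
POST_EPOCH = (0.0, 500.0)
MIN_TRIALS = 6


@dataclass(frozen=True)
class ScreeningResult:
    neuron_id: int
    responsive: bool
    per_image_p: dict[int, float]
    excluded: bool = False  # too few trials to screen


def _epoch_rates(neuron: NeuronRecord, image_id: int, epoch: tuple[float, float]) -> np.ndarray:
    lo, hi = epoch
    dur_s = (hi - lo) / 1000.0
    return np.array(
        [count_in_window(t.spike_times, lo, hi) / dur_s for t in neuron.trials_for_image(image_id)]
    )


def face_responsiveness(
    neuron: NeuronRecord, catalog: StimulusCatalog, alpha: float = 0.05
) -> ScreeningResult:
    """Screen one neuron; flags the neuron excluded if any image has fewer
    than 6 trials."""
    counts = neuron.trial_counts(catalog)
    if min(counts.values()) < MIN_TRIALS:
        return ScreeningResult(neuron.neuron_id, False, {}, excluded=True)
    per_image_p: dict[int, float] = {}
    responsive = False
    for iid in catalog.image_ids:
        pre = _epoch_rates(neuron, iid, PRE_EPOCH)
        post = _epoch_rates(neuron, iid, POST_EPOCH)
        res = wilcoxon_signed_rank(post, pre)
        per_image_p[iid] = res.pvalue
        if res.pvalue < alpha and np.median(post - pre) > 0:
            responsive = True
    return ScreeningResult(neuron.neuron_id, responsive, per_image_p)


def screen_dataset(dataset: SpikeDataset, alpha: float = 0.05) -> list[ScreeningResult]:
    return [face_responsiveness(n, dataset.catalog, alpha) for n in dataset.neurons]
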