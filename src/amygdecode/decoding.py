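"""One-vs-rest linear-SVM population decoding of facial expression.

For each 50-ms window, spike counts form a population response vector x
(one entry per neuron).  Counts are max-normalized within each neuron
(reference maximum taken from the training folds by default), and three
soft-margin linear classifiers f_k(x) = w_k . x + b_k (C-SVC, linear
kernel, cost 0.125) are trained one-vs-rest, one per expression.  The
predicted expression maximizes f_k, ties broken in the fixed order
(open_mouth, neutral, pout_lips).

Because the neurons were not recorded simultaneously, pseudo-trials are
assembled by pairing randomly chosen trials of the same image across
neurons; each of the (default 100) repetitions redraws the 80/20
train/test split and the pseudo-trial pairing.  Chance performance is
estimated with label-shuffled training sets through the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .data_model import EXPRESSIONS, SpikeDataset, WindowSpec
from .stats import auc, reflect_auc
from .timecourse import windowed_counts

SVM_COST = 0.125
SVM_TOL = 1e-6


@dataclass
class ClassifierEnsemble:
    """The three one-vs-rest linear decision functions for one window."""

    weights: np.ndarray  # (3, n_neurons) rows ordered as EXPRESSIONS
    offsets: np.ndarray  # (3,)
    center: float
    cost: float = SVM_COST

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        if x.shape[1] != self.weights.shape[1]:
            raise ValueError("response-vector dimension mismatch")
        return x @ self.weights.T + self.offsets


def normalize_responses(train: np.ndarray, apply_to: np.ndarray) -> np.ndarray:
    """Divide each neuron's counts by its maximum in the training reference
    (columns = neurons); a zero reference maximum maps the neuron to zeros."""
    train = np.asarray(train, dtype=float)
    apply_to = np.asarray(apply_to, dtype=float)
    if train.shape[1] != apply_to.shape[1]:
        raise ValueError("same neuron set required in both matrices")
    ref_max = train.max(axis=0)
    scale = np.where(ref_max > 0, ref_max, 1.0)
    out = apply_to / scale
    out[:, ref_max == 0] = 0.0
    return out


def train_ovr(x: np.ndarray, labels: np.ndarray, cost: float = SVM_COST,
              center: float = np.nan) -> ClassifierEnsemble:
    """Train the three one-vs-rest soft-margin linear SVMs (C-SVC)."""
    labels = np.asarray(labels)
    present = set(labels.tolist())
    missing = [e for e in EXPRESSIONS if e not in present]
    if missing:
        raise ValueError(f"expression(s) absent from training set: {missing}")
    n_features = x.shape[1]
    weights = np.empty((3, n_features))
    offsets = np.empty(3)
    for k, expr in enumerate(EXPRESSIONS):
        y = (labels == expr).astype(int)
        clf = SVC(kernel="linear", C=cost, tol=SVM_TOL)
        clf.fit(x, y)
        weights[k] = clf.coef_[0]
        offsets[k] = clf.intercept_[0]
    return ClassifierEnsemble(weights, offsets, center=center, cost=cost)


def classify(ensemble: ClassifierEnsemble, x: np.ndarray) -> np.ndarray:
    """Predicted expression per row of x: argmax_k f_k(x); ties go to the
    first expression in the fixed order."""
    f = ensemble.decision_values(x)
    return np.array(EXPRESSIONS)[np.argmax(f, axis=1)]


@dataclass
class DecodeWindowResult:
    center: float
    overall: np.ndarray  # (n_reps,) fraction correct on the test vectors
    per_class: np.ndarray  # (n_reps, 3) per-expression fraction correct
    neuron_ids: np.ndarray  # all eligible neuron ids (weight columns)
    weights_open_mouth: np.ndarray | None = None  # (n_reps, n_neurons), NaN = not subsampled
    n_train: int = 0
    n_test: int = 0

    @property
    def mean_overall(self) -> float:
        return float(self.overall.mean())

    @property
    def mean_per_class(self) -> np.ndarray:
        return self.per_class.mean(axis=0)


def _eligible_neurons(dataset: SpikeDataset, n_trials_required: int = 10):
    """Neurons tested with exactly ``n_trials_required`` trials per image;
    others are excluded before the analysis."""
    kept, dropped = [], []
    for n in dataset.neurons:
        counts = n.trial_counts(dataset.catalog)
        if all(c == n_trials_required for c in counts.values()):
            kept.append(n)
        else:
            dropped.append(n.neuron_id)
    return kept, dropped


def _window_count_cache(neurons, catalog, centers: np.ndarray, width: float):
    """Per neuron: trial positions grouped by image and the
    (n_centers, n_trials) count matrix."""
    per_image_pos = []
    all_counts = []
    ws = _ArbitraryCenters(centers, width)
    for n in neurons:
        per_image_pos.append(
            {iid: [j for j, t in enumerate(n.trials) if t.image_id == iid]
             for iid in catalog.image_ids}
        )
        all_counts.append(windowed_counts(n, ws))
    return all_counts, per_image_pos


class _ArbitraryCenters:
    """Duck-typed WindowSpec over an explicit center list."""

    def __init__(self, centers: np.ndarray, width: float):
        self.centers = np.asarray(centers, dtype=float)
        self.width = float(width)


def decode_window(
    dataset: SpikeDataset,
    center: float,
    spec: WindowSpec,
    n_reps: int = 100,
    n_neurons: int | None = None,
    train_frac: float = 0.8,
    seed: int | None = None,
    cost: float = SVM_COST,
    shuffle_labels: bool = False,
    store_weights: bool = False,
    normalization_reference: str = "train",
) -> DecodeWindowResult:
    """Cross-validated decoding at a single window center (see module docs).

    ``normalization_reference`` is "train" (per-neuron max over training
    folds, the default) or "all" (max over all folds, the leakier variant).
    """
    return _decode_centers(
        dataset, np.array([center]), spec.width, n_reps, n_neurons, train_frac,
        seed, cost, shuffle_labels, store_weights, normalization_reference,
    )[0]


def _decode_centers(
    dataset, centers, width, n_reps, n_neurons, train_frac, seed, cost,
    shuffle_labels, store_weights, normalization_reference,
) -> list[DecodeWindowResult]:
    neurons, dropped = _eligible_neurons(dataset)
    if dropped:
        import logging

        logging.getLogger(__name__).info(
            "excluded %d neuron(s) without a full 10-trial set: %s", len(dropped), dropped
        )
    if not neurons:
        raise ValueError("no neuron has the required complete trial set")
    n_total = len(neurons)
    if n_neurons is None:
        n_neurons = n_total
    if n_neurons > n_total:
        raise ValueError("cannot equalize to more neurons than available")
    catalog = dataset.catalog
    image_ids = list(catalog.image_ids)
    expr_per_image = np.array([catalog.expression_of(i) for i in image_ids])
    m = len(neurons[0].trials_for_image(image_ids[0]))
    n_train = int(round(train_frac * m))
    n_test = m - n_train

    all_counts, per_image_pos = _window_count_cache(neurons, catalog, centers, width)
    # per-neuron counts rearranged to (n_centers, 9 images, m reps)
    counts_cim = []
    for ni in range(n_total):
        pos = np.array([per_image_pos[ni][iid] for iid in image_ids])  # (9, m)
        counts_cim.append(all_counts[ni][:, pos])  # (n_centers, 9, m)

    train_labels_full = np.repeat(expr_per_image, n_train)
    test_labels = np.repeat(expr_per_image, n_test)
    expr_order = np.array(EXPRESSIONS)

    # substreams keyed by (base seed, window center, repetition) so the same
    # window reproduces the same splits regardless of which centers were run
    base = int(np.random.SeedSequence(seed).entropy % (2**31))

    results = []
    for ci in range(centers.size):
        center_key = int(round(8 * float(centers[ci]))) + 2**16
        overall = np.empty(n_reps)
        per_class = np.empty((n_reps, 3))
        wom = np.full((n_reps, n_total), np.nan) if store_weights else None
        for rep in range(n_reps):
            rng = np.random.default_rng(
                np.random.SeedSequence([base, int(shuffle_labels), center_key, rep])
            )
            sel = (
                np.sort(rng.choice(n_total, size=n_neurons, replace=False))
                if n_neurons < n_total
                else np.arange(n_total)
            )
            x_train = np.empty((9 * n_train, n_neurons))
            x_test = np.empty((9 * n_test, n_neurons))
            for col, ni in enumerate(sel):
                cim = counts_cim[ni][ci]  # (9, m)
                for im in range(9):
                    perm = rng.permutation(m)
                    x_train[im * n_train:(im + 1) * n_train, col] = cim[im, perm[:n_train]]
                    x_test[im * n_test:(im + 1) * n_test, col] = cim[im, perm[n_train:]]
            train_labels = train_labels_full
            if shuffle_labels:
                train_labels = rng.permutation(train_labels_full)
            xt = normalize_responses(x_train, x_train)
            if normalization_reference == "train":
                xs = normalize_responses(x_train, x_test)
            elif normalization_reference == "all":
                both = np.vstack([x_train, x_test])
                xt = normalize_responses(both, x_train)
                xs = normalize_responses(both, x_test)
            else:
                raise ValueError("normalization_reference must be 'train' or 'all'")
            ens = train_ovr(xt, train_labels, cost=cost, center=centers[ci])
            pred = classify(ens, xs)
            correct = pred == test_labels
            overall[rep] = correct.mean()
            for k, expr in enumerate(expr_order):
                mask = test_labels == expr
                per_class[rep, k] = correct[mask].mean()
            if store_weights:
                k_open = EXPRESSIONS.index("open_mouth")
                wom[rep, sel] = ens.weights[k_open]
        results.append(
            DecodeWindowResult(
                center=float(centers[ci]),
                overall=overall,
                per_class=per_class,
                neuron_ids=np.array([n.neuron_id for n in neurons]),
                weights_open_mouth=wom,
                n_train=9 * n_train,
                n_test=9 * n_test,
            )
        )
    return results


@dataclass
class DecodingTimecourse:
    centers: np.ndarray
    overall: np.ndarray  # (n_centers, n_reps)
    per_class: np.ndarray  # (n_centers, n_reps, 3)
    chance: np.ndarray | None  # (n_centers, n_reps) label-shuffled
    n_reps: int
    seed: int | None
    window_results: list[DecodeWindowResult] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.overall.mean(axis=1)

    @property
    def mean_per_class(self) -> np.ndarray:
        return self.per_class.mean(axis=1)

    @property
    def mean_chance(self) -> np.ndarray | None:
        return None if self.chance is None else self.chance.mean(axis=1)

    def result_at(self, center: float) -> DecodeWindowResult:
        i = int(np.argmin(np.abs(self.centers - center)))
        return self.window_results[i]


def decode_timecourse(
    dataset: SpikeDataset,
    spec: WindowSpec,
    n_reps: int = 100,
    n_neurons: int | None = None,
    train_frac: float = 0.8,
    seed: int | None = None,
    cost: float = SVM_COST,
    with_chance: bool = True,
    store_weights_at: float | None = None,
) -> DecodingTimecourse:
    """Decoding accuracy at every window center; classifiers are trained
    independently per window.  ``store_weights_at`` keeps the per-rep
    open-mouth weight vectors at the nearest center (for weight analysis)."""
    centers = spec.centers
    results = _decode_centers(
        dataset, centers, spec.width, n_reps, n_neurons, train_frac, seed,
        cost, False, False, "train",
    )
    if store_weights_at is not None:
        i = int(np.argmin(np.abs(centers - store_weights_at)))
        results[i] = _decode_centers(
            dataset, centers[i:i + 1], spec.width, n_reps, n_neurons, train_frac,
            seed, cost, False, True, "train",
        )[0]
    chance = None
    if with_chance:
        chance_results = _decode_centers(
            dataset, centers, spec.width, n_reps, n_neurons, train_frac,
            seed, cost, True, False, "train",
        )
        chance = np.stack([r.overall for r in chance_results])
    return DecodingTimecourse(
        centers=centers,
        overall=np.stack([r.overall for r in results]),
        per_class=np.stack([r.per_class for r in results]),
        chance=chance,
        n_reps=n_reps,
        seed=seed,
        window_results=results,
    )


def pairwise_auc_profile(timecourse: DecodingTimecourse, center: float) -> dict[tuple[str, str], float]:
    """Reflected AUC between the per-repetition correct-rate distributions
    of each expression pair at the window nearest ``center``."""
    res = timecourse.result_at(center)
    out = {}
    pairs = [("open_mouth", "neutral"), ("open_mouth", "pout_lips"), ("neutral", "pout_lips")]
    for a, b in pairs:
        ia, ib = EXPRESSIONS.index(a), EXPRESSIONS.index(b)
        out[(a, b)] = reflect_auc(auc(res.per_class[:, ia], res.per_class[:, ib]))
    return out
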