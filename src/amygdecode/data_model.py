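"""Domain types, spike-dataset I/O and windowed spike counting.

Spike times are floating-point milliseconds relative to stimulus onset at 0
(prestimulus negative), restricted to [-500, 1000).  Analysis windows follow
a half-open convention: the window with center ``c`` and width ``w`` covers
``[c - w/2, c + w/2)``, so adjacent non-overlapping windows partition time.

The on-disk format is plain CSV, one row per trial::

    neuron_id,area,trial_id,image_id,spike_times

with ``spike_times`` a semicolon-separated list of times in ms (empty string
for a silent trial).  A YAML sidecar at ``<path>.meta.yaml`` carries the
stimulus catalog.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

EXPRESSIONS = ("open_mouth", "neutral", "pout_lips")
IDENTITIES = ("M1", "M2", "M3")
AREAS = ("amygdala", "temporal_cortex")

#: center spatial frequencies (cycles/image) and stimulus sizes (degrees)
#: of the 7 x 5 bandpass-filtered stimulus grid
SF_GRID_CENTER_SFS = (2.0, 2.8, 4.0, 5.7, 8.0, 11.3, 16.0)
SF_GRID_SIZES = (3.8, 5.4, 7.7, 11.0, 15.3)

TIME_MIN_MS = -500.0
TIME_MAX_MS = 1000.0


class ValidationError(ValueError):
    """A dataset or file violates a structural invariant."""


@dataclass(frozen=True)
class StimulusImage:
    image_id: int
    identity: str
    expression: str


@dataclass(frozen=True)
class StimulusCatalog:
    """The 9 face images: 3 identities x 3 expressions, plus the optional
    spatial-frequency/size grid used in the tuning-surface experiment."""

    images: tuple[StimulusImage, ...]
    sf_grid: tuple[tuple[float, ...], tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        if len(self.images) != 9:
            raise ValidationError(f"catalog needs exactly 9 images, got {len(self.images)}")
        pairs = {(im.identity, im.expression) for im in self.images}
        if pairs != {(i, e) for i in IDENTITIES for e in EXPRESSIONS}:
            raise ValidationError("images must form the full 3x3 identity x expression cross")
        if len({im.image_id for im in self.images}) != 9:
            raise ValidationError("image ids must be unique")
        if self.sf_grid is not None:
            sfs, sizes = self.sf_grid
            if tuple(sfs) != SF_GRID_CENTER_SFS or tuple(sizes) != SF_GRID_SIZES:
                raise ValidationError("sf_grid must be the canonical 7 SF x 5 size grid")

    def expression_of(self, image_id: int) -> str:
        return self._by_id()[image_id].expression

    def identity_of(self, image_id: int) -> str:
        return self._by_id()[image_id].identity

    def _by_id(self) -> dict[int, StimulusImage]:
        return {im.image_id: im for im in self.images}

    @property
    def image_ids(self) -> tuple[int, ...]:
        return tuple(im.image_id for im in self.images)


def default_catalog(with_sf_grid: bool = False) -> StimulusCatalog:
    """Canonical catalog: image_id 1..9 in identity-major order."""
    images = []
    iid = 1
    for ident in IDENTITIES:
        for expr in EXPRESSIONS:
            images.append(StimulusImage(iid, ident, expr))
            iid += 1
    grid = (SF_GRID_CENTER_SFS, SF_GRID_SIZES) if with_sf_grid else None
    return StimulusCatalog(tuple(images), grid)


@dataclass
class Trial:
    trial_id: int
    image_id: int
    spike_times: np.ndarray  # ms, sorted ascending

    def validate(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        if t.ndim != 1:
            raise ValidationError("spike_times must be 1-D")
        if t.size and (t.min() < TIME_MIN_MS or t.max() >= TIME_MAX_MS):
            raise ValidationError(
                f"trial {self.trial_id}: spike time outside [{TIME_MIN_MS}, {TIME_MAX_MS})"
            )
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError(f"trial {self.trial_id}: spike times not strictly increasing")


@dataclass
class NeuronRecord:
    neuron_id: int
    area: str
    trials: list[Trial] = field(default_factory=list)

    def validate(self, catalog: StimulusCatalog) -> None:
        if self.area not in AREAS:
            raise ValidationError(f"unknown area {self.area!r}")
        known = set(catalog.image_ids)
        for tr in self.trials:
            if tr.image_id not in known:
                raise ValidationError(
                    f"neuron {self.neuron_id}: unknown image_id {tr.image_id}"
                )
            tr.validate()

    def trials_for_image(self, image_id: int) -> list[Trial]:
        return [t for t in self.trials if t.image_id == image_id]

    def trial_counts(self, catalog: StimulusCatalog) -> dict[int, int]:
        return {iid: len(self.trials_for_image(iid)) for iid in catalog.image_ids}


@dataclass
class SpikeDataset:
    """Trial-aligned spike times for a population of (non-simultaneously
    recorded) neurons, with the stimulus catalog they were tested on."""

    neurons: list[NeuronRecord]
    catalog: StimulusCatalog

    def validate(self) -> None:
        if len({n.neuron_id for n in self.neurons}) != len(self.neurons):
            raise ValidationError("neuron ids must be unique")
        for n in self.neurons:
            n.validate(self.catalog)

    def neuron(self, neuron_id: int) -> NeuronRecord:
        for n in self.neurons:
            if n.neuron_id == neuron_id:
                return n
        raise KeyError(neuron_id)

    def subset(self, neuron_ids: Iterable[int]) -> "SpikeDataset":
        wanted = set(neuron_ids)
        return SpikeDataset([n for n in self.neurons if n.neuron_id in wanted], self.catalog)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry.  ``centers`` is the inclusive center range
    sampled every ``step`` ms; each window is half-open
    [center - width/2, center + width/2)."""

    width: float = 50.0
    step: float = 1.0
    center_min: float = -100.0
    center_max: float = 500.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.step <= 0:
            raise ValidationError("width and step must be positive")
        if self.center_max < self.center_min:
            raise ValidationError("empty center range")

    @property
    def centers(self) -> np.ndarray:
        n = int(np.floor((self.center_max - self.center_min) / self.step + 1e-9)) + 1
        return self.center_min + self.step * np.arange(n)

    def bounds(self, center: float) -> tuple[float, float]:
        return center - self.width / 2.0, center + self.width / 2.0


@dataclass
class ResponseMatrix:
    """neurons x trials spike counts for one window.

    ``trials`` indexes pseudo-trials; ``image_ids`` / ``expressions`` label
    the trial axis.  Counts are raw (unnormalized) nonnegative integers.
    """

    counts: np.ndarray  # (n_neurons, n_trials) int
    neuron_ids: np.ndarray
    image_ids: np.ndarray
    expressions: np.ndarray  # str per trial
    center: float
    width: float

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValidationError("counts must be 2-D (neurons x trials)")
        if (c < 0).any():
            raise ValidationError("counts must be nonnegative")
        if len(self.image_ids) != c.shape[1] or len(self.expressions) != c.shape[1]:
            raise ValidationError("label arity must match trial axis")
        if len(self.neuron_ids) != c.shape[0]:
            raise ValidationError("neuron_ids arity must match neuron axis")


def count_in_window(spike_times: np.ndarray, lo: float, hi: float) -> int:
    """Spikes in the half-open interval [lo, hi) (times assumed sorted)."""
    t = np.asarray(spike_times, dtype=float)
    return int(np.searchsorted(t, hi, side="left") - np.searchsorted(t, lo, side="left"))


def count_spikes(dataset: SpikeDataset, center: float, spec: WindowSpec) -> ResponseMatrix:
    """Count spikes of every neuron in every trial within the window at
    ``center``.

    Trials are concatenated per neuron in stored order; all neurons must have
    identical (image_id ordered) trial structure for the matrix to be
    meaningful, which holds for simulated datasets and for the pseudo-trial
    assemblies built by the decoder.
    """
    lo, hi = spec.bounds(center)
    rows, n_trials = [], None
    image_ids = None
    for n in dataset.neurons:
        counts = [count_in_window(t.spike_times, lo, hi) for t in n.trials]
        if n_trials is None:
            n_trials = len(counts)
            image_ids = np.array([t.image_id for t in n.trials])
        elif len(counts) != n_trials:
            raise ValidationError("neurons have unequal trial counts; subset first")
        rows.append(counts)
    cat = dataset.catalog
    expressions = np.array([cat.expression_of(i) for i in image_ids])
    return ResponseMatrix(
        counts=np.asarray(rows, dtype=int),
        neuron_ids=np.array([n.neuron_id for n in dataset.neurons]),
        image_ids=image_ids,
        expressions=expressions,
        center=center,
        width=spec.width,
    )


def firing_rate(counts: ResponseMatrix) -> np.ndarray:
    """Convert window counts to firing rates in spikes/s."""
    return counts.counts / (counts.width / 1000.0)


# ---------------------------------------------------------------------------
# file I/O


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".meta.yaml")


def write_spike_dataset(dataset: SpikeDataset, path: str | Path) -> None:
    """Write a dataset to CSV plus a YAML catalog sidecar (lossless
    roundtrip with :func:`read_spike_dataset`)."""
    dataset.validate()
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["neuron_id", "area", "trial_id", "image_id", "spike_times"])
        for n in dataset.neurons:
            for tr in n.trials:
                times = ";".join(repr(float(t)) for t in tr.spike_times)
                w.writerow([n.neuron_id, n.area, tr.trial_id, tr.image_id, times])
    meta = {
        "images": [
            {"image_id": im.image_id, "identity": im.identity, "expression": im.expression}
            for im in dataset.catalog.images
        ]
    }
    if dataset.catalog.sf_grid is not None:
        sfs, sizes = dataset.catalog.sf_grid
        meta["sf_grid"] = {"center_sfs": list(sfs), "sizes": list(sizes)}
    with open(_sidecar(path), "w") as fh:
        yaml.safe_dump(meta, fh)


def read_spike_dataset(path: str | Path) -> SpikeDataset:
    """Read a dataset written by :func:`write_spike_dataset`."""
    path = Path(path)
    with open(_sidecar(path)) as fh:
        meta = yaml.safe_load(fh)
    images = tuple(
        StimulusImage(int(d["image_id"]), d["identity"], d["expression"])
        for d in meta["images"]
    )
    grid = None
    if "sf_grid" in meta:
        grid = (tuple(meta["sf_grid"]["center_sfs"]), tuple(meta["sf_grid"]["sizes"]))
    catalog = StimulusCatalog(images, grid)

    neurons: dict[int, NeuronRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or header[:5] != ["neuron_id", "area", "trial_id", "image_id", "spike_times"]:
            raise ValidationError(f"{path}: missing or malformed header row")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                nid, area, tid, iid = int(row[0]), row[1], int(row[2]), int(row[3])
                times = np.array(
                    [float(x) for x in row[4].split(";") if x != ""], dtype=float
                )
            except (ValueError, IndexError) as exc:
                raise ValidationError(f"{path}:{lineno}: malformed row: {exc}") from exc
            rec = neurons.setdefault(nid, NeuronRecord(nid, area))
            if rec.area != area:
                raise ValidationError(f"{path}:{lineno}: inconsistent area for neuron {nid}")
            rec.trials.append(Trial(tid, iid, times))
    ds = SpikeDataset(list(neurons.values()), catalog)
    ds.validate()
    return ds
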