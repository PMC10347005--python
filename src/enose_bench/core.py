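"""Domain types and dataset plumbing for electronic-nose trials.

An electronic-nose *trial* is one exposure of a gas-sensor array to a sample:
each metal-oxide sensor produces a rising, saturating voltage trace sampled at
1 Hz over the 80 s exposure window. The traces of the S sensors are
concatenated (sensor-major, in layout order) into a single feature vector of
length ``S * samples_per_sensor``, which is the input to every downstream
augmentation and classification step. Labels are small positive integers
identifying the beverage class; a sidecar mapping may carry human-readable
variety/producer names.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SensorLayout",
    "Trial",
    "Dataset",
    "assemble_features",
    "stratified_split",
    "load_dataset",
    "save_dataset",
    "register_adapter",
    "get_adapter",
]


@dataclass(frozen=True)
class SensorLayout:
    """Sensor arrangement: which sensors, and how many samples each contributes.

    ``samples_per_sensor`` is the length of the rise-phase trace kept per
    sensor (default 80 samples at 1 Hz); the purge phase is never stored.
    """

    sensor_names: tuple[str, ...] = ("S1", "S2", "S3")
    samples_per_sensor: int = 80

    def __post_init__(self) -> None:
        if self.samples_per_sensor < 2:
            raise ValueError("samples_per_sensor must be >= 2")
        if len(self.sensor_names) < 1:
            raise ValueError("at least one sensor required")
        object.__setattr__(self, "sensor_names", tuple(self.sensor_names))

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_names)

    @property
    def n_features(self) -> int:
        return self.n_sensors * self.samples_per_sensor

    def segment_slices(self) -> list[slice]:
        """Per-sensor slices into the concatenated feature vector."""
        w = self.samples_per_sensor
        return [slice(s * w, (s + 1) * w) for s in range(self.n_sensors)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "sensor_names": list(self.sensor_names),
                "samples_per_sensor": self.samples_per_sensor,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SensorLayout":
        d = json.loads(text)
        return cls(tuple(d["sensor_names"]), int(d["samples_per_sensor"]))


@dataclass(frozen=True)
class Trial:
    """One e-nose measurement: concatenated sensor traces plus class label."""

    features: np.ndarray
    label: int
    trial_id: str
    is_synthetic: bool = False

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        if feats.ndim != 1:
            raise ValueError("features must be a 1-D vector")
        if not np.all(np.isfinite(feats)):
            raise ValueError(f"trial {self.trial_id!r} has non-finite features")
        feats.setflags(write=False)
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "label", int(self.label))


@dataclass
class Dataset:
    """Homogeneous collection of trials sharing one sensor layout.

    ``classes`` is the ordered class inventory; trials may cover a subset of
    it (e.g. after filtering), but never a label outside it.
    """

    trials: list[Trial]
    layout: SensorLayout
    classes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.trials = list(self.trials)
        if not self.classes:
            self.classes = tuple(sorted({t.label for t in self.trials}))
        self.classes = tuple(int(c) for c in self.classes)
        n = self.layout.n_features
        for t in self.trials:
            if t.features.shape[0] != n:
                raise ValueError(
                    f"trial {t.trial_id!r} has {t.features.shape[0]} features, "
                    f"layout expects {n}"
                )
            if t.label not in self.classes:
                raise ValueError(
                    f"trial {t.trial_id!r} has label {t.label} outside class "
                    f"inventory {self.classes}"
                )

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def feature_matrix(self) -> np.ndarray:
        """(n_trials, n_features) float array; a copy, safe to mutate."""
        if not self.trials:
            return np.empty((0, self.layout.n_features))
        return np.stack([t.features for t in self.trials])

    def labels(self) -> np.ndarray:
        return np.array([t.label for t in self.trials], dtype=int)

    def trial_ids(self) -> list[str]:
        return [t.trial_id for t in self.trials]

    def class_counts(self) -> dict[int, int]:
        counts = {c: 0 for c in self.classes}
        for t in self.trials:
            counts[t.label] += 1
        return counts

    def indices_of_class(self, label: int) -> list[int]:
        return [i for i, t in enumerate(self.trials) if t.label == label]

    def subset(self, indices: Iterable[int]) -> "Dataset":
        return Dataset([self.trials[i] for i in indices], self.layout, self.classes)

    def extend(self, other: "Dataset") -> "Dataset":
        """New dataset with ``other``'s trials appended; inputs untouched."""
        if other.layout.n_features != self.layout.n_features:
            raise ValueError("feature-length mismatch between datasets")
        return Dataset(self.trials + other.trials, self.layout, self.classes)


def assemble_features(
    per_sensor_series: Sequence[np.ndarray], layout: SensorLayout
) -> np.ndarray:
    """Concatenate per-sensor rise-phase traces into one feature vector.

    Binding the S sensor responses in layout order yields the
    ``S * samples_per_sensor`` input vector used throughout (240 features for
    the 3-sensor layout, 400 for 5 sensors).
    """
    if len(per_sensor_series) != layout.n_sensors:
        raise ValueError(
            f"expected {layout.n_sensors} sensor series, got {len(per_sensor_series)}"
        )
    parts = []
    for name, series in zip(layout.sensor_names, per_sensor_series):
        arr = np.asarray(series, dtype=float).ravel()
        if arr.shape[0] != layout.samples_per_sensor:
            raise ValueError(
                f"sensor {name!r}: series has {arr.shape[0]} samples, "
                f"expected {layout.samples_per_sensor}"
            )
        parts.append(arr)
    return np.concatenate(parts)


def stratified_split(
    dataset: Dataset, train_per_class: int, test_per_class: int, seed: int
) -> tuple[Dataset, Dataset]:
    """Random per-class split into disjoint train/test datasets.

    Draws exactly ``train_per_class`` + ``test_per_class`` trials from each
    class without replacement (the canonical protocol is 7 train + 5 test out
    of 12 trials per class). Deterministic for a fixed seed; train and test
    never share a trial.
    """
    if train_per_class < 0 or test_per_class < 0:
        raise ValueError("per-class counts must be non-negative")
    need = train_per_class + test_per_class
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in dataset.classes:
        members = dataset.indices_of_class(c)
        if len(members) < need:
            raise ValueError(
                f"class {c} has {len(members)} trials, need {need} "
                f"({train_per_class} train + {test_per_class} test)"
            )
        perm = rng.permutation(len(members))
        chosen = [members[i] for i in perm]
        train_idx.extend(chosen[:train_per_class])
        test_idx.extend(chosen[train_per_class:need])
    return dataset.subset(sorted(train_idx)), dataset.subset(sorted(test_idx))


# ---------------------------------------------------------------------------
# CSV persistence
#
# Dataset CSV: header trial_id,label[,is_synthetic],f0,...,f{n-1}; one trial
# per row; UTF-8. Layout travels in a JSON sidecar (<stem>.layout.json).
# ---------------------------------------------------------------------------


def _layout_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".layout.json") if path.suffix != ".csv" \
        else path.with_name(path.stem + ".layout.json")


def save_dataset(dataset: Dataset, path: str | Path) -> None:
    path = Path(path)
    n = dataset.layout.n_features
    cols = ["trial_id", "label", "is_synthetic"] + [f"f{i}" for i in range(n)]
    rows = []
    for t in dataset.trials:
        rows.append([t.trial_id, t.label, int(t.is_synthetic)] + list(t.features))
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False, float_format="%.17g")
    _layout_sidecar(path).write_text(dataset.layout.to_json())


def load_dataset(path: str | Path, layout: SensorLayout | None = None) -> Dataset:
    """Load a dataset CSV; layout from argument or the JSON sidecar."""
    path = Path(path)
    if layout is None:
        sidecar = _layout_sidecar(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no layout given and sidecar {sidecar} not found"
            )
        layout = SensorLayout.from_json(sidecar.read_text())
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no trials (empty file)") from None
    if df.empty:
        raise ValueError(f"{path}: no trials")
    n = layout.n_features
    feat_cols = [f"f{i}" for i in range(n)]
    missing = [c for c in ("trial_id", "label") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    extra = [c for c in df.columns if c.startswith("f") and c not in feat_cols]
    if extra or any(c not in df.columns for c in feat_cols):
        raise ValueError(
            f"{path}: feature columns do not match layout width {n}"
        )
    has_syn = "is_synthetic" in df.columns
    trials = []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        rowd = row._asdict()
        feats = np.array([rowd[c] for c in feat_cols], dtype=float)
        if not np.all(np.isfinite(feats)):
            raise ValueError(f"{path}: non-numeric or non-finite cell in row {row_num}")
        try:
            label = int(rowd["label"])
        except (TypeError, ValueError):
            raise ValueError(f"{path}: bad label in row {row_num}") from None
        trials.append(
            Trial(
                feats,
                label,
                str(rowd["trial_id"]),
                bool(int(rowd["is_synthetic"])) if has_syn else False,
            )
        )
    return Dataset(trials, layout)


# Adapter registry for externally deposited datasets whose on-disk dialect is
# not fixed by this package. Adapters are best-effort: callables taking a path
# and returning a Dataset.
_ADAPTERS: dict[str, Callable[..., Dataset]] = {}


def register_adapter(name: str, fn: Callable[..., Dataset]) -> None:
    _ADAPTERS[name] = fn


def get_adapter(name: str) -> Callable[..., Dataset]:
    try:
        return _ADAPTERS[name]
    except KeyError:
        raise KeyError(f"no adapter registered under {name!r}") from None
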