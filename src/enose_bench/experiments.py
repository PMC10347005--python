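"""Evaluation harness: repeated trainings, sweeps, and method comparisons.

The protocol throughout mirrors the small-sample benchmarking discipline:

* the dataset is split **once** per experiment into train and test pools
  (the test set is shared across every condition and repeat);
* augmentation sees only the training pool — the test set is never
  augmented and never supplies parents (a leakage guard asserts this on
  every run);
* each condition is repeated (default 10 trainings); by default every
  repeat redraws fresh synthetic data from its own RNG substream, so the
  reported SD reflects both training and augmentation randomness
  (``freeze_augment=True`` reuses one synthetic pool instead);
* accuracy is reported in percent, with the mean and sample SD over
  repeats always recomputable from the stored per-repeat values.

A master seed spawns labelled substreams (split / augment x repeat /
train x repeat) so any cell of a sweep is re-runnable in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .augment import AugmentConfig, augment, cv_to_bounds
from .classify import ClassifierSpec, evaluate, train
from .core import Dataset, load_dataset, stratified_split
from .synthgen import generate_dataset, scenario_config

__all__ = [
    "SweepResult",
    "ExperimentPlan",
    "child_seed",
    "run_repeated",
    "aug_size_sweep",
    "cv_sweep",
    "method_comparison",
    "moving_average_forward",
    "accuracy_table",
    "sd_table",
]


def child_seed(master_seed: int, *tags: int | str) -> int:
    """Deterministic labelled substream seed (< 2**31) from a master seed."""
    key = [int(master_seed)]
    for t in tags:
        if isinstance(t, str):
            key.extend(ord(ch) for ch in t)
        else:
            key.append(int(t))
    ss = np.random.SeedSequence(key)
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SweepResult:
    """Per-repeat accuracies for one experimental condition."""

    condition: str
    accuracies: list[float]
    degenerate_sd: bool = False  # True when repeats == 1 (SD reported as 0)

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        if len(self.accuracies) < 2:
            return 0.0
        if len(set(self.accuracies)) == 1:  # identical repeats: SD exactly 0
            return 0.0
        return float(np.std(self.accuracies, ddof=1))

    def __post_init__(self) -> None:
        if len(self.accuracies) < 1:
            raise ValueError("at least one repeat required")
        self.degenerate_sd = len(self.accuracies) == 1

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "accuracies": list(self.accuracies),
            "mean": self.mean,
            "sd": self.sd,
            "degenerate_sd": self.degenerate_sd,
        }


def _assert_no_leakage(train_ds: Dataset, test_ds: Dataset) -> None:
    overlap = set(train_ds.trial_ids()) & set(test_ds.trial_ids())
    if overlap:
        raise RuntimeError(
            f"leakage: {len(overlap)} trial ids shared between augmentation "
            f"parents and test set, e.g. {sorted(overlap)[:3]}"
        )


def run_repeated(
    train_ds: Dataset,
    test_ds: Dataset,
    spec: ClassifierSpec,
    aug_config: AugmentConfig | None,
    n_aug: int,
    repeats: int = 10,
    master_seed: int = 0,
    condition: str | None = None,
    freeze_augment: bool = False,
) -> SweepResult:
    """Train/evaluate one condition ``repeats`` times on a fixed split.

    ``n_aug = 0`` (or ``aug_config is None``) bypasses augmentation and
    trains on the raw pool. Otherwise each repeat augments the training pool
    with a fresh synthetic draw (its own substream), trains with a
    repeat-specific seed, and scores on the untouched test set.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    _assert_no_leakage(train_ds, test_ds)
    # Deterministic classifiers (one-vs-one linear SVM, with or without PCA)
    # always see one frozen synthetic pool: repeated trainings are then
    # genuinely identical, which is what their zero repeat-to-repeat SD means.
    if spec.kind in ("msvm", "pca_msvm"):
        freeze_augment = True
    accs = []
    frozen_pool: Dataset | None = None
    for r in range(repeats):
        if aug_config is not None and n_aug > 0:
            if freeze_augment:
                if frozen_pool is None:
                    cfg = replace(aug_config, n_synthetic=n_aug)
                    rng = np.random.default_rng(
                        child_seed(master_seed, "augment", 0)
                    )
                    frozen_pool = augment(train_ds, cfg, rng)
                pool = train_ds.extend(frozen_pool)
            else:
                cfg = replace(aug_config, n_synthetic=n_aug)
                rng = np.random.default_rng(child_seed(master_seed, "augment", r))
                pool = train_ds.extend(augment(train_ds, cfg, rng))
            _assert_no_leakage(pool, test_ds)
        else:
            pool = train_ds
        model = train(spec, pool, seed=child_seed(master_seed, "train", r))
        accs.append(evaluate(model, test_ds).accuracy)
    label = condition if condition is not None else f"{spec.name}/{n_aug}AD"
    return SweepResult(label, accs)


def aug_size_sweep(
    train_ds: Dataset,
    test_ds: Dataset,
    specs: Sequence[ClassifierSpec],
    aug_config: AugmentConfig,
    sizes: Sequence[int] = (0, 100, 500, 2000),
    repeats: int = 10,
    master_seed: int = 0,
    freeze_augment: bool = False,
) -> dict[tuple[str, int], SweepResult]:
    """One repeated condition per (classifier, augmentation size) cell."""
    if any(s < 0 for s in sizes):
        raise ValueError("augmentation sizes must be non-negative")
    results: dict[tuple[str, int], SweepResult] = {}
    for spec in specs:
        for size in sizes:
            results[(spec.name, size)] = run_repeated(
                train_ds,
                test_ds,
                spec,
                aug_config,
                size,
                repeats=repeats,
                master_seed=child_seed(master_seed, spec.name, size),
                condition=f"{spec.name}/{size}AD",
                freeze_augment=freeze_augment,
            )
    return results


def accuracy_table(results: dict[tuple[str, int], SweepResult]) -> pd.DataFrame:
    """Mean-accuracy matrix, classifiers x sizes, 2-decimal granularity."""
    names = list(dict.fromkeys(k[0] for k in results))
    sizes = sorted({k[1] for k in results})
    data = {
        f"{s} AD": [round(results[(n, s)].mean, 2) for n in names] for s in sizes
    }
    return pd.DataFrame(data, index=names)


def sd_table(results: dict[tuple[str, int], SweepResult]) -> pd.DataFrame:
    names = list(dict.fromkeys(k[0] for k in results))
    sizes = sorted({k[1] for k in results})
    data = {
        f"{s} AD": [round(results[(n, s)].sd, 2) for n in names] for s in sizes
    }
    return pd.DataFrame(data, index=names)


def moving_average_forward(values: Sequence[float], window: int = 11) -> np.ndarray:
    """Forward moving average: each value with its (window-1) successors.

    Truncated at the tail: positions with fewer successors average over the
    available suffix. A constant series is a fixed point.
    """
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    for i in range(v.size):
        out[i] = v[i : i + window].mean()
    return out


def cv_sweep(
    train_ds: Dataset,
    test_ds: Dataset,
    spec: ClassifierSpec,
    cv_grid: Sequence[float],
    n_aug: int = 500,
    k: int = 3,
    repeats: int = 10,
    master_seed: int = 0,
) -> tuple[list[SweepResult], np.ndarray]:
    """Sweep the alpha-interval half-width: per cv, bounds = (0.5-cv, 0.5+cv),
    ``n_aug`` synthetic trials, repeated training; returns the per-cv results
    and the window-11 forward moving average of the mean accuracies."""
    grid = list(cv_grid)
    if any(c <= 0 for c in grid):
        raise ValueError("cv values must be positive")
    if any(b >= a for a, b in zip(grid[1:], grid[:-1])):
        raise ValueError("cv grid must be strictly increasing")
    results = []
    for i, cv in enumerate(grid):
        c1, c2 = cv_to_bounds(cv)
        cfg = AugmentConfig(
            method="interp_extrap", n_synthetic=n_aug, k=k, c1=c1, c2=c2
        )
        results.append(
            run_repeated(
                train_ds,
                test_ds,
                spec,
                cfg,
                n_aug,
                repeats=repeats,
                master_seed=child_seed(master_seed, "cv", i),
                condition=f"cv={cv:g}",
            )
        )
    smoothed = moving_average_forward([r.mean for r in results], window=11)
    return results, smoothed


def method_comparison(
    train_ds: Dataset,
    test_ds: Dataset,
    spec: ClassifierSpec,
    methods: Sequence[str] = (
        "interp_extrap",
        "stretch",
        "gaussian_and_stretch",
        "smote",
        "gaussian",
    ),
    sizes: Sequence[int] = (100, 500, 2000),
    repeats: int = 10,
    master_seed: int = 0,
    k: int = 3,
    c1: float = -2.0,
    c2: float = 3.0,
    sigma: float = 0.05,
    stretch_alpha: float = 0.1,
) -> pd.DataFrame:
    """Mean-accuracy table, augmentation methods x synthetic counts.

    Canonical parameter set: k = 3 for the kNN methods, interval (-2, 3)
    for interpolation–extrapolation, sigma = 0.05 and stretch factor 0.1
    for the noise/stretch family.
    """
    if not methods:
        raise ValueError("at least one method required")
    rows = {}
    for m in methods:
        cfg = AugmentConfig(
            method=m, k=k, c1=c1, c2=c2, sigma=sigma, stretch_alpha=stretch_alpha
        )
        cells = []
        for size in sizes:
            res = run_repeated(
                train_ds,
                test_ds,
                spec,
                cfg,
                size,
                repeats=repeats,
                master_seed=child_seed(master_seed, m, size),
                condition=f"{m}/{size}AD",
            )
            cells.append(round(res.mean, 2))
        rows[m] = cells
    return pd.DataFrame(rows, index=[f"{s} AD" for s in sizes]).T


# ---------------------------------------------------------------------------
# Plan files
# ---------------------------------------------------------------------------


@dataclass
class ExperimentPlan:
    """Declarative description of a full sweep, loadable from YAML.

    ``dataset`` is either a CSV path or a generator scenario name
    ('separable' / 'overlapping' / 'chance').
    """

    dataset: str = "overlapping"
    trials_per_class: int = 12
    train_per_class: int = 7
    test_per_class: int = 5
    classifiers: list[ClassifierSpec] = field(
        default_factory=lambda: [ClassifierSpec(kind="ann", nl=3, nu=50)]
    )
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    sizes: list[int] = field(default_factory=lambda: [0, 100, 500, 2000])
    repeats: int = 10
    master_seed: int = 0
    freeze_augment: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentPlan":
        d = yaml.safe_load(Path(path).read_text()) or {}
        specs = [
            ClassifierSpec(**c) for c in d.get("classifiers", [{"kind": "ann"}])
        ]
        aug = AugmentConfig(**d.get("augment", {}))
        keys = (
            "dataset",
            "trials_per_class",
            "train_per_class",
            "test_per_class",
            "sizes",
            "repeats",
            "master_seed",
            "freeze_augment",
        )
        kw = {kk: d[kk] for kk in keys if kk in d}
        return cls(classifiers=specs, augment=aug, **kw)

    def resolve_dataset(self) -> Dataset:
        if Path(self.dataset).suffix == ".csv":
            return load_dataset(self.dataset)
        cfg = scenario_config(
            self.dataset, seed=child_seed(self.master_seed, "generate")
        )
        return generate_dataset(cfg, self.trials_per_class)

    def split(self, ds: Dataset):
        return stratified_split(
            ds,
            self.train_per_class,
            self.test_per_class,
            seed=child_seed(self.master_seed, "split"),
        )

    def run(self) -> dict[tuple[str, int], SweepResult]:
        ds = self.resolve_dataset()
        train_ds, test_ds = self.split(ds)
        return aug_size_sweep(
            train_ds,
            test_ds,
            self.classifiers,
            self.augment,
            self.sizes,
            repeats=self.repeats,
            master_seed=self.master_seed,
            freeze_augment=self.freeze_augment,
        )
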