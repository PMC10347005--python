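"""Feature-space data augmentation for small e-nose training sets.

Four methods share one contract (original data in, synthetic trials out,
labels preserved, originals never mutated):

* **Interpolation–extrapolation** — the centerpiece. A synthetic vector is
  ``X_N = X_i + alpha * (X_j - X_i)`` where the anchor ``X_i`` is drawn
  uniformly from the training pool, the partner ``X_j`` uniformly from the
  anchor's k nearest same-class neighbours (Euclidean), and
  ``alpha ~ Uniform(c1, c2)``. With ``c1 < 0`` or ``c2 > 1`` the synthetic
  point can lie beyond the segment joining the parents, so the method
  extrapolates as well as interpolates. Defaults ``c1=-2, c2=3, k=3``.
* **SMOTE** — the special case with the alpha interval pinned to ``[0, 1]``
  (pure interpolation). Implemented by delegation so that, seed for seed, it
  is bit-identical to interpolation–extrapolation at bounds (0, 1).
* **Gaussian noise** — a randomly chosen original plus i.i.d. zero-mean
  Gaussian perturbation per component (default sigma 0.05 V).
* **Signal stretching** — a shortened prefix of each per-sensor trace is
  linearly resampled back to full length, emulating a slower sensor
  response; combined noise+stretch emits one of each per drawn parent.

The alpha interval can be parameterized by a single half-width ``cv``
centred at 0.5: ``c1 = 0.5 - cv``, ``c2 = 0.5 + cv``; ``cv = 0.5`` recovers
pure interpolation and ``cv = 2.5`` the default (-2, 3) interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Dataset, Trial

__all__ = [
    "AugmentConfig",
    "cv_to_bounds",
    "k_nearest_same_class",
    "interp_extrap_sample",
    "augment_interp_extrap",
    "augment_smote",
    "augment_gaussian",
    "stretch_series",
    "augment_noise_and_stretch",
    "augment",
]

METHODS = ("interp_extrap", "smote", "gaussian", "stretch", "gaussian_and_stretch")


@dataclass(frozen=True)
class AugmentConfig:
    """Method selector plus every knob any of the methods uses.

    ``n_synthetic`` is the exact number of synthetic trials to emit; ``k``
    the neighbour count for the kNN-based methods; ``c1``/``c2`` the alpha
    bounds for interpolation–extrapolation; ``sigma`` the noise SD in volts;
    ``stretch_alpha`` the stretch factor in (0, 1).
    """

    method: str = "interp_extrap"
    n_synthetic: int = 500
    k: int = 3
    c1: float = -2.0
    c2: float = 3.0
    sigma: float = 0.05
    stretch_alpha: float = 0.1
    seed: int = 0
    eq5_literal: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; one of {METHODS}")
        if self.n_synthetic < 0:
            raise ValueError("n_synthetic must be non-negative")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.method == "interp_extrap" and not self.c1 < self.c2:
            raise ValueError("require c1 < c2")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def cv_to_bounds(cv: float) -> tuple[float, float]:
    """Alpha bounds from the half-width parameter: (0.5 - cv, 0.5 + cv).

    cv = 0.5 gives (0, 1), interpolation only; cv = 2.5 gives (-2, 3).
    """
    if cv <= 0:
        raise ValueError("cv must be positive")
    return (0.5 - cv, 0.5 + cv)


def k_nearest_same_class(
    dataset: Dataset, anchor_index: int, k: int
) -> list[int]:
    """Indices of up to k same-class nearest neighbours of the anchor.

    Euclidean distance on raw feature vectors; the anchor itself is
    excluded; ties broken by lower index (stable sort) for determinism.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    anchor = dataset.trials[anchor_index]
    candidates = [
        i for i in dataset.indices_of_class(anchor.label) if i != anchor_index
    ]
    if not candidates:
        raise ValueError(
            f"class {anchor.label} is a singleton: no same-class partner "
            f"for trial {anchor.trial_id!r}"
        )
    diffs = np.stack([dataset.trials[i].features for i in candidates]) - anchor.features
    dists = np.linalg.norm(diffs, axis=1)
    order = np.argsort(dists, kind="stable")
    return [candidates[i] for i in order[:k]]


def interp_extrap_sample(
    xi: np.ndarray, xj: np.ndarray, alpha: float
) -> np.ndarray:
    """Affine combination ``xi + alpha * (xj - xi)`` of two parent vectors."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise ValueError(f"parent length mismatch: {xi.shape} vs {xj.shape}")
    return xi + alpha * (xj - xi)


def _draw_interp_extrap(
    train: Dataset,
    n_synthetic: int,
    k: int,
    c1: float,
    c2: float,
    rng: np.random.Generator,
    tag: str,
) -> Dataset:
    # Neighbour lists are a pure function of the training pool; cache per anchor.
    knn_cache: dict[int, list[int]] = {}
    trials = []
    for s in range(n_synthetic):
        anchor_idx = int(rng.integers(len(train)))
        if anchor_idx not in knn_cache:
            knn_cache[anchor_idx] = k_nearest_same_class(train, anchor_idx, k)
        neighbours = knn_cache[anchor_idx]
        partner_idx = neighbours[int(rng.integers(len(neighbours)))]
        alpha = float(rng.uniform(c1, c2))
        anchor = train.trials[anchor_idx]
        partner = train.trials[partner_idx]
        feats = interp_extrap_sample(anchor.features, partner.features, alpha)
        trials.append(
            Trial(feats, anchor.label, f"{tag}_{s:05d}", is_synthetic=True)
        )
    return Dataset(trials, train.layout, train.classes)


def augment_interp_extrap(
    train: Dataset, config: AugmentConfig, rng: np.random.Generator | None = None
) -> Dataset:
    """Generate ``config.n_synthetic`` interpolation–extrapolation trials."""
    if not config.c1 < config.c2:
        raise ValueError("require c1 < c2")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _draw_interp_extrap(
        train, config.n_synthetic, config.k, config.c1, config.c2, rng, "syn"
    )


def augment_smote(
    train: Dataset,
    n_synthetic: int,
    k: int = 3,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> Dataset:
    """SMOTE-style interpolation: alpha restricted to [0, 1].

    Shares the sampling protocol of :func:`augment_interp_extrap`, so with
    the same RNG state the two produce identical outputs at bounds (0, 1).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    return _draw_interp_extrap(train, n_synthetic, k, 0.0, 1.0, rng, "syn")


def augment_gaussian(
    train: Dataset,
    n_synthetic: int,
    sigma: float = 0.05,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> Dataset:
    """Each synthetic trial = random original + i.i.d. N(0, sigma^2) noise."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if len(train) == 0:
        raise ValueError("empty training pool")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = train.layout.n_features
    trials = []
    for s in range(n_synthetic):
        parent = train.trials[int(rng.integers(len(train)))]
        eps = rng.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)
        trials.append(
            Trial(parent.features + eps, parent.label, f"gn_{s:05d}", is_synthetic=True)
        )
    return Dataset(trials, train.layout, train.classes)


def stretch_series(
    x: np.ndarray, stretch_alpha: float, eq5_literal: bool = False
) -> np.ndarray:
    """Stretch one time series: resample a shortened prefix back to length n.

    Default reading: keep the first ``m = round(n / (1 + alpha))`` samples
    (m < n for alpha > 0) and linearly interpolate them onto n equally spaced
    positions, so the output is a slowed copy of the early response. The
    alternative literal reading ``m = round(n * (1 + alpha))`` upsamples the
    series to m points and keeps the first n, which compresses by the same
    factor from the opposite direction; it is available behind
    ``eq5_literal`` for comparison.
    """
    if not 0 < stretch_alpha < 1:
        raise ValueError("stretch_alpha must lie in (0, 1)")
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("series must have at least 2 samples")
    if eq5_literal:
        m = int(round(n * (1 + stretch_alpha)))
        up = np.interp(np.linspace(0.0, n - 1, m), np.arange(n), x)
        return up[:n]
    m = int(round(n / (1 + stretch_alpha)))
    m = max(m, 2)
    prefix = x[:m]
    return np.interp(np.linspace(0.0, m - 1, n), np.arange(m), prefix)


def _stretch_trial(
    trial: Trial, train: Dataset, stretch_alpha: float, eq5_literal: bool
) -> np.ndarray:
    # Stretch per sensor segment: a stretch across sensor boundaries would
    # mix channels that are independent time series.
    out = np.empty_like(trial.features)
    for seg in train.layout.segment_slices():
        out[seg] = stretch_series(trial.features[seg], stretch_alpha, eq5_literal)
    return out


def augment_noise_and_stretch(
    train: Dataset,
    T: int,
    sigma: float = 0.05,
    stretch_alpha: float = 0.1,
    rng: np.random.Generator | None = None,
    seed: int = 0,
    eq5_literal: bool = False,
) -> Dataset:
    """Draw T parents; emit one Gaussian-noise and one stretched trial each.

    Emits exactly 2T synthetic trials (trial ids tagged ``_noise`` /
    ``_stretch``).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if len(train) == 0:
        raise ValueError("empty training pool")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = train.layout.n_features
    trials = []
    for s in range(T):
        parent = train.trials[int(rng.integers(len(train)))]
        eps = rng.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)
        trials.append(
            Trial(
                parent.features + eps,
                parent.label,
                f"ns_{s:05d}_noise",
                is_synthetic=True,
            )
        )
        trials.append(
            Trial(
                _stretch_trial(parent, train, stretch_alpha, eq5_literal),
                parent.label,
                f"ns_{s:05d}_stretch",
                is_synthetic=True,
            )
        )
    return Dataset(trials, train.layout, train.classes)


def _stretch_only(
    train: Dataset,
    n_synthetic: int,
    stretch_alpha: float,
    rng: np.random.Generator,
    eq5_literal: bool,
) -> Dataset:
    if len(train) == 0:
        raise ValueError("empty training pool")
    trials = []
    for s in range(n_synthetic):
        parent = train.trials[int(rng.integers(len(train)))]
        trials.append(
            Trial(
                _stretch_trial(parent, train, stretch_alpha, eq5_literal),
                parent.label,
                f"st_{s:05d}",
                is_synthetic=True,
            )
        )
    return Dataset(trials, train.layout, train.classes)


def augment(
    train: Dataset, config: AugmentConfig, rng: np.random.Generator | None = None
) -> Dataset:
    """Dispatch on ``config.method``; always emits ``n_synthetic`` trials."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.method
    if m == "interp_extrap":
        return augment_interp_extrap(train, config, rng)
    if m == "smote":
        return augment_smote(train, config.n_synthetic, config.k, rng)
    if m == "gaussian":
        return augment_gaussian(train, config.n_synthetic, config.sigma, rng)
    if m == "stretch":
        return _stretch_only(
            train, config.n_synthetic, config.stretch_alpha, rng, config.eq5_literal
        )
    if m == "gaussian_and_stretch":
        # N = 2T trials; odd requests round T up then truncate to the exact count.
        T = (config.n_synthetic + 1) // 2
        if config.n_synthetic == 0:
            return Dataset([], train.layout, train.classes)
        out = augment_noise_and_stretch(
            train,
            T,
            config.sigma,
            config.stretch_alpha,
            rng,
            eq5_literal=config.eq5_literal,
        )
        return Dataset(
            out.trials[: config.n_synthetic], train.layout, train.classes
        )
    raise ValueError(f"unknown method {m!r}")
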