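"""Synthetic severely class-imbalanced classification datasets.

Dermoscopic-lesion benchmarks such as HAM10000 and ISIC2019 are dominated by
a single class (melanocytic nevi) with several clinically critical classes
below 5% of samples.  The generator here reproduces that *imbalance
structure* with Gaussian class-conditional features, so the optimizer and
privacy machinery can be exercised end-to-end without image data or
downloads: class counts come from largest-remainder apportionment of the
configured proportions, class centroids sit on a sphere of radius
``class_mean_separation`` (random directions, deterministic in the seed; for
``K <= d`` the directions are orthonormal, giving equal pairwise centroid
distances), and features are isotropic Gaussians around the centroids.

The two presets are deliberately *approximate* emulations: they match the
class count, dominant-class share and few-shot tail of the real datasets,
not the exact per-class counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "LabelledDataset",
    "largest_remainder_counts",
    "generate_gaussian_mixture",
    "ham10000_like_preset",
    "isic2019_like_preset",
    "train_val_split",
    "write_dataset",
    "read_dataset",
]

LARGE_SHOT = "large_shot"
FEW_SHOT = "few_shot"


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the Gaussian-mixture generator."""

    n_samples: int
    class_proportions: tuple
    n_features: int = 10
    class_mean_separation: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        props = tuple(float(p) for p in self.class_proportions)
        object.__setattr__(self, "class_proportions", props)
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if self.class_mean_separation <= 0 or self.noise_sd <= 0:
            raise ValueError("class_mean_separation and noise_sd must be positive")
        if len(props) < 2:
            raise ValueError("need at least two classes")
        if any(p <= 0 for p in props):
            raise ValueError("every class proportion must be > 0")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {sum(props)}")

    @property
    def n_classes(self) -> int:
        return len(self.class_proportions)


@dataclass
class LabelledDataset:
    """Feature matrix, integer labels and class metadata."""

    features: np.ndarray
    labels: np.ndarray
    class_counts: np.ndarray
    group_map: dict

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.class_counts = np.asarray(self.class_counts, dtype=int)
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels must have equal length")
        realized = np.bincount(self.labels, minlength=len(self.class_counts))
        if not np.array_equal(realized, self.class_counts):
            raise ValueError("class_counts inconsistent with labels")
        if set(self.group_map) != set(range(len(self.class_counts))):
            raise ValueError("group_map must cover every class exactly")

    @property
    def n_classes(self) -> int:
        return len(self.class_counts)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def __len__(self) -> int:
        return self.labels.shape[0]


def largest_remainder_counts(n: int, proportions) -> np.ndarray:
    """Apportion ``n`` samples to classes, conserving ``n`` exactly.

    Floors of ``n * p_k`` plus one extra for the largest fractional
    remainders (ties broken toward lower class index).
    """
    props = np.asarray(proportions, dtype=float)
    quotas = n * props
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    if remainder > 0:
        frac = quotas - counts
        order = np.lexsort((np.arange(len(props)), -frac))
        counts[order[:remainder]] += 1
    if np.any(counts == 0):
        raise ValueError(
            f"apportionment of n={n} gives an empty class "
            f"(counts {counts.tolist()}); increase n_samples"
        )
    return counts


def _dominant_group_map(counts) -> dict:
    dominant = int(np.argmax(counts))
    return {k: (LARGE_SHOT if k == dominant else FEW_SHOT) for k in range(len(counts))}


def _class_centroids(K: int, d: int, separation: float, rng: np.random.Generator) -> np.ndarray:
    raw = rng.standard_normal((d, max(K, 1)))
    if K <= d:
        # Orthonormal directions: every pair of centroids is separation*sqrt(2) apart.
        q, _ = np.linalg.qr(raw[:, :K])
        dirs = q.T
    else:
        dirs = raw[:, :K].T
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return separation * dirs


def generate_gaussian_mixture(config: SyntheticConfig) -> LabelledDataset:
    """Draw an imbalanced Gaussian-mixture dataset, deterministic in the seed."""
    counts = largest_remainder_counts(config.n_samples, config.class_proportions)
    rng = np.random.default_rng(config.seed)
    centroids = _class_centroids(
        config.n_classes, config.n_features, config.class_mean_separation, rng
    )
    features = np.empty((config.n_samples, config.n_features))
    labels = np.empty(config.n_samples, dtype=int)
    row = 0
    for k, c in enumerate(counts):
        features[row : row + c] = centroids[k] + config.noise_sd * rng.standard_normal(
            (c, config.n_features)
        )
        labels[row : row + c] = k
        row += c
    perm = rng.permutation(config.n_samples)
    return LabelledDataset(
        features=features[perm],
        labels=labels[perm],
        class_counts=counts,
        group_map=_dominant_group_map(counts),
    )


def ham10000_like_preset(n_samples: int = 10015, seed: int = 0, **overrides) -> SyntheticConfig:
    """7-class config with one dominant class (~67%) and a few-shot tail.

    Approximate emulation of the HAM10000 imbalance structure (class 0 stands
    in for melanocytic nevi); not the exact per-class counts.
    """
    props = (0.67, 0.11, 0.11, 0.05, 0.033, 0.015, 0.012)
    return SyntheticConfig(
        n_samples=n_samples, class_proportions=props, seed=seed, **overrides
    )


def isic2019_like_preset(n_samples: int = 25331, seed: int = 0, **overrides) -> SyntheticConfig:
    """8-class config dominated by one class, with four classes below 5%.

    Approximate emulation of the ISIC2019 imbalance structure (class 0 stands
    in for melanocytic nevi, the last for squamous cell carcinoma).
    """
    props = (0.51, 0.18, 0.13, 0.10, 0.034, 0.025, 0.011, 0.01)
    return SyntheticConfig(
        n_samples=n_samples, class_proportions=props, seed=seed, **overrides
    )


def train_val_split(
    dataset: LabelledDataset,
    fraction: float = 0.8,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[LabelledDataset, LabelledDataset]:
    """Disjoint, exhaustive train/validation split.

    Stratified (default) keeps per-class proportions to within rounding and
    requires at least one sample per class on each side.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    n = len(dataset)
    if stratified:
        train_idx: list = []
        val_idx: list = []
        for k in range(dataset.n_classes):
            idx = np.flatnonzero(dataset.labels == k)
            n_k = len(idx)
            n_train = int(np.floor(fraction * n_k + 0.5))
            n_train = min(max(n_train, 1), n_k - 1)
            if n_k < 2:
                raise ValueError(
                    f"class {k} has {n_k} samples; stratified split impossible"
                )
            idx = rng.permutation(idx)
            train_idx.append(idx[:n_train])
            val_idx.append(idx[n_train:])
        train_idx = np.concatenate(train_idx)
        val_idx = np.concatenate(val_idx)
    else:
        perm = rng.permutation(n)
        n_train = int(np.floor(fraction * n + 0.5))
        train_idx, val_idx = perm[:n_train], perm[n_train:]

    def subset(idx: np.ndarray) -> LabelledDataset:
        labels = dataset.labels[idx]
        return LabelledDataset(
            features=dataset.features[idx],
            labels=labels,
            class_counts=np.bincount(labels, minlength=dataset.n_classes),
            group_map=dict(dataset.group_map),
        )

    return subset(np.sort(train_idx)), subset(np.sort(val_idx))


def write_dataset(dataset: LabelledDataset, path, sidecar: bool = False) -> None:
    """Write features + label as CSV (columns ``f0..f{d-1}, label``).

    With ``sidecar=True`` a ``<path>.json`` with class counts and the
    few-shot/large-shot grouping is written next to it.
    """
    d = dataset.n_features
    df = pd.DataFrame(dataset.features, columns=[f"f{i}" for i in range(d)])
    df["label"] = dataset.labels
    df.to_csv(path, index=False)
    if sidecar:
        meta = {
            "n_samples": len(dataset),
            "n_features": d,
            "class_counts": dataset.class_counts.tolist(),
            "group_map": {str(k): v for k, v in dataset.group_map.items()},
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_dataset(path, group_map: dict | None = None) -> LabelledDataset:
    """Read a dataset CSV written by :func:`write_dataset`.

    The decimal separator is always the point regardless of locale.  If no
    ``group_map`` is given, the most frequent class is marked large-shot.
    """
    try:
        df = pd.read_csv(path, decimal=".")
    except pd.errors.ParserError as exc:  # pandas reports the offending line
        raise ValueError(f"malformed dataset CSV {path}: {exc}") from exc
    if "label" not in df.columns:
        raise ValueError(f"dataset CSV {path} is missing the 'label' column")
    feature_cols = [c for c in df.columns if c != "label"]
    features = df[feature_cols].to_numpy(dtype=float)
    if not np.issubdtype(df["label"].dtype, np.integer):
        if not np.allclose(df["label"] % 1, 0):
            raise ValueError(f"dataset CSV {path}: labels must be integers")
    labels = df["label"].to_numpy(dtype=int)
    if labels.min() < 0:
        raise ValueError(f"dataset CSV {path}: negative class label")
    counts = np.bincount(labels)
    if np.any(counts == 0):
        raise ValueError(f"dataset CSV {path}: class indices must be contiguous")
    return LabelledDataset(
        features=features,
        labels=labels,
        class_counts=counts,
        group_map=group_map or _dominant_group_map(counts),
    )
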