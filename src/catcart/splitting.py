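"""Seeded train/validation splits and k-fold assignments."""

from __future__ import annotations

import numpy as np

__all__ = ["SplitIndices", "split_train_validation", "kfold_indices",
           "stratified_kfold_indices"]

from dataclasses import dataclass


@dataclass(frozen=True)
class SplitIndices:
    training: np.ndarray
    validation: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        both = np.concatenate([self.training, self.validation])
        if len(np.unique(both)) != len(both):
            raise ValueError("training and validation sets overlap")


def split_train_validation(n: int, fraction: float, seed: int) -> SplitIndices:
    """Random split with training size floor(fraction * n)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if n < 2:
        raise ValueError("need at least two records to split")
    n_train = int(np.floor(fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves an empty partition")
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndices(
        training=np.sort(perm[:n_train]),
        validation=np.sort(perm[n_train:]),
        seed=seed,
    )


def kfold_indices(n: int, k: int, seed: int) -> np.ndarray:
    """Fold assignment per record; fold sizes differ by at most one."""
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}]")
    perm = np.random.default_rng(seed).permutation(n)
    folds = np.empty(n, dtype=int)
    folds[perm] = np.arange(n) % k
    return folds


def stratified_kfold_indices(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """K-fold assignment balanced within each class label."""
    labels = np.asarray(labels)
    n = len(labels)
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}]")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    start = 0  # rotate fold ids across strata so small classes spread out
    for label in np.unique(labels):
        idx = np.flatnonzero(labels == label)
        idx = rng.permutation(idx)
        folds[idx] = (start + np.arange(len(idx))) % k
        start += len(idx)
    return folds
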