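"""Min-max normalization and the stratified train/test partition.

Numeric variables are rescaled to [0, 1] with bounds learned on training
rows only; binary 0/1 variables pass through untouched.  Values seen at
predict time outside the training range are clipped into [0, 1], which
also keeps them inside the fuzzy partitions downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .schema import LABEL, NUMERIC_FEATURES, column_spec


class ConstantFeatureError(ValueError):
    """A feature with a single observed value cannot be min-max scaled."""


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature (min, max) bounds learned on the training rows."""

    bounds: dict[str, tuple[float, float]]

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.bounds)

    def to_dict(self) -> dict:
        return {name: [lo, hi] for name, (lo, hi) in self.bounds.items()}

    @classmethod
    def from_dict(cls, payload: dict) -> "NormalizationParams":
        return cls({name: (float(lo), float(hi)) for name, (lo, hi) in payload.items()})


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint positional train/test indices covering all rows."""

    train: np.ndarray
    test: np.ndarray
    seed: Optional[int] = None


def fit_normalizer(train: pd.DataFrame, features: Optional[Sequence[str]] = None
                   ) -> NormalizationParams:
    """Learn min/max bounds per numeric feature on training rows.

    Raises :class:`ConstantFeatureError` for a constant column — such a
    column should have been removed by the quasi-constant filter first.
    """
    if features is None:
        features = [f for f in NUMERIC_FEATURES if f in train.columns]
    bounds: dict[str, tuple[float, float]] = {}
    for name in features:
        if name not in train.columns:
            raise KeyError(f"feature {name!r} not present in cohort")
        x = train[name].to_numpy(dtype=float)
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            raise ConstantFeatureError(
                f"feature {name!r} is constant on the training rows; "
                "remove it with drop_quasi_constant before normalizing")
        bounds[name] = (lo, hi)
    return NormalizationParams(bounds)


def apply_normalizer(params: NormalizationParams, cohort: pd.DataFrame) -> pd.DataFrame:
    """Scale numeric features to [0, 1] (with clipping); pass binaries through."""
    out = cohort.copy()
    for name, (lo, hi) in params.bounds.items():
        if name not in out.columns:
            raise KeyError(f"feature {name!r} not present in cohort")
        out[name] = np.clip((out[name].to_numpy(dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    return out


def split_cohort(cohort: pd.DataFrame, test_fraction: float = 0.2,
                 seed: Optional[int] = None, stratified: bool = True) -> SplitIndices:
    """Partition rows into train/test sets.

    The test size is round(test_fraction * n) with half-way ties going to
    the test set.  Stratification allocates test slots per outcome class
    by largest remainder, preserving the class ratio within one patient.
    """
    n = len(cohort)
    if n < 5:
        raise ValueError("cohort too small to split (need n >= 5)")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    n_test = int(np.floor(test_fraction * n + 0.5))
    rng = np.random.default_rng(seed)

    if not stratified:
        perm = rng.permutation(n)
        test = np.sort(perm[:n_test])
        train = np.sort(perm[n_test:])
        return SplitIndices(train=train, test=test, seed=seed)

    if LABEL not in cohort.columns:
        raise ValueError("stratified split requires the label column")
    y = cohort[LABEL].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("stratified split requires both outcome classes")

    ideal = n_test * counts / n
    alloc = np.floor(ideal).astype(int)
    remainder = ideal - alloc
    # Assign leftover test slots to the classes with largest remainder;
    # ties break on class order for determinism.
    for idx in np.argsort(-remainder, kind="stable")[: n_test - alloc.sum()]:
        alloc[idx] += 1

    test_parts = []
    for cls, k in zip(classes, alloc):
        members = np.flatnonzero(y == cls)
        picked = rng.permutation(len(members))[:k]
        test_parts.append(members[picked])
    test = np.sort(np.concatenate(test_parts))
    mask = np.ones(n, dtype=bool)
    mask[test] = False
    train = np.flatnonzero(mask)
    return SplitIndices(train=train, test=test, seed=seed)
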