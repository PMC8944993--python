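"""Input normalization, outcome codification, and dataset partitioning.

Inputs are scaled to [0.1, 0.9] by the min-max map

    y = 0.8 * (x - x_min) / (x_max - x_min) + 0.1

with per-feature bounds learned from a fitting partition (by default the
training rows only, to avoid information leakage; fitting on all rows is
available as a flag).  Held-out values falling outside the fitted range are
clipped to [0.1, 0.9] by default.  Outcomes are codified for the network as
SGA -> 0.5 and AGA -> 1.0.  Splitting assigns every mother/neonate to
exactly one of train / validation / independent_test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import AGA, FEATURE_NAMES, SGA, TARGET_CODES

TRAIN = "train"
VALIDATION = "validation"
INDEPENDENT_TEST = "independent_test"
PARTITIONS = (TRAIN, VALIDATION, INDEPENDENT_TEST)


@dataclass
class NormalizationParams:
    """Per-feature (x_min, x_max) bounds defining the affine map to [0.1, 0.9]."""

    feature_names: list[str]
    x_min: np.ndarray
    x_max: np.ndarray

    def __post_init__(self) -> None:
        self.x_min = np.asarray(self.x_min, dtype=float).ravel()
        self.x_max = np.asarray(self.x_max, dtype=float).ravel()
        n = len(self.feature_names)
        if self.x_min.shape != (n,) or self.x_max.shape != (n,):
            raise ValueError("bounds must have one (min, max) pair per feature")
        if not np.all(self.x_max > self.x_min):
            bad = [f for f, lo, hi in
                   zip(self.feature_names, self.x_min, self.x_max) if hi <= lo]
            raise ValueError(f"x_max must exceed x_min; degenerate feature(s): {bad}")

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "x_min": self.x_min.tolist(),
            "x_max": self.x_max.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(list(d["feature_names"]), np.asarray(d["x_min"]),
                   np.asarray(d["x_max"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "NormalizationParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_normalizer(cohort: pd.DataFrame, rows=None,
                   feature_names: list[str] | None = None) -> NormalizationParams:
    """Learn per-feature (min, max) on the selected rows.

    ``rows`` is any pandas row selector (boolean mask, index array or None
    for all rows).  A feature that is constant on the selection makes the
    map undefined and raises, naming the feature.
    """
    feature_names = list(feature_names or FEATURE_NAMES)
    sub = cohort if rows is None else cohort.loc[rows]
    if len(sub) == 0:
        raise ValueError("cannot fit normalizer on an empty selection")
    X = sub[feature_names].to_numpy(dtype=float)
    x_min = X.min(axis=0)
    x_max = X.max(axis=0)
    constant = [f for f, lo, hi in zip(feature_names, x_min, x_max) if hi == lo]
    if constant:
        raise ValueError(
            f"feature(s) constant on the fitting rows, normalization undefined: {constant}")
    return NormalizationParams(feature_names, x_min, x_max)


def binary_normalizer_bounds(params: NormalizationParams,
                             binary_features: list[str] = ("mvi",)) -> NormalizationParams:
    """Force (min, max) = (0, 1) for binary features so no/yes map to 0.1/0.9
    regardless of which categories the fitting rows happened to contain."""
    x_min = params.x_min.copy()
    x_max = params.x_max.copy()
    for name in binary_features:
        if name in params.feature_names:
            i = params.feature_names.index(name)
            x_min[i], x_max[i] = 0.0, 1.0
    return NormalizationParams(params.feature_names, x_min, x_max)


def normalize(x, params: NormalizationParams, clip: bool = True):
    """Scale raw feature values into [0.1, 0.9].

    Accepts a vector, a matrix, or a DataFrame containing the panel columns.
    Values outside the fitted range land outside [0.1, 0.9] and are clipped
    there by default (``clip=False`` extrapolates linearly instead).
    """
    if isinstance(x, pd.DataFrame):
        x = x[params.feature_names].to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != len(params.feature_names):
        raise ValueError(
            f"expected {len(params.feature_names)} features, got {X.shape[1]}")
    y = 0.8 * (X - params.x_min) / (params.x_max - params.x_min) + 0.1
    if clip:
        y = np.clip(y, 0.1, 0.9)
    return y[0] if single else y


def denormalize(y, params: NormalizationParams):
    """Inverse of :func:`normalize` on [0.1, 0.9] (clipping is not invertible)."""
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = np.atleast_2d(y)
    if Y.shape[1] != len(params.feature_names):
        raise ValueError(
            f"expected {len(params.feature_names)} features, got {Y.shape[1]}")
    x = (Y - 0.1) / 0.8 * (params.x_max - params.x_min) + params.x_min
    return x[0] if single else x


def codify_outcome(label: str) -> float:
    """SGA -> 0.5, AGA -> 1.0 (the network's target coding)."""
    try:
        return TARGET_CODES[label]
    except KeyError:
        raise ValueError(f"unknown outcome label {label!r}; expected SGA or AGA") from None


def decodify_outcome(target: float) -> str:
    """Inverse of :func:`codify_outcome` for exact codes only."""
    for label, code in TARGET_CODES.items():
        if target == code:
            return label
    raise ValueError(f"target {target!r} is not a codified outcome (0.5 or 1.0)")


@dataclass
class SplitAssignment:
    """Disjoint, exhaustive partition of cohort rows into
    train / validation / independent_test."""

    tags: np.ndarray
    fractions: tuple
    seed: int

    def indices(self, tag: str) -> np.ndarray:
        if tag not in PARTITIONS:
            raise ValueError(f"unknown partition {tag!r}")
        return np.flatnonzero(self.tags == tag)

    def counts(self) -> dict:
        return {tag: int(np.sum(self.tags == tag)) for tag in PARTITIONS}


def _apportion(n: int, fractions) -> list[int]:
    """Largest-remainder apportionment of n rows to the fractions."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    short = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def split_dataset(cohort: pd.DataFrame | int, fractions=(0.70, 0.15, 0.15),
                  seed: int = 0) -> SplitAssignment:
    """Randomly assign each row to train / validation / independent_test.

    ``fractions`` must sum to 1 (within rounding); per-partition counts are
    the largest-remainder rounding of fraction * n.  Deterministic given
    ``seed``; every row lands in exactly one partition.
    """
    n = cohort if isinstance(cohort, int) else len(cohort)
    if len(fractions) != 3:
        raise ValueError("fractions must be (train, validation, independent_test)")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be nonnegative")
    counts = _apportion(n, fractions)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    tags = np.empty(n, dtype=object)
    start = 0
    for tag, c in zip(PARTITIONS, counts):
        tags[perm[start:start + c]] = tag
        start += c
    return SplitAssignment(tags=tags, fractions=tuple(fractions), seed=seed)
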