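"""Feature-set augmentation: permutation, random generation, re-sampling.

Three mechanisms expand a small labeled set while balancing classes:

* segment **permutation** and **window slicing** act on raw signals (the
  pipeline re-extracts features from the perturbed signal);
* **random generation** draws feature rows column-wise uniform within the
  per-class min/max envelope of the real rows;
* **re-sampling** interpolates between random same-class row pairs (with a
  small seeded jitter) until every class reaches a target count.

Real rows are never mutated; every synthetic row is flagged ``augmented``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .staticfeat import BlockLayout


@dataclass
class LabeledFeatureSet:
    """Feature matrix with labels and real/augmented provenance flags."""

    matrix: np.ndarray
    labels: np.ndarray
    augmented: np.ndarray
    layout: Optional[BlockLayout] = None

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.labels = np.asarray(self.labels)
        self.augmented = np.asarray(self.augmented, dtype=bool)
        n = self.matrix.shape[0]
        if self.labels.shape[0] != n or self.augmented.shape[0] != n:
            raise ValueError("matrix rows, labels and flags must align")
        if self.layout is not None and self.layout.total_length != self.matrix.shape[1]:
            raise ValueError("layout does not match the matrix width")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def class_counts(self) -> dict:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def real_rows(self) -> "LabeledFeatureSet":
        m = ~self.augmented
        return LabeledFeatureSet(self.matrix[m], self.labels[m], self.augmented[m], self.layout)

    def extended(self, rows: np.ndarray, labels, augmented=True) -> "LabeledFeatureSet":
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if rows.shape[0] == 0:
            return self
        flags = np.full(rows.shape[0], bool(augmented))
        return LabeledFeatureSet(
            np.vstack([self.matrix, rows]),
            np.concatenate([self.labels, np.asarray(labels)]),
            np.concatenate([self.augmented, flags]),
            self.layout,
        )


@dataclass
class AugmentConfig:
    multiplier: float = 4.0  # target rows ~ multiplier x input rows
    D: int = 4  # equal-length parts for signal permutation
    ws_fraction: float = 0.9  # window-slicing fraction of the signal length
    random_gen_fraction: float = 0.3  # share of new rows from random generation
    jitter: float = 0.01  # resampling jitter as a fraction of the column range
    seed: int = 0

    def validate(self) -> None:
        if self.multiplier < 1:
            raise ValueError(f"multiplier must be >= 1, got {self.multiplier}")
        if self.D < 1:
            raise ValueError(f"D must be >= 1, got {self.D}")
        if not (0 < self.ws_fraction <= 1):
            raise ValueError(f"ws_fraction must lie in (0, 1], got {self.ws_fraction}")
        if not (0 <= self.random_gen_fraction <= 1):
            raise ValueError("random_gen_fraction must lie in [0, 1]")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


# ---------------------------------------------------------------------------
# signal-level perturbations

def permute_blocks(x: np.ndarray, D: int, seed_or_rng=0) -> np.ndarray:
    """Split the signal into ``D`` equal parts and reassemble them in a
    random non-identity order (trailing remainder stays in place)."""
    rng = np.random.default_rng(seed_or_rng) if not isinstance(seed_or_rng, np.random.Generator) else seed_or_rng
    x = np.asarray(x, dtype=float)
    if D > x.size:
        raise ValueError(f"D={D} exceeds signal length {x.size}")
    if D == 1:
        return x.copy()
    seg = x.size // D
    head, tail = x[: seg * D], x[seg * D :]
    parts = head.reshape(D, seg)
    perm = rng.permutation(D)
    while np.all(perm == np.arange(D)):  # samples must not repeat the original order
        perm = rng.permutation(D)
    return np.concatenate([parts[perm].reshape(-1), tail])


def window_slice(x: np.ndarray, fraction: float, seed_or_rng=0,
                 fs: float | None = None, heart_rate_bpm: float | None = None) -> np.ndarray:
    """Keep a contiguous window of ``fraction * len`` samples at a seeded
    random offset.  Warns when the window is shorter than one beat at the
    stated heart rate."""
    rng = np.random.default_rng(seed_or_rng) if not isinstance(seed_or_rng, np.random.Generator) else seed_or_rng
    x = np.asarray(x, dtype=float)
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    win = max(1, int(round(fraction * x.size)))
    if fs is not None and heart_rate_bpm is not None and win < fs * 60.0 / heart_rate_bpm:
        warnings.warn(
            f"window of {win} samples is shorter than one beat at {heart_rate_bpm} bpm",
            stacklevel=2,
        )
    if win >= x.size:
        return x.copy()
    off = int(rng.integers(0, x.size - win + 1))
    return x[off : off + win].copy()


# ---------------------------------------------------------------------------
# feature-row synthesis

def _class_envelope(fset: LabeledFeatureSet, label) -> tuple:
    real = fset.real_rows()
    rows = real.matrix[real.labels == label]
    if rows.shape[0] == 0:
        raise ValueError(f"no real rows for class {label!r}")
    return rows.min(axis=0), rows.max(axis=0)


def random_generate(fset: LabeledFeatureSet, n_new_per_class: int, seed_or_rng=0) -> LabeledFeatureSet:
    """Append rows drawn column-wise uniform within the per-class envelope
    of the real rows (highest/lowest magnitude bounds)."""
    if n_new_per_class < 0:
        raise ValueError(f"n_new_per_class must be >= 0, got {n_new_per_class}")
    rng = np.random.default_rng(seed_or_rng) if not isinstance(seed_or_rng, np.random.Generator) else seed_or_rng
    if n_new_per_class == 0:
        return fset
    out = fset
    for label in np.unique(fset.labels):
        lo, hi = _class_envelope(fset, label)
        rows = rng.uniform(lo, hi, size=(n_new_per_class, lo.size))
        rows = np.where(hi > lo, rows, lo)  # constant columns stay constant
        out = out.extended(rows, np.repeat(label, n_new_per_class))
    return out


def resample_balance(fset: LabeledFeatureSet, target_per_class: int, seed_or_rng=0,
                     jitter: float = 0.01, allow_downsample: bool = False) -> LabeledFeatureSet:
    """Bring every class to exactly ``target_per_class`` rows.

    Deficits are filled with jittered interpolations between random
    same-class row pairs; original rows are retained (unless explicit
    downsampling is requested, in which case augmented rows go first).
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(seed_or_rng, np.random.Generator) else seed_or_rng
    counts = fset.class_counts()
    if not counts:
        raise ValueError("empty feature set")
    if any(c == 0 for c in counts.values()):
        raise ValueError("every class needs at least one row")
    if not allow_downsample and target_per_class < max(counts.values()):
        raise ValueError(
            f"target {target_per_class} below the largest class ({max(counts.values())}); "
            "pass allow_downsample=True to shrink"
        )
    keep = np.ones(fset.n_rows, dtype=bool)
    new_rows, new_labels = [], []
    for label in np.unique(fset.labels):
        idx = np.flatnonzero(fset.labels == label)
        n = idx.size
        if n > target_per_class:
            # drop augmented rows first, then (only if forced) real rows
            aug_idx = idx[fset.augmented[idx]]
            real_idx = idx[~fset.augmented[idx]]
            n_drop = n - target_per_class
            drop = aug_idx[rng.permutation(aug_idx.size)][:n_drop]
            if drop.size < n_drop:
                extra = real_idx[rng.permutation(real_idx.size)][: n_drop - drop.size]
                drop = np.concatenate([drop, extra])
            keep[drop] = False
        elif n < target_per_class:
            deficit = target_per_class - n
            col_range = fset.matrix[idx].max(axis=0) - fset.matrix[idx].min(axis=0)
            a = idx[rng.integers(0, n, size=deficit)]
            b = idx[rng.integers(0, n, size=deficit)]
            u = rng.uniform(0, 1, size=(deficit, 1))
            rows = fset.matrix[a] + u * (fset.matrix[b] - fset.matrix[a])
            if jitter > 0:
                rows = rows + jitter * col_range[None, :] * rng.standard_normal(rows.shape)
            new_rows.append(rows)
            new_labels.append(np.repeat(label, deficit))
    base = LabeledFeatureSet(fset.matrix[keep], fset.labels[keep], fset.augmented[keep], fset.layout)
    if new_rows:
        base = base.extended(np.vstack(new_rows), np.concatenate(new_labels))
    return base


def augment(fset: LabeledFeatureSet, config: AugmentConfig | None = None) -> LabeledFeatureSet:
    """Grow the set to ``multiplier x`` its size with balanced classes.

    A share of the new rows (``random_gen_fraction``) comes from envelope
    random generation; the rest from interpolation re-sampling, which also
    exactly balances the classes.  Deterministic given ``config.seed``.
    """
    config = config or AugmentConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    if fset.n_rows == 0:
        raise ValueError("cannot augment an empty set")
    counts = fset.class_counts()
    n_classes = len(counts)
    total_target = int(round(config.multiplier * fset.n_rows))
    per_class = max(max(counts.values()), total_target // n_classes)

    n_new_total = max(0, per_class * n_classes - fset.n_rows)
    n_rand = int(round(config.random_gen_fraction * n_new_total / n_classes))
    # leave room for resampling to top up every class
    n_rand = min(n_rand, per_class - max(counts.values()))
    out = fset
    if n_rand > 0:
        out = random_generate(out, n_rand, rng)
    out = resample_balance(out, per_class, rng, jitter=config.jitter)
    return out
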