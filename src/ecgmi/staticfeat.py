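"""Haar-subband and statistical features, and full feature-vector assembly.

Blocks (default lengths in parentheses):

* A1 medical intervals (5)     — :mod:`ecgmi.fiducials`
* A2 MKMFCC (30)               — :mod:`ecgmi.cepstral`
* A3 Haar subband (4)          — log relative energy of 4 detail levels
* A4 mean (1), A5 variance (1) — population moments
* A6 relative amplitude (50)   — pairwise (d_m - d_n)/(d_m + d_n) over leads
  (single-lead records are split into 12 equal pseudo-channel segments)
* A7 relative energy (100)     — normalised spectral band energies
* A8 entropy (1)               — mean log squared amplitude at unit RMS
* A9 kurtosis (1)              — Pearson m4/m2^2
* A10 information gain (1)     — uniformity deficit of the amplitude histogram

The concatenated vector is 194-dimensional under the default block sizes;
every length is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pywt
from scipy.fft import rfft
from scipy.stats import kurtosis as _scipy_kurtosis

from .cepstral import MkmfccConfig, mkmfcc
from .fiducials import extract_medical_block
from .records import ECGRecord

EPS = 1e-10


class FeatureError(ValueError):
    """A feature block could not be computed; carries the block name."""

    def __init__(self, block: str, message: str):
        super().__init__(f"block {block}: {message}")
        self.block = block


@dataclass
class BlockLayout:
    """Ordered (name, offset, length) descriptor partitioning a vector."""

    blocks: list  # of (name, offset, length)

    @classmethod
    def from_lengths(cls, named_lengths) -> "BlockLayout":
        blocks, off = [], 0
        for name, length in named_lengths:
            blocks.append((name, off, length))
            off += length
        return cls(blocks=blocks)

    @property
    def total_length(self) -> int:
        if not self.blocks:
            return 0
        name, off, length = self.blocks[-1]
        return off + length

    def lengths(self) -> tuple:
        return tuple(length for _n, _o, length in self.blocks)

    def slice_of(self, name: str) -> slice:
        for n, off, length in self.blocks:
            if n == name:
                return slice(off, off + length)
        raise KeyError(name)

    def column_names(self) -> list:
        return [f"{n}_{i}" for n, _o, length in self.blocks for i in range(length)]

    @classmethod
    def from_column_names(cls, cols) -> "BlockLayout":
        named = []
        for c in cols:
            name = c.rsplit("_", 1)[0]
            if named and named[-1][0] == name:
                named[-1][1] += 1
            else:
                named.append([name, 1])
        return cls.from_lengths([(n, length) for n, length in named])

    def validate_partition(self) -> None:
        off = 0
        for name, o, length in self.blocks:
            if o != off or length < 0:
                raise ValueError(f"layout not contiguous at block {name}")
            off = o + length


@dataclass
class FeatureVector:
    values: np.ndarray
    layout: BlockLayout

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.layout.total_length:
            raise ValueError(
                f"vector length {self.values.size} != layout total {self.layout.total_length}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector must be finite")

    def block(self, name: str) -> np.ndarray:
        return self.values[self.layout.slice_of(name)]


# ---------------------------------------------------------------------------
# individual blocks

def haar_features(x: np.ndarray, levels: int = 4, eps: float = EPS) -> np.ndarray:
    """Log relative energy of the Haar detail subbands, finest first.

    Uses periodised boundary handling so the subband energies exactly
    partition the signal energy (orthogonality).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 ** levels:
        raise ValueError(f"haar_features needs >= {2 ** levels} samples, got {x.size}")
    coeffs = pywt.wavedec(x, "haar", level=levels, mode="periodization")
    detail_e = [float(np.sum(c ** 2)) for c in coeffs[1:]][::-1]  # d1..dlevels
    total = float(np.sum(coeffs[0] ** 2)) + float(np.sum(detail_e))
    total = max(total, eps)
    return np.array([np.log(eps + e / total) for e in detail_e])


def signal_mean(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("mean of empty signal")
    return float(np.mean(x))


def signal_variance(x: np.ndarray) -> float:
    """Population variance (1/C normalisation)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("variance of empty signal")
    return float(np.mean((x - np.mean(x)) ** 2))


def relative_amplitude(channels: np.ndarray, n_pairs: int = 50) -> np.ndarray:
    """Pairwise relative amplitudes (d_m - d_n)/(d_m + d_n), m < n.

    ``d`` is the per-channel maximum absolute amplitude.  The first
    ``n_pairs`` lexicographic pairs are kept; fewer pairs are zero-padded.
    A degenerate pair with d_m + d_n = 0 yields 0.
    """
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    if channels.shape[0] < 2:
        raise ValueError("relative_amplitude needs at least 2 channels")
    d = np.max(np.abs(channels), axis=1)
    out = np.zeros(n_pairs)
    for i, (m, n) in enumerate(combinations(range(d.size), 2)):
        if i >= n_pairs:
            break
        denom = d[m] + d[n]
        out[i] = (d[m] - d[n]) / denom if denom > 0 else 0.0
    return out


def segment_channels(x: np.ndarray, n_segments: int = 12) -> np.ndarray:
    """Split a single lead into equal-length pseudo-channels (trailing
    remainder discarded)."""
    x = np.asarray(x, dtype=float)
    seg = x.size // n_segments
    if seg < 1:
        raise ValueError(f"signal too short for {n_segments} segments")
    return x[: seg * n_segments].reshape(n_segments, seg)


def relative_energy(x: np.ndarray, n_bands: int = 100) -> np.ndarray:
    """Spectral band energies over (0, fs/2], normalised to sum 1.

    The DC bin is excluded; the remaining magnitude-squared spectrum is
    partitioned into ``n_bands`` equal-width bands.  An all-zero signal
    yields the uniform vector 1/n_bands (documented fallback).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("relative_energy of empty signal")
    power = np.abs(rfft(x)) ** 2
    power = power[1:]  # exclude DC
    total = power.sum()
    if total <= 0:
        return np.full(n_bands, 1.0 / n_bands)
    edges = np.linspace(0, power.size, n_bands + 1).astype(int)
    bands = np.add.reduceat(power, edges[:-1])
    # reduceat with repeated edges (short signals) may duplicate entries
    bands = np.where(np.diff(edges) > 0, bands, 0.0)
    return bands / bands.sum()


def log_energy_entropy(x: np.ndarray, eps: float = EPS) -> float:
    """Mean log squared amplitude after scaling to unit RMS.

    A peaky signal (energy concentrated in a few samples) scores lower than
    a constant-magnitude one of the same RMS (Jensen's inequality), so the
    value tracks amplitude uncertainty.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("entropy of empty signal")
    rms = float(np.sqrt(np.mean(x ** 2)))
    if rms <= 0:
        return float(np.log(eps))
    xs = x / rms
    return float(np.mean(np.log(xs ** 2 + eps)))


def kurtosis(x: np.ndarray) -> float:
    """Pearson kurtosis m4/m2^2 (normal -> 3); 0 for a zero-variance signal."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("kurtosis of empty signal")
    if np.var(x) <= 0:
        return 0.0
    return float(_scipy_kurtosis(x, fisher=False, bias=True))


def information_gain(x: np.ndarray, bins: int = 10) -> float:
    """Uniformity deficit of the amplitude histogram, in bits.

    A10 = log2(bins) - H(p) where p is the normalised ``bins``-bin
    amplitude histogram; 0 for a perfectly uniform histogram, log2(bins)
    for a constant signal.  Label-free, so feature extraction needs no
    class information.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("information_gain of empty signal")
    counts, _ = np.histogram(x, bins=bins)
    p = counts / counts.sum()
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    return float(np.log2(bins) - h)


# ---------------------------------------------------------------------------
# assembly

@dataclass
class AssembleConfig:
    mkmfcc: MkmfccConfig = field(default_factory=MkmfccConfig)
    haar_levels: int = 4
    n_rel_amp: int = 50
    n_energy_bands: int = 100
    ig_bins: int = 10
    n_segments: int = 12  # pseudo-channels for single-lead relative amplitude

    def layout(self) -> BlockLayout:
        return BlockLayout.from_lengths([
            ("A1", 5),
            ("A2", self.mkmfcc.n_coeffs),
            ("A3", self.haar_levels),
            ("A4", 1), ("A5", 1),
            ("A6", self.n_rel_amp),
            ("A7", self.n_energy_bands),
            ("A8", 1), ("A9", 1), ("A10", 1),
        ])


def assemble(record: ECGRecord, config: AssembleConfig | None = None) -> FeatureVector:
    """Extract every block from a (filtered) record and concatenate them."""
    config = config or AssembleConfig()
    x = record.primary_lead()
    parts = []

    def _run(name, fn):
        try:
            return np.atleast_1d(np.asarray(fn(), dtype=float))
        except Exception as exc:
            raise FeatureError(name, str(exc)) from exc

    parts.append(_run("A1", lambda: extract_medical_block(record)))
    parts.append(_run("A2", lambda: mkmfcc(x, record.fs, config.mkmfcc)))
    parts.append(_run("A3", lambda: haar_features(x, config.haar_levels)))
    parts.append(_run("A4", lambda: signal_mean(x)))
    parts.append(_run("A5", lambda: signal_variance(x)))
    channels = record.samples if record.n_leads >= 2 else segment_channels(x, config.n_segments)
    parts.append(_run("A6", lambda: relative_amplitude(channels, config.n_rel_amp)))
    parts.append(_run("A7", lambda: relative_energy(x, config.n_energy_bands)))
    parts.append(_run("A8", lambda: log_energy_entropy(x)))
    parts.append(_run("A9", lambda: kurtosis(x)))
    parts.append(_run("A10", lambda: information_gain(x, config.ig_bins)))
    layout = config.layout()
    return FeatureVector(values=np.concatenate(parts), layout=layout)
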