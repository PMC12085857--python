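"""Multiple-kernel-weighted Mel-frequency cepstral coefficients (MKMFCC).

The classic MFCC chain — pre-emphasis, framing, windowing, FFT power
spectrum, triangular Mel filter bank, log, DCT — with one twist: each Mel
band's energy is multiplied by a kernel weight before the log.  The weight
is a mix of two kernels over the band index, a Gaussian bump and a linear
ramp, each normalised to unit mean:

    W = lambda * Gauss(center, sigma) + (1 - lambda) * ramp

With ``kernel_mix = 1`` and a very wide sigma the weights flatten to 1 and
plain MFCC is recovered (used as a cross-check in the tests).

The windowing function uses the non-standard 0.56/0.46 Hamming-style
constants: w(c) = 0.56 - 0.46 cos(2 pi c / (C - 1)).

Per frame the coefficient-0 slot is replaced by the log frame energy, the
coefficients are mean/variance normalised within the frame, and frames are
averaged into a single row of ``n_coeffs`` (default 30) numbers per record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, rfft

from .records import ConfigurationError


@dataclass
class MkmfccConfig:
    pre_emphasis: float = 0.97
    frame_ms: float = 25.0  # 20-40 ms is the conventional quasi-stationary span
    hop_ms: float = 10.0
    n_mels: int = 40
    n_coeffs: int = 30
    kernel_mix: float = 0.5  # lambda: weight of the Gaussian kernel
    kernel_sigma: float = 2.0  # Gaussian width in Mel-band index units
    kernel_center: float | None = None  # default: middle band
    fmin: float = 0.5
    energy_floor: float = 1e-10

    def validate(self) -> None:
        if not (0 <= self.pre_emphasis < 1):
            raise ConfigurationError(f"pre_emphasis must lie in [0, 1), got {self.pre_emphasis}")
        if self.frame_ms <= 0 or self.hop_ms <= 0:
            raise ConfigurationError("frame_ms and hop_ms must be > 0")
        if self.n_coeffs > self.n_mels:
            raise ConfigurationError(
                f"n_coeffs ({self.n_coeffs}) cannot exceed n_mels ({self.n_mels})"
            )
        if not (0 <= self.kernel_mix <= 1):
            raise ConfigurationError(f"kernel_mix must lie in [0, 1], got {self.kernel_mix}")
        if self.kernel_sigma <= 0:
            raise ConfigurationError("kernel_sigma must be > 0")


def pre_emphasis(x: np.ndarray, y: float) -> np.ndarray:
    """First-difference pre-emphasis x'[c] = x[c] - y*x[c-1]; x'[0] = x[0]."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("pre_emphasis needs a non-empty signal")
    out = x.copy()
    out[1:] = x[1:] - y * x[:-1]
    return out


def hamming_like(C: int) -> np.ndarray:
    """w(c) = 0.56 - 0.46 cos(2 pi c / (C-1)), c = 0..C-1."""
    if C == 1:
        return np.array([0.56 - 0.46])
    c = np.arange(C)
    return 0.56 - 0.46 * np.cos(2 * np.pi * c / (C - 1))


def frame_and_window(x: np.ndarray, fs: float, config: MkmfccConfig) -> np.ndarray:
    """Split into overlapping frames and apply the window.

    Frame count is ``1 + floor((len - frame) / hop)``.
    """
    x = np.asarray(x, dtype=float)
    frame = int(round(config.frame_ms * fs / 1000.0))
    hop = int(round(config.hop_ms * fs / 1000.0))
    if x.size < frame:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one {frame}-sample frame"
        )
    n_frames = 1 + (x.size - frame) // hop
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx] * hamming_like(frame)[None, :]


def mel_scale(f: np.ndarray) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def mel_inverse(m: np.ndarray) -> np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, fs: float, fmin: float) -> np.ndarray:
    """Triangular filters (n_mels x n_fft//2+1) equally spaced on the Mel scale."""
    fmax = fs / 2.0
    pts = mel_inverse(np.linspace(mel_scale(fmin), mel_scale(fmax), n_mels + 2))
    bins = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    fb = np.zeros((n_mels, bins.size))
    for j in range(n_mels):
        lo, ctr, hi = pts[j], pts[j + 1], pts[j + 2]
        up = (bins - lo) / max(ctr - lo, 1e-12)
        down = (hi - bins) / max(hi - ctr, 1e-12)
        fb[j] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def kernel_weights(config: MkmfccConfig) -> np.ndarray:
    """Multiple-kernel band weights, unit mean."""
    j = np.arange(config.n_mels, dtype=float)
    center = (config.n_mels - 1) / 2.0 if config.kernel_center is None else config.kernel_center
    gauss = np.exp(-0.5 * ((j - center) / config.kernel_sigma) ** 2)
    gauss = gauss / gauss.mean()
    ramp = j + 1.0
    ramp = ramp / ramp.mean()
    w = config.kernel_mix * gauss + (1.0 - config.kernel_mix) * ramp
    return w


def mel_filterbank_energies(frames: np.ndarray, fs: float, config: MkmfccConfig) -> np.ndarray:
    """Kernel-weighted log Mel band energies, one row per frame."""
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    C = frames.shape[1]
    n_fft = 1 << max(1, (C - 1).bit_length())  # next power of two >= frame
    spec = rfft(frames, n=n_fft, axis=1)
    power = (np.abs(spec) ** 2) / C
    fb = mel_filterbank(config.n_mels, n_fft, fs, config.fmin)
    energies = power @ fb.T
    energies = energies * kernel_weights(config)[None, :]
    return np.log(np.maximum(energies, config.energy_floor))


def mkmfcc(x: np.ndarray, fs: float, config: MkmfccConfig | None = None) -> np.ndarray:
    """The full MKMFCC block: one row of ``n_coeffs`` values per record."""
    config = config or MkmfccConfig()
    config.validate()
    x = np.asarray(x, dtype=float)
    z = pre_emphasis(x, config.pre_emphasis)
    frames = frame_and_window(z, fs, config)
    log_e = mel_filterbank_energies(frames, fs, config)
    coeffs = dct(log_e, type=2, norm="ortho", axis=1)[:, : config.n_coeffs]
    # slot 0 carries the log frame energy (spectrum-and-energy step)
    frame_energy = np.sum(frames ** 2, axis=1)
    coeffs[:, 0] = np.log(np.maximum(frame_energy, config.energy_floor))
    # per-frame cepstral mean/variance normalisation
    mu = coeffs.mean(axis=1, keepdims=True)
    sd = coeffs.std(axis=1, keepdims=True)
    coeffs = (coeffs - mu) / np.maximum(sd, 1e-12)
    return coeffs.mean(axis=0)
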