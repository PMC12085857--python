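"""Core domain containers: ECG records, ground truth, generator/noise configs.

An :class:`ECGRecord` stores the sample matrix (leads x samples, mV), the
sampling rate and an optional class label (``"MI"`` — myocardial infarction,
the positive class — or ``"HC"`` — healthy control).  Synthetic records carry
a :class:`GroundTruth` with the exact fiducial positions used to build them,
which downstream delineation tests compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

LABELS = ("MI", "HC")


class ConfigurationError(ValueError):
    """A generator / filter configuration field is invalid."""


@dataclass
class NoiseSpec:
    """One additive corruption applied to a record.

    kind:
        ``baseline_wander`` — low-frequency sinusoidal drift (respiration,
        electrode motion), ``powerline`` — mains interference at 50/60 Hz,
        ``impulse`` — isolated single-sample spikes (muscle/electrode
        artefacts; what a median filter provably removes), ``gaussian`` —
        broadband measurement noise.
    amplitude:
        mV: sinusoid amplitude, spike magnitude or gaussian standard
        deviation depending on ``kind``.
    """

    kind: str
    amplitude: float = 0.1
    frequency: float = 0.3
    impulse_rate: float = 1.0
    seed: int = 0

    KINDS = ("baseline_wander", "powerline", "impulse", "gaussian")

    def validate(self) -> None:
        if self.kind not in self.KINDS:
            raise ConfigurationError(f"unknown noise kind {self.kind!r}; expected one of {self.KINDS}")
        if self.amplitude < 0:
            raise ConfigurationError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.kind in ("baseline_wander", "powerline") and self.frequency <= 0:
            raise ConfigurationError(f"frequency must be > 0 for {self.kind}, got {self.frequency}")
        if self.kind == "impulse" and self.impulse_rate < 0:
            raise ConfigurationError(f"impulse_rate must be >= 0, got {self.impulse_rate}")


@dataclass
class GroundTruth:
    """Exact per-beat fiducials of a synthetic record (test oracle only)."""

    r_locations: np.ndarray  # sample indices, strictly increasing
    beat_fiducials: np.ndarray  # (n_beats, 5): P,Q,R,S,T sample indices
    morphology: list  # per beat: "normal" | "mi"
    noise_manifest: list = field(default_factory=list)  # applied NoiseSpec's

    def validate(self, n_samples: int) -> None:
        r = np.asarray(self.r_locations)
        if r.size and (np.any(np.diff(r) <= 0) or r[0] < 0 or r[-1] >= n_samples):
            raise ValueError("ground-truth R locations must be strictly increasing and in range")
        bf = np.asarray(self.beat_fiducials)
        if bf.size:
            if np.any(np.diff(bf, axis=1) <= 0):
                raise ValueError("per-beat fiducials must be strictly increasing (P<Q<R<S<T)")
            if bf.min() < 0 or bf.max() >= n_samples:
                raise ValueError("fiducial index out of record range")


@dataclass
class ECGRecord:
    """A (multi-)lead ECG trace.

    ``samples`` has shape (n_leads, n_samples) in millivolt; single-lead
    input may be passed 1-D and is promoted.
    """

    samples: np.ndarray
    fs: float = 1000.0
    lead_names: Sequence[str] = ("I",)
    label: Optional[str] = None
    truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.ndim != 2:
            raise ValueError(f"samples must be 1-D or 2-D, got ndim={arr.ndim}")
        self.samples = arr
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must be finite")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("record must contain at least one lead and one sample")
        self.lead_names = list(self.lead_names)
        if len(self.lead_names) != arr.shape[0]:
            raise ValueError(
                f"{len(self.lead_names)} lead names for {arr.shape[0]} leads"
            )
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS} or None, got {self.label!r}")
        if self.truth is not None:
            self.truth.validate(arr.shape[1])

    @property
    def n_leads(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name_or_index=0) -> np.ndarray:
        """Return one lead as a 1-D array.  Lead II is the conventional
        rhythm lead; :func:`primary_lead` prefers it when present."""
        if isinstance(name_or_index, str):
            return self.samples[list(self.lead_names).index(name_or_index)]
        return self.samples[name_or_index]

    def primary_lead(self) -> np.ndarray:
        if "II" in self.lead_names:
            return self.lead("II")
        return self.samples[0]

    def with_samples(self, samples: np.ndarray, truth: Optional[GroundTruth] = None) -> "ECGRecord":
        return replace(self, samples=samples, truth=truth if truth is not None else self.truth)


#: default Gaussian bump parameters per wave: (amplitude mV, center offset s
#: relative to R, width s).  Offsets give PR ~160 ms, QRS ~80 ms, QT ~320 ms —
#: ordinary adult morphology at rest.
DEFAULT_WAVES = {
    "P": (0.15, -0.16, 0.020),
    "Q": (-0.10, -0.040, 0.008),
    "R": (1.00, 0.0, 0.010),
    "S": (-0.15, 0.040, 0.008),
    "T": (0.30, 0.240, 0.040),
}


@dataclass
class MIParams:
    """Morphology changes of an infarcted beat.

    st_offset_mv raises the ST segment (the window between S and T onset,
    nominally R+80..R+160 ms); t_inversion flips the T wave; q_deepening
    scales the Q amplitude (pathological Q waves).
    """

    st_offset_mv: float = 0.2
    t_inversion: bool = True
    q_deepening: float = 2.0


@dataclass
class SynthConfig:
    """Synthetic ECG generator settings (defaults emulate a 1000 Hz
    single-lead resting recording)."""

    duration_s: float = 10.0
    heart_rate_bpm: float = 60.0
    fs: float = 1000.0
    waves: dict = field(default_factory=lambda: dict(DEFAULT_WAVES))
    mi: bool = False
    mi_params: MIParams = field(default_factory=MIParams)
    rr_jitter: float = 0.0  # fractional std of the beat period
    amp_jitter: float = 0.0  # fractional std of per-beat wave amplitudes
    n_leads: int = 1
    lead_scale_range: tuple = (0.6, 1.2)  # per-lead amplitude scaling span
    seed: int = 0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ConfigurationError(f"duration_s must be > 0, got {self.duration_s}")
        if not (20 <= self.heart_rate_bpm <= 250):
            raise ConfigurationError(
                f"heart_rate_bpm must lie in [20, 250], got {self.heart_rate_bpm}"
            )
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be > 0, got {self.fs}")
        for name, (amp, _off, width) in self.waves.items():
            if width <= 0:
                raise ConfigurationError(f"waves[{name!r}]: width must be > 0, got {width}")
        if self.rr_jitter < 0 or self.amp_jitter < 0:
            raise ConfigurationError("jitter fractions must be >= 0")
        if self.n_leads < 1:
            raise ConfigurationError(f"n_leads must be >= 1, got {self.n_leads}")
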