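"""Synthetic ECG generation.

Beats are modelled as a sum of five Gaussian bumps (P, Q, R, S, T) on a zero
baseline — simple, fully controllable, and with exactly known fiducials, so
every downstream stage (filtering, delineation, features) can be tested
against ground truth.  Infarct-like morphology is imposed per beat as an ST
segment offset, T-wave inversion and Q deepening.
"""

from __future__ import annotations

import numpy as np

from .records import ECGRecord, GroundTruth, NoiseSpec, SynthConfig

_LEAD_NAMES = ["I", "II", "III", "aVR", "aVL", "aVF", "V1", "V2", "V3", "V4", "V5", "V6"]

WAVE_ORDER = ("P", "Q", "R", "S", "T")

# ST measurement window relative to R, seconds (between the J point and the
# T onset at resting heart rates)
ST_WINDOW = (0.080, 0.160)


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def generate_record(config: SynthConfig) -> ECGRecord:
    """Generate a labeled synthetic ECG record with ground-truth fiducials.

    Deterministic for a fixed ``config`` (including its ``seed``).  The
    record length is ``round(duration_s * fs)`` samples; beats whose five
    fiducials would not all fall inside the record are omitted.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = float(config.fs)
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    period = 60.0 / config.heart_rate_bpm
    waves = config.waves
    # beat-support extent before/after R so fiducials and bump tails fit
    pre = max(-off + 3 * w for _a, off, w in [waves[k] for k in ("P", "Q")])
    post = max(off + 3 * w for _a, off, w in [waves[k] for k in ("S", "T")])

    r_times = []
    r_t = max(pre, 0.35 * period)
    while r_t + post < config.duration_s:
        r_times.append(r_t)
        step = period
        if config.rr_jitter > 0:
            step = period * max(0.2, 1.0 + config.rr_jitter * rng.standard_normal())
        r_t = r_t + step

    x = np.zeros(n)
    fiducials = []
    morphology = []
    mi = config.mi
    mp = config.mi_params
    for r_time in r_times:
        beat_fid = {}
        for name in WAVE_ORDER:
            amp, off, width = waves[name]
            if mi:
                if name == "T" and mp.t_inversion:
                    amp = -amp
                if name == "Q":
                    amp = amp * mp.q_deepening
            if config.amp_jitter > 0:
                amp = amp * (1.0 + config.amp_jitter * rng.standard_normal())
            center = r_time + off
            x += amp * _gauss(t, center, width)
            beat_fid[name] = int(round(center * fs))
        if mi and mp.st_offset_mv != 0.0:
            lo = int(round((r_time + ST_WINDOW[0]) * fs))
            hi = int(round((r_time + ST_WINDOW[1]) * fs))
            x[lo:hi] += mp.st_offset_mv
        fiducials.append([beat_fid[k] for k in WAVE_ORDER])
        morphology.append("mi" if mi else "normal")

    leads = [x]
    names = [_LEAD_NAMES[0]]
    for j in range(1, config.n_leads):
        lo, hi = config.lead_scale_range
        scale = rng.uniform(lo, hi)
        leads.append(scale * x)
        names.append(_LEAD_NAMES[j % len(_LEAD_NAMES)])

    truth = GroundTruth(
        r_locations=np.array([f[2] for f in fiducials], dtype=int),
        beat_fiducials=np.array(fiducials, dtype=int).reshape(len(fiducials), 5),
        morphology=morphology,
        noise_manifest=[],
    )
    return ECGRecord(
        samples=np.vstack(leads),
        fs=fs,
        lead_names=names,
        label=("MI" if mi else "HC"),
        truth=truth,
    )


def add_noise(record: ECGRecord, spec: NoiseSpec) -> ECGRecord:
    """Return a copy of ``record`` with one noise process added to every lead.

    The applied :class:`NoiseSpec` is appended to the ground-truth noise
    manifest (when truth is present).  Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = record.fs
    n = record.n_samples
    t = np.arange(n) / fs
    out = record.samples.copy()

    for li in range(record.n_leads):
        if spec.kind in ("baseline_wander", "powerline"):
            phase = rng.uniform(0, 2 * np.pi)
            out[li] += spec.amplitude * np.sin(2 * np.pi * spec.frequency * t + phase)
        elif spec.kind == "impulse":
            n_events = rng.poisson(spec.impulse_rate * n / fs)
            if n_events > 0:
                idx = rng.integers(0, n, size=n_events)
                sign = rng.choice([-1.0, 1.0], size=n_events)
                out[li, idx] += sign * spec.amplitude
        elif spec.kind == "gaussian":
            out[li] += spec.amplitude * rng.standard_normal(n)

    truth = record.truth
    if truth is not None:
        truth = GroundTruth(
            r_locations=truth.r_locations,
            beat_fiducials=truth.beat_fiducials,
            morphology=list(truth.morphology),
            noise_manifest=list(truth.noise_manifest) + [spec],
        )
    return record.with_samples(out, truth=truth)
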