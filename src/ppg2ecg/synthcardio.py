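"""Synthetic paired ECG/PPG generator with known ground truth.

Emulates the features of real paired ICU waveform records that the
reconstruction pipeline depends on: a beat train with heart-rate
variability, ECG morphology with P/Q/R/S/T deflections, PPG pulses
delayed by a pulse-arrival-time (PAT) lag, additive white noise and an
optional low-frequency baseline-wander sinusoid (which exercises the
0.5 Hz high-pass edge of the preprocessing filters).

Each ECG beat is a sum of five Gaussian bumps; each PPG pulse is a
systolic Gaussian plus an optional dicrotic Gaussian.  The Gaussian-sum
morphology is deliberately simple: every downstream property (R-peak
location, systolic-peak lag, record length) is analytically checkable,
which is what makes the pipeline testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .recordio import DEFAULT_FS, Record, child_seed

__all__ = ["SynthParams", "gen_beat_times", "gen_ecg", "gen_ppg", "gen_record"]

# (amplitude, centre offset from R in s, Gaussian width in s) per wave.
# R is the dominant deflection so the per-beat argmax sits at the R centre.
DEFAULT_WAVES: Dict[str, Tuple[float, float, float]] = {
    "P": (0.15, -0.20, 0.040),
    "Q": (-0.15, -0.04, 0.012),
    "R": (1.00, 0.00, 0.014),
    "S": (-0.20, 0.035, 0.014),
    "T": (0.30, 0.28, 0.060),
}

# (systolic amplitude, systolic width s, dicrotic amplitude, dicrotic delay s,
#  dicrotic width s)
DEFAULT_PPG: Tuple[float, float, float, float, float] = (1.0, 0.09, 0.25, 0.30, 0.09)

FIRST_BEAT_OFFSET_S = 0.5  # first beat well inside the record: no clipped waves
MIN_IBI_S = 0.3  # physiological floor on the inter-beat interval


@dataclass
class SynthParams:
    """Parameters of one synthetic paired recording."""

    duration_s: float = 294.0
    fs: float = DEFAULT_FS
    hr_bpm: float = 70.0
    hrv_sd_s: float = 0.03
    pat_s: float = 0.24
    noise_sd: float = 0.02
    wave_params: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WAVES)
    )
    ppg_params: Tuple[float, float, float, float, float] = DEFAULT_PPG
    baseline_wander: bool = False
    baseline_amp: float = 0.1
    baseline_hz: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hr_bpm <= 0:
            raise ValueError("hr_bpm must be positive")
        if self.pat_s < 0:
            raise ValueError("pat_s must be non-negative")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.hrv_sd_s < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if any(w[2] <= 0 for w in self.wave_params.values()):
            raise ValueError("wave widths must be positive")
        if self.ppg_params[1] <= 0 or self.ppg_params[4] <= 0:
            raise ValueError("pulse widths must be positive")
        r_amp = self.wave_params.get("R", (0, 0, 1))[0]
        if any(abs(a) > r_amp for a, _, _ in self.wave_params.values()):
            raise ValueError("R must be the largest-amplitude ECG wave")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def gen_beat_times(params: SynthParams) -> np.ndarray:
    """Draw a strictly increasing beat-time train in ``[0, duration)``.

    Inter-beat intervals are Normal(60/hr, hrv_sd) truncated below at
    0.3 s; the first beat sits at a fixed 0.5 s offset so that edge
    beats keep their full morphology.
    """
    mean_ibi = 60.0 / params.hr_bpm
    if params.duration_s <= mean_ibi:
        raise ValueError("duration must exceed one mean beat interval")
    rng = np.random.default_rng(child_seed(params.seed, "beat_times"))
    times: List[float] = []
    t = FIRST_BEAT_OFFSET_S
    while t < params.duration_s:
        times.append(t)
        ibi = mean_ibi + (rng.normal(0.0, params.hrv_sd_s) if params.hrv_sd_s > 0 else 0.0)
        t += max(ibi, MIN_IBI_S)
    return np.asarray(times)


def _gaussian_sum(
    t: np.ndarray, centres: np.ndarray, amps: np.ndarray, widths: np.ndarray
) -> np.ndarray:
    """Sum of Gaussian bumps, evaluated only on a ±5-width support per bump."""
    out = np.zeros_like(t)
    n = len(t)
    dt = t[1] - t[0] if n > 1 else 1.0
    for c, a, w in zip(centres, amps, widths):
        lo = max(int((c - 5 * w) / dt), 0)
        hi = min(int((c + 5 * w) / dt) + 2, n)
        if lo >= hi:
            continue
        seg = t[lo:hi]
        out[lo:hi] += a * np.exp(-((seg - c) ** 2) / (2.0 * w**2))
    return out


def gen_ecg(beat_times: np.ndarray, params: SynthParams) -> np.ndarray:
    """Render the ECG channel for the given beat train."""
    t = np.arange(params.n_samples) / params.fs
    centres, amps, widths = [], [], []
    for tb in beat_times:
        for amp, off, width in params.wave_params.values():
            centres.append(tb + off)
            amps.append(amp)
            widths.append(width)
    ecg = _gaussian_sum(t, np.asarray(centres), np.asarray(amps), np.asarray(widths))
    rng = np.random.default_rng(child_seed(params.seed, "ecg_noise"))
    if params.noise_sd > 0:
        ecg = ecg + rng.normal(0.0, params.noise_sd, size=ecg.shape)
    if params.baseline_wander:
        ecg = ecg + params.baseline_amp * np.sin(2 * np.pi * params.baseline_hz * t)
    return ecg


def gen_ppg(beat_times: np.ndarray, params: SynthParams) -> np.ndarray:
    """Render the PPG channel: systolic (+ dicrotic) pulse per beat, lagged by PAT."""
    t = np.arange(params.n_samples) / params.fs
    sys_amp, sys_w, dic_amp, dic_delay, dic_w = params.ppg_params
    centres, amps, widths = [], [], []
    for tb in beat_times:
        centres.append(tb + params.pat_s)
        amps.append(sys_amp)
        widths.append(sys_w)
        if dic_amp != 0.0:
            centres.append(tb + params.pat_s + dic_delay)
            amps.append(dic_amp)
            widths.append(dic_w)
    ppg = _gaussian_sum(t, np.asarray(centres), np.asarray(amps), np.asarray(widths))
    rng = np.random.default_rng(child_seed(params.seed, "ppg_noise"))
    if params.noise_sd > 0:
        ppg = ppg + rng.normal(0.0, params.noise_sd, size=ppg.shape)
    if params.baseline_wander:
        ppg = ppg + params.baseline_amp * np.sin(
            2 * np.pi * params.baseline_hz * t + 1.0
        )
    return ppg


def gen_record(params: SynthParams, record_id: str | None = None) -> Record:
    """Generate one paired record; R-peak sample indices go to ``annotations``."""
    beats = gen_beat_times(params)
    ecg = gen_ecg(beats, params)
    ppg = gen_ppg(beats, params)
    ann = np.round(beats * params.fs).astype(np.int64)
    ann = ann[ann < params.n_samples]
    rid = record_id if record_id is not None else f"synth-{params.seed}"
    return Record(ecg=ecg, ppg=ppg, fs=params.fs, record_id=rid, annotations=ann)
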