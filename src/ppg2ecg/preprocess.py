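"""Preprocessing: filtering, peak detection, alignment, segmentation, gaps.

The pipeline for each record runs, in order:

1. zero-phase Chebyshev type-II bandpass filtering (PPG 0.5-10 Hz,
   ECG 0.5-20 Hz);
2. R-peak detection (Pan-Tompkins) and PPG systolic-peak detection
   (two event-related moving averages);
3. "Alignment I": the PPG channel is advanced so the third systolic peak
   coincides with its corresponding R peak, removing the pulse-arrival-time
   lag;
4. per-record min-max normalisation of both channels to [0, 1];
5. trimming to the first 294 s and division into non-overlapping 3 s
   segments (375 samples at 125 Hz);
6. a chronological 60/20/20 train/validation/test split;
7. injection of one contiguous missing-ECG gap (1-4 s) at a seeded uniform
   position inside the training portion, recorded as zeroed samples plus an
   explicit boolean mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .recordio import Record, RunConfig, child_seed

__all__ = [
    "AlignedRecord",
    "SegmentPair",
    "GapSpec",
    "cheby2_bandpass",
    "detect_r_peaks",
    "detect_systolic_peaks",
    "align_pair",
    "normalize_minmax",
    "segment_record",
    "split_segments",
    "inject_gap",
    "preprocess_record",
]

PPG_BAND_HZ = (0.5, 10.0)
ECG_BAND_HZ = (0.5, 20.0)
CHEBY2_STOPBAND_DB = 40.0


@dataclass
class AlignedRecord:
    """ECG/PPG pair after Alignment I (lag removed, common overlap kept)."""

    ecg: np.ndarray
    ppg: np.ndarray
    lag_samples: int
    fs: float
    record_id: str = "record"

    def __post_init__(self) -> None:
        if len(self.ecg) != len(self.ppg):
            raise ValueError("aligned channels must have equal length")
        if self.lag_samples < 0:
            raise ValueError("lag_samples must be non-negative")

    def __len__(self) -> int:
        return len(self.ecg)


@dataclass
class SegmentPair:
    """One aligned (PPG input, ECG target) segment plus its presence mask."""

    ppg_in: np.ndarray
    ecg_target: np.ndarray
    mask: np.ndarray  # True where the ECG sample is present
    segment_index: int
    record_id: str = "record"

    def __post_init__(self) -> None:
        if not (len(self.ppg_in) == len(self.ecg_target) == len(self.mask)):
            raise ValueError("segment channels must have equal length")


@dataclass(frozen=True)
class GapSpec:
    """One injected contiguous missing-ECG span, in record coordinates."""

    gap_seconds: float
    start_sample: int
    record_id: str = "record"


def cheby2_bandpass(
    x: np.ndarray,
    fs: float,
    low_hz: float,
    high_hz: float,
    order: int = 4,
    stopband_db: float = CHEBY2_STOPBAND_DB,
) -> np.ndarray:
    """Zero-phase Chebyshev type-II bandpass.

    ``low_hz``/``high_hz`` are the passband edges.  Because a type-II design
    is specified by its stopband, the stopband corners are placed one octave
    outside the passband (clamped below Nyquist), which leaves the stated
    band flat while reaching ``stopband_db`` attenuation beyond the corners.
    Applied forward-backward (``sosfiltfilt``) so peak positions, which the
    subsequent alignment depends on, are not displaced.
    """
    x = np.asarray(x, dtype=np.float64)
    nyq = fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) must satisfy 0 < low < high < Nyquist ({nyq})"
        )
    if len(x) <= 3 * order:
        raise ValueError("signal too short for the requested filter order")
    stop = (low_hz / 2.0, min(high_hz * 2.0, 0.95 * nyq))
    sos = sps.cheby2(order, stopband_db, stop, btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    width = max(int(width), 1)
    kernel = np.full(width, 1.0 / width)
    return np.convolve(x, kernel, mode="same")


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins QRS detection.

    Classic chain: 5-15 Hz bandpass, derivative, squaring, 150 ms moving
    window integration, adaptive dual thresholds with search-back, 200 ms
    refractory period.  Detections are refined to the local ECG maximum in a
    +/-75 ms window so the returned indices land on the R apex.
    """
    ecg = np.asarray(ecg, dtype=np.float64)
    if fs < 100:
        raise ValueError("Pan-Tompkins requires fs >= 100 Hz")
    if len(ecg) < 2 * fs:
        raise ValueError("need at least 2 s of ECG")
    if np.ptp(ecg) == 0:
        return np.asarray([], dtype=np.int64)

    sos = sps.butter(2, (5.0, 15.0), btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, ecg)
    deriv = np.gradient(bp)
    squared = deriv**2
    integ = _moving_average(squared, int(round(0.150 * fs)))

    refractory = int(round(0.200 * fs))
    search_win = int(round(0.075 * fs))
    # candidate local maxima of the integrated signal
    cand, _ = sps.find_peaks(integ, distance=refractory)
    if len(cand) == 0:
        return np.asarray([], dtype=np.int64)

    # adaptive thresholding over candidates (signal/noise running estimates)
    spki = float(np.max(integ[: int(2 * fs)]) * 0.25)
    npki = float(np.mean(integ[: int(2 * fs)]) * 0.5)
    peaks: List[int] = []
    missed_limit = 1.66  # search-back when an RR interval stretches past 166%
    rr_avg = None
    last = None
    i = 0
    while i < len(cand):
        c = cand[i]
        thr = npki + 0.25 * (spki - npki)
        if integ[c] > thr:
            peaks.append(c)
            spki = 0.125 * integ[c] + 0.875 * spki
            if last is not None:
                rr = c - last
                rr_avg = rr if rr_avg is None else 0.125 * rr + 0.875 * rr_avg
            last = c
        else:
            npki = 0.125 * integ[c] + 0.875 * npki
            # search-back: accept at half threshold if a beat is overdue
            if (
                last is not None
                and rr_avg is not None
                and (c - last) > missed_limit * rr_avg
                and integ[c] > thr / 2.0
            ):
                peaks.append(c)
                spki = 0.25 * integ[c] + 0.75 * spki
                last = c
        i += 1

    # refine onto the R apex of the bandpassed ECG
    refined: List[int] = []
    for p in peaks:
        lo = max(p - search_win, 0)
        hi = min(p + search_win + 1, len(ecg))
        refined.append(lo + int(np.argmax(bp[lo:hi])))
    refined_arr = np.unique(np.asarray(refined, dtype=np.int64))
    # enforce the refractory period after refinement
    keep: List[int] = []
    for p in refined_arr:
        if not keep or p - keep[-1] >= refractory:
            keep.append(int(p))
        elif bp[p] > bp[keep[-1]]:
            keep[-1] = int(p)
    return np.asarray(keep, dtype=np.int64)


def detect_systolic_peaks(ppg: np.ndarray, fs: float) -> np.ndarray:
    """Systolic-peak detection with two event-related moving averages.

    Block-based scheme: bandpassed PPG is clipped at zero and squared; a
    111 ms "peak" moving average crossing above a 667 ms "beat" moving
    average (plus a small offset proportional to the mean squared amplitude)
    delimits systolic blocks; blocks shorter than 111 ms are rejected and
    each surviving block contributes its PPG argmax.  A 300 ms minimum
    separation suppresses double counting of dicrotic waves.
    """
    ppg = np.asarray(ppg, dtype=np.float64)
    if fs < 100:
        raise ValueError("systolic detection requires fs >= 100 Hz")
    if len(ppg) < 2 * fs:
        raise ValueError("need at least 2 s of PPG")
    if np.ptp(ppg) == 0:
        return np.asarray([], dtype=np.int64)

    filtered = cheby2_bandpass(ppg, fs, *PPG_BAND_HZ)
    clipped = np.clip(filtered, 0.0, None)
    squared = clipped**2

    w_peak = int(round(0.111 * fs))
    w_beat = int(round(0.667 * fs))
    ma_peak = _moving_average(squared, w_peak)
    ma_beat = _moving_average(squared, w_beat)
    alpha = 0.02 * float(np.mean(squared))
    interest = ma_peak > (ma_beat + alpha)

    min_sep = int(round(0.3 * fs))
    peaks: List[int] = []
    edges = np.flatnonzero(np.diff(interest.astype(np.int8)))
    starts = list(edges[::2] + 1) if interest[0] == 0 else [0] + list(edges[1::2] + 1)
    # recompute block boundaries robustly
    blocks: List[Tuple[int, int]] = []
    in_block = False
    for i, flag in enumerate(interest):
        if flag and not in_block:
            start = i
            in_block = True
        elif not flag and in_block:
            blocks.append((start, i))
            in_block = False
    if in_block:
        blocks.append((start, len(interest)))

    for lo, hi in blocks:
        if hi - lo < w_peak:
            continue
        p = lo + int(np.argmax(filtered[lo:hi]))
        if peaks and p - peaks[-1] < min_sep:
            if filtered[p] > filtered[peaks[-1]]:
                peaks[-1] = p
            continue
        peaks.append(p)
    return np.asarray(peaks, dtype=np.int64)


# ---------------------------------------------------------------------------
# Alignment I
# ---------------------------------------------------------------------------

def align_pair(
    record: Record, r_peaks: np.ndarray, sys_peaks: np.ndarray
) -> AlignedRecord:
    """Remove the pulse-arrival-time lag (Alignment I).

    The third systolic peak is matched with the nearest R peak at or before
    it (PPG trails ECG physiologically); the PPG channel is advanced by that
    lag and both channels are truncated to the common overlap, so the
    aligned record is shorter than the original.
    """
    r_peaks = np.asarray(r_peaks)
    sys_peaks = np.asarray(sys_peaks)
    if len(sys_peaks) < 3:
        raise ValueError("alignment needs at least 3 systolic peaks")
    third = int(sys_peaks[2])
    preceding = r_peaks[r_peaks <= third]
    if len(preceding) == 0:
        raise ValueError("no R peak at or before the third systolic peak")
    lag = third - int(preceding[-1])
    n = len(record) - lag
    return AlignedRecord(
        ecg=record.ecg[:n].copy(),
        ppg=record.ppg[lag : lag + n].copy(),
        lag_samples=lag,
        fs=record.fs,
        record_id=record.record_id,
    )


def normalize_minmax(
    x: np.ndarray, target_range: Tuple[float, float] = (0.0, 1.0)
) -> np.ndarray:
    """Affine per-record map of [min, max] onto ``target_range``."""
    x = np.asarray(x, dtype=np.float64)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise ValueError("cannot min-max normalise a constant signal")
    a, b = target_range
    return a + (x - lo) * (b - a) / (hi - lo)


# ---------------------------------------------------------------------------
# Segmentation / splitting / gap injection
# ---------------------------------------------------------------------------

def segment_record(aligned: AlignedRecord, cfg: RunConfig) -> List[SegmentPair]:
    """Normalise both channels to [0, 1], trim to ``record_seconds_used`` and
    cut into consecutive non-overlapping ``segment_seconds`` segments.

    The PPG input is scaled to [0, 1]; the ECG target is likewise scaled to
    [0, 1] per record, which keeps it inside the Tanh output range of the
    reconstruction networks.
    """
    seg_len = cfg.segment_samples
    total = int(round(cfg.record_seconds_used * cfg.fs))
    if len(aligned) < total:
        raise ValueError(
            f"aligned record {aligned.record_id} has {len(aligned)} samples; "
            f"{total} required"
        )
    ppg = normalize_minmax(aligned.ppg[:total])
    ecg = normalize_minmax(aligned.ecg[:total])
    n_seg = total // seg_len
    segments = []
    for k in range(n_seg):
        sl = slice(k * seg_len, (k + 1) * seg_len)
        segments.append(
            SegmentPair(
                ppg_in=ppg[sl].copy(),
                ecg_target=ecg[sl].copy(),
                mask=np.ones(seg_len, dtype=bool),
                segment_index=k,
                record_id=aligned.record_id,
            )
        )
    return segments


def split_segments(
    segments: Sequence[SegmentPair], fractions: Tuple[float, float, float] = (0.6, 0.2, 0.2)
) -> Tuple[range, range, range]:
    """Chronological split: first 60% train, next 20% validation, rest test."""
    n = len(segments)
    if n < 5:
        raise ValueError("need at least 5 segments to split")
    f_train, f_val, _ = fractions
    a = math.floor(f_train * n)
    b = math.floor((f_train + f_val) * n)
    return range(0, a), range(a, b), range(b, n)


def inject_gap(
    segments: Sequence[SegmentPair],
    cfg: RunConfig,
    rng: np.random.Generator,
) -> Tuple[List[SegmentPair], GapSpec]:
    """Zero out one contiguous missing-ECG span inside the training portion.

    The span start is drawn uniformly (from ``rng``) over the positions that
    keep the whole gap inside the training segments; it may cross segment
    boundaries.  Affected ECG samples are set to 0 with ``mask`` False; the
    PPG input is untouched.  Returns fresh segments plus the gap descriptor.
    """
    seg_len = cfg.segment_samples
    train_idx, _, _ = split_segments(segments, cfg.split_fractions)
    train_len = len(train_idx) * seg_len
    gap_len = int(round(cfg.gap_seconds * cfg.fs))
    if gap_len > train_len:
        raise ValueError(
            f"gap of {gap_len} samples exceeds the {train_len}-sample training portion"
        )
    start = int(rng.integers(0, train_len - gap_len + 1))
    out: List[SegmentPair] = []
    for seg in segments:
        lo = seg.segment_index * seg_len
        ecg = seg.ecg_target.copy()
        mask = seg.mask.copy()
        a = max(start - lo, 0)
        b = min(start + gap_len - lo, seg_len)
        if a < b:
            ecg[a:b] = 0.0
            mask[a:b] = False
        out.append(
            SegmentPair(
                ppg_in=seg.ppg_in.copy(),
                ecg_target=ecg,
                mask=mask,
                segment_index=seg.segment_index,
                record_id=seg.record_id,
            )
        )
    spec = GapSpec(
        gap_seconds=cfg.gap_seconds,
        start_sample=start,
        record_id=segments[0].record_id if segments else "record",
    )
    return out, spec


def preprocess_record(
    record: Record, cfg: RunConfig, inject: bool = True
) -> Tuple[List[SegmentPair], Tuple[range, range, range], GapSpec | None, AlignedRecord]:
    """Run the full per-record preprocessing chain.

    Returns the (possibly gapped) segments, the split index ranges, the gap
    descriptor (None when ``inject`` is False) and the aligned record.
    """
    ecg_f = cheby2_bandpass(record.ecg, record.fs, *ECG_BAND_HZ)
    ppg_f = cheby2_bandpass(record.ppg, record.fs, *PPG_BAND_HZ)
    filtered = Record(
        ecg=ecg_f, ppg=ppg_f, fs=record.fs, record_id=record.record_id,
        annotations=record.annotations,
    )
    r_peaks = detect_r_peaks(filtered.ecg, record.fs)
    sys_peaks = detect_systolic_peaks(filtered.ppg, record.fs)
    aligned = align_pair(filtered, r_peaks, sys_peaks)
    segments = segment_record(aligned, cfg)
    split = split_segments(segments, cfg.split_fractions)
    gap = None
    if inject:
        rng = np.random.default_rng(
            child_seed(cfg.seed, f"gap:{record.record_id}:{cfg.gap_seconds}")
        )
        segments, gap = inject_gap(segments, cfg, rng)
    return segments, split, gap, aligned
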