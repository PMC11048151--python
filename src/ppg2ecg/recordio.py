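"""Paired physiological record I/O and run configuration.

A :class:`Record` holds one simultaneously recorded ECG/PPG pair sampled at a
common rate (125 Hz by convention for the ICU waveform records this package
targets).  The canonical interchange format is a two-column CSV with an
``ecg,ppg`` header; reading standard WFDB header/signal pairs (format 16) is
supported as a convenience and is implemented natively so the package has no
hard dependency on a WFDB library.

All randomness in a pipeline run flows from ``RunConfig.seed`` through named
child seeds (see :func:`child_seed`), so a run is fully determined by its
configuration plus its input records.

Sample indexing is 0-based throughout the package; sample ``i`` corresponds to
time ``t = i / fs`` seconds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import os
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

DEFAULT_FS = 125.0

__all__ = [
    "Record",
    "RunConfig",
    "child_seed",
    "read_record_csv",
    "write_record_csv",
    "read_record_wfdb",
    "write_record_wfdb",
    "load_config",
]


def child_seed(seed: int, name: str) -> int:
    """Derive a stable, named child seed below 2**31 from a master seed.

    Uses SHA-256 of ``"{seed}:{name}"`` so the mapping is stable across runs,
    platforms and Python hash randomisation.
    """
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class Record:
    """One paired ECG + PPG recording.

    Attributes
    ----------
    ecg, ppg:
        Equal-length amplitude series (arbitrary units; normalised later in
        the pipeline).
    fs:
        Sampling rate in Hz (both channels share it).
    record_id:
        Identifier used in reports and file names.
    annotations:
        Optional ground-truth R-peak sample indices (known for synthetic
        records, absent for real ones).
    """

    ecg: np.ndarray
    ppg: np.ndarray
    fs: float = DEFAULT_FS
    record_id: str = "record"
    annotations: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=np.float64)
        self.ppg = np.asarray(self.ppg, dtype=np.float64)
        if self.ecg.ndim != 1 or self.ppg.ndim != 1:
            raise ValueError("ecg and ppg must be 1-D series")
        if len(self.ecg) != len(self.ppg):
            raise ValueError(
                f"ecg and ppg must have equal length, got {len(self.ecg)} != {len(self.ppg)}"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not (np.all(np.isfinite(self.ecg)) and np.all(np.isfinite(self.ppg))):
            raise ValueError("record contains non-finite samples")
        if self.annotations is not None:
            self.annotations = np.asarray(self.annotations, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return len(self.ecg) / self.fs


# Defaults follow the study protocol this package reimplements: 125 Hz
# recordings, 3 s segments (375 samples), first 294 s of each record,
# 60/20/20 chronological split, Adam for 500 epochs at batch 128 with
# lr 1e-3 decayed by 0.1 every 100 epochs.
@dataclass
class RunConfig:
    seed: int = 0
    fs: float = DEFAULT_FS
    segment_seconds: float = 3.0
    record_seconds_used: float = 294.0
    split_fractions: tuple = (0.6, 0.2, 0.2)
    gap_seconds: float = 2.0
    variant: str = "wnet"
    epochs: int = 500
    batch_size: int = 128
    lr: float = 1e-3
    lr_decay_factor: float = 0.1
    lr_decay_step: int = 100
    masked_loss: bool = False
    max_align_lag_seconds: float = 1.0
    allow_any_gap: bool = False

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        fr = tuple(float(f) for f in self.split_fractions)
        if len(fr) != 3 or any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must be 3 positive values summing to 1, got {fr}")
        self.split_fractions = fr
        n = self.segment_seconds * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"segment_seconds*fs must be an integer number of samples, got {n}"
            )
        if not self.allow_any_gap and self.gap_seconds not in (1.0, 2.0, 3.0, 4.0):
            raise ValueError(
                f"gap_seconds must be one of 1, 2, 3, 4 (got {self.gap_seconds}); "
                "set allow_any_gap to override"
            )
        if self.variant not in ("wnet", "wnet_bilstm"):
            raise ValueError(f"unknown model variant {self.variant!r}")

    @property
    def segment_samples(self) -> int:
        return int(round(self.segment_seconds * self.fs))

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def load_config(path: str) -> RunConfig:
    """Load a :class:`RunConfig` from a flat YAML key-value file.

    Unspecified keys take the study-protocol defaults; unknown keys are
    rejected so typos fail loudly.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "split_fractions" in data:
        data["split_fractions"] = tuple(data["split_fractions"])
    if "gap_seconds" in data:
        data["gap_seconds"] = float(data["gap_seconds"])
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def read_record_csv(path: str, fs: float = DEFAULT_FS, record_id: Optional[str] = None) -> Record:
    """Read a two-column ``ecg,ppg`` CSV into a :class:`Record`."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if list(df.columns) != ["ecg", "ppg"]:
        raise ValueError(
            f"{path}: expected columns ['ecg', 'ppg'], got {list(df.columns)}"
        )
    if len(df) == 0:
        raise ValueError(f"{path}: empty record")
    if not all(np.issubdtype(df[c].dtype, np.number) for c in df.columns):
        raise ValueError(f"{path}: non-numeric values in record")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in record")
    rid = record_id if record_id is not None else os.path.splitext(os.path.basename(path))[0]
    return Record(ecg=df["ecg"].to_numpy(), ppg=df["ppg"].to_numpy(), fs=fs, record_id=rid)


def write_record_csv(record: Record, path: str) -> None:
    """Write a record as ``ecg,ppg`` CSV (repr-round-trip float formatting)."""
    df = pd.DataFrame({"ecg": record.ecg, "ppg": record.ppg})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# WFDB (native, format 16 only)
# ---------------------------------------------------------------------------

def read_record_wfdb(record_name: str, ecg_channel: str = "II", ppg_channel: str = "PLETH") -> Record:
    """Read a local WFDB ``.hea``/``.dat`` pair into a :class:`Record`.

    Only single-segment records in the common 16-bit format ("16") with all
    channels in one signal file are supported, which covers the matched ICU
    waveform records this package targets.  Channels are selected by the
    signal description/name in the header.
    """
    header_path = record_name + ".hea"
    if not os.path.exists(header_path):
        raise FileNotFoundError(header_path)
    with open(header_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else DEFAULT_FS
    n_samp = int(head[3]) if len(head) > 3 else None
    sig_lines = lines[1 : 1 + n_sig]
    names, gains, baselines, fmts, files = [], [], [], [], []
    for ln in sig_lines:
        parts = ln.split()
        files.append(parts[0])
        fmts.append(parts[1])
        gain_spec = parts[2] if len(parts) > 2 else "200"
        m = re.match(r"([-+0-9.eE]+)(?:\(([-+0-9]+)\))?", gain_spec)
        gain = float(m.group(1)) if m else 200.0
        baseline = int(m.group(2)) if (m and m.group(2) is not None) else 0
        gains.append(gain if gain != 0 else 200.0)
        baselines.append(baseline)
        names.append(parts[-1])
    if any(f != "16" for f in fmts):
        raise ValueError(f"unsupported WFDB signal format(s) {sorted(set(fmts))}; only format 16 is supported")
    if len(set(files)) != 1:
        raise ValueError("multi-file WFDB records are not supported")
    for label in (ecg_channel, ppg_channel):
        if label not in names:
            raise ValueError(
                f"channel {label!r} not found in {header_path}; available: {names}"
            )
    dat_path = os.path.join(os.path.dirname(header_path), files[0])
    raw = np.fromfile(dat_path, dtype="<i2")
    raw = raw[: (len(raw) // n_sig) * n_sig].reshape(-1, n_sig)
    if n_samp is not None:
        raw = raw[:n_samp]

    def physical(label: str) -> np.ndarray:
        i = names.index(label)
        return (raw[:, i].astype(np.float64) - baselines[i]) / gains[i]

    return Record(
        ecg=physical(ecg_channel),
        ppg=physical(ppg_channel),
        fs=fs,
        record_id=os.path.basename(record_name),
    )


def write_record_wfdb(
    record: Record,
    record_name: str,
    ecg_channel: str = "II",
    ppg_channel: str = "PLETH",
    gain: float = 1000.0,
) -> None:
    """Write a record as a WFDB ``.hea``/``.dat`` pair (format 16).

    Amplitudes are quantised to ``1/gain`` physical units; round-tripping is
    exact for amplitudes that are integer multiples of the quantum within the
    16-bit range.
    """
    n = len(record)
    base = os.path.basename(record_name)
    dat_file = base + ".dat"
    digital = np.empty((n, 2), dtype="<i2")
    for j, x in enumerate((record.ecg, record.ppg)):
        d = np.rint(x * gain)
        if np.any(np.abs(d) > 32767):
            raise ValueError("amplitude exceeds 16-bit range at the chosen gain")
        digital[:, j] = d.astype("<i2")
    digital.tofile(record_name + ".dat")
    fs_txt = f"{record.fs:g}"
    with open(record_name + ".hea", "w") as fh:
        fh.write(f"{base} 2 {fs_txt} {n}\n")
        fh.write(f"{dat_file} 16 {gain:g}(0) 16 0 0 0 0 {ecg_channel}\n")
        fh.write(f"{dat_file} 16 {gain:g}(0) 16 0 0 0 0 {ppg_channel}\n")
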