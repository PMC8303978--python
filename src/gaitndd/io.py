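"""Reading, validating, and windowing vertical ground reaction force records.

A record is a 5-minute (typically) two-channel force time series: left-foot
(LF) and right-foot (RF) force sampled at a common rate.  The compound-foot
(CF) channel is the elementwise sum LF + RF.  Records are segmented into
non-overlapping, contiguous windows of 10, 30, or 60 s anchored at t = 0;
partial tail windows are discarded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

log = logging.getLogger(__name__)

GROUPS = ("HC", "ALS", "HD", "PD")

#: Sampling rate of the public gait database this package targets, in Hz.
DEFAULT_FS = 300.0


class FormatError(ValueError):
    """A force-record file violates the expected plain-text dialect."""


@dataclass
class GaitRecord:
    """One subject's two-channel vGRF time series.

    Parameters
    ----------
    subject_id : str
        Unique identifier within a cohort.
    group : str
        One of ``HC``, ``ALS``, ``HD``, ``PD``.
    fs : float
        Sampling rate in Hz, > 0.
    lf, rf : ndarray
        Left-foot and right-foot force series (arbitrary force units),
        equal length, finite, non-negative after calibration.
    """

    subject_id: str
    group: str
    fs: float
    lf: np.ndarray
    rf: np.ndarray

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        self.lf = np.asarray(self.lf, dtype=float)
        self.rf = np.asarray(self.rf, dtype=float)
        if self.lf.shape != self.rf.shape or self.lf.ndim != 1:
            raise ValueError("lf and rf must be 1-D arrays of equal length")
        if not (np.isfinite(self.lf).all() and np.isfinite(self.rf).all()):
            raise ValueError("force values must be finite")
        if (self.lf < 0).any() or (self.rf < 0).any():
            raise ValueError("force values must be >= 0 after calibration")

    @property
    def n_samples(self) -> int:
        return self.lf.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        if name == "LF":
            return self.lf
        if name == "RF":
            return self.rf
        if name == "CF":
            return compose_cf(self)
        raise ValueError(f"unknown channel {name!r}; expected LF, RF, or CF")


@dataclass
class SignalWindow:
    """A fixed-length segment of one channel of a record."""

    subject_id: str
    group: str
    channel: str
    window_s: float
    index: int
    fs: float
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        expected = int(round(self.window_s * self.fs))
        if self.samples.size != expected:
            raise ValueError(
                f"window has {self.samples.size} samples, expected {expected}"
            )


def read_record(
    path: str | Path,
    group: str,
    fs: float = DEFAULT_FS,
    subject_id: str | None = None,
    clamp_negative: bool = True,
) -> GaitRecord:
    """Parse a plain-text force record.

    Two dialects are auto-detected by column count: ``LF RF`` (2 columns)
    and ``time LF RF`` (3 or more columns, forces in columns 2-3).
    Whitespace or comma separated.  Small negative baseline values are
    clamped to 0 (the force sensor reads 0 with no load); the clamp count
    is logged.
    """
    path = Path(path)
    lf_vals: list[float] = []
    rf_vals: list[float] = []
    ncols: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip().replace(",", " ")
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if ncols is None:
                ncols = len(parts)
                if ncols < 2:
                    raise FormatError(f"{path}: line {lineno}: fewer than 2 columns")
            elif len(parts) != ncols:
                raise FormatError(
                    f"{path}: line {lineno}: ragged row ({len(parts)} columns, "
                    f"expected {ncols}): {line!r}"
                )
            offset = 0 if ncols == 2 else 1
            try:
                lf_vals.append(float(parts[offset]))
                rf_vals.append(float(parts[offset + 1]))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-numeric field in {line!r}"
                ) from None
    if not lf_vals:
        raise FormatError(f"{path}: empty file")
    lf = np.array(lf_vals)
    rf = np.array(rf_vals)
    if clamp_negative:
        n_neg = int((lf < 0).sum() + (rf < 0).sum())
        if n_neg:
            log.info("%s: clamped %d negative baseline samples to 0", path, n_neg)
        lf = np.maximum(lf, 0.0)
        rf = np.maximum(rf, 0.0)
    return GaitRecord(
        subject_id=subject_id or path.stem, group=group, fs=fs, lf=lf, rf=rf
    )


def compose_cf(record: GaitRecord) -> np.ndarray:
    """Compound-foot force: the elementwise sum LF + RF."""
    return record.lf + record.rf


def segment_windows(
    record: GaitRecord, channel: str, window_s: float
) -> list[SignalWindow]:
    """Split one channel into successive non-overlapping windows from t = 0.

    The partial tail (less than ``window_s`` long) is discarded, so a
    5-minute record yields 30 / 10 / 5 windows at 10 / 30 / 60 s.
    """
    wlen_f = window_s * record.fs
    wlen = int(round(wlen_f))
    if abs(wlen_f - wlen) > 1e-9:
        raise ValueError(f"window_s * fs = {wlen_f} is not an integer sample count")
    x = record.channel(channel)
    n_win = x.size // wlen
    if n_win == 0:
        warnings.warn(
            f"record {record.subject_id}: window of {window_s} s longer than "
            f"record ({record.duration_s:.1f} s); no windows produced",
            stacklevel=2,
        )
        return []
    return [
        SignalWindow(
            subject_id=record.subject_id,
            group=record.group,
            channel=channel,
            window_s=window_s,
            index=i,
            fs=record.fs,
            samples=x[i * wlen : (i + 1) * wlen],
        )
        for i in range(n_win)
    ]


def cohort_window_census(
    cohort: Iterable[GaitRecord], window_s: float
) -> dict[str, int]:
    """Per-group and total window counts for a cohort at one window length.

    Returns a mapping ``{group: count, ..., "total": count}``.  For the
    database's cohort (16 HC / 13 ALS / 20 HD / 15 PD five-minute records)
    this reproduces 1920 / 640 / 320 total spectrogram inputs at
    10 / 30 / 60 s.
    """
    counts: dict[str, int] = {g: 0 for g in GROUPS}
    for rec in cohort:
        wlen = int(round(window_s * rec.fs))
        counts[rec.group] += rec.n_samples // wlen
    counts["total"] = sum(counts[g] for g in GROUPS)
    return counts


def write_record(path: str | Path, record: GaitRecord) -> None:
    """Write a record in the 3-column ``time LF RF`` text dialect."""
    t = np.arange(record.n_samples) / record.fs
    np.savetxt(
        path,
        np.column_stack([t, record.lf, record.rf]),
        fmt="%.6f",
        header=f"subject={record.subject_id} group={record.group} fs={record.fs}",
    )


def write_manifest(
    path: str | Path, entries: Iterable[tuple[str, str, str]]
) -> None:
    """Write a cohort manifest: one ``path<TAB>subject_id<TAB>group`` per line."""
    with open(path, "w") as fh:
        for rec_path, subject_id, group in entries:
            fh.write(f"{rec_path}\t{subject_id}\t{group}\n")


def read_manifest(
    path: str | Path, fs: float = DEFAULT_FS
) -> list[GaitRecord]:
    """Load every record listed in a cohort manifest file."""
    base = Path(path).parent
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rec_path, subject_id, group = line.split("\t")
            p = Path(rec_path)
            if not p.is_absolute():
                p = base / p
            records.append(read_record(p, group=group, fs=fs, subject_id=subject_id))
    return records
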