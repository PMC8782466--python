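"""Raw accelerometry to per-minute activity counts.

Wrist-worn accelerometers record tri-axial acceleration (in gravitational
force equivalents, g) at 32 Hz.  Actigraphy analyses operate on a much
coarser object: one non-negative *activity count* per minute, defined as the
mean absolute deviation of the acceleration magnitude from gravity over the
minute,

    count[m] = mean over minute m of | sqrt(x^2 + y^2 + z^2) - gravity | .

This module holds the domain containers (:class:`RawAccelSeries`,
:class:`ActivitySeries`, :class:`EpochSpec`), the CSV dialects used for both
levels, the raw-to-minute conversion, mean imputation of missing minutes,
and epoch extraction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "RawAccelSeries",
    "ActivitySeries",
    "EpochSpec",
    "ParseError",
    "MissingDataError",
    "read_raw_accel",
    "write_raw_accel",
    "read_minute_csv",
    "write_minute_csv",
    "minute_counts",
    "impute_missing",
    "extract_epoch",
    "MinuteCountExtractor",
]

STATES = ("manic", "euthymic", "unlabelled")


class ParseError(ValueError):
    """A raw or per-minute CSV file could not be parsed."""


class MissingDataError(ValueError):
    """Too much missing data for the series to be analysable.

    Attributes
    ----------
    missing_frac : float
        Fraction of minutes that are missing.
    """

    def __init__(self, msg: str, missing_frac: float):
        super().__init__(msg)
        self.missing_frac = missing_frac


@dataclass
class RawAccelSeries:
    """Tri-axial acceleration sampled at a fixed rate, in g-equivalents."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sampling_rate: float = 32.0
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("x, y, z must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def magnitude(self) -> np.ndarray:
        """Euclidean norm of the acceleration vector, per sample."""
        return np.sqrt(self.x**2 + self.y**2 + self.z**2)


@dataclass
class ActivitySeries:
    """Per-minute activity counts with a missingness mask.

    ``counts[i]`` is meaningful only where ``missing_mask[i]`` is False.
    """

    counts: np.ndarray
    missing_mask: np.ndarray | None = None
    start_time: datetime | None = None
    subject_id: str | None = None
    state: str = "unlabelled"
    epoch: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(len(self.counts), dtype=bool)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if len(self.missing_mask) != len(self.counts):
            raise ValueError("missing_mask and counts must have equal length")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        observed = self.counts[~self.missing_mask]
        if observed.size and (np.nanmin(observed) < 0):
            raise ValueError("observed activity counts must be non-negative")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def missing_frac(self) -> float:
        return float(self.missing_mask.mean()) if len(self) else 0.0

    @property
    def values(self) -> np.ndarray:
        """The counts, requiring a fully observed series."""
        if self.missing_mask.any():
            raise MissingDataError(
                "series has missing minutes; impute_missing() first",
                self.missing_frac,
            )
        return self.counts


@dataclass(frozen=True)
class EpochSpec:
    """A contiguous analysis window inside a per-minute series."""

    offset_minutes: int
    duration_minutes: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.offset_minutes < 0:
            raise ValueError("offset_minutes must be >= 0")
        if self.duration_minutes <= 0:
            raise ValueError("duration_minutes must be > 0")


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def read_raw_accel(
    path,
    dialect: str = "empatica_header",
    sampling_rate: float = 32.0,
    start_time: datetime | None = None,
) -> RawAccelSeries:
    """Read a raw tri-axial CSV file.

    ``empatica_header``: row 1 holds the start UNIX timestamp (repeated per
    column), row 2 the sampling rate per column, then one ``x,y,z`` row per
    sample.  ``plain_xyz``: only ``x,y,z`` rows; rate and start come from the
    keyword arguments.
    """
    if dialect not in ("empatica_header", "plain_xyz"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                rows.append([float(v) for v in row])
            except ValueError as exc:
                raise ParseError(f"{path}: non-numeric value on line {lineno}: {row}") from exc
            if len(rows[-1]) != 3:
                raise ParseError(
                    f"{path}: expected 3 columns on line {lineno}, got {len(rows[-1])}"
                )
    if dialect == "empatica_header":
        if len(rows) < 3:
            raise ParseError(f"{path}: empatica_header file needs timestamp, rate and data rows")
        start_time = datetime.utcfromtimestamp(rows[0][0])
        sampling_rate = rows[1][0]
        rows = rows[2:]
    data = np.asarray(rows, dtype=float)
    return RawAccelSeries(
        x=data[:, 0], y=data[:, 1], z=data[:, 2],
        sampling_rate=sampling_rate, start_time=start_time,
    )


def write_raw_accel(series: RawAccelSeries, path, dialect: str = "empatica_header") -> None:
    """Write a raw series in the dialects :func:`read_raw_accel` understands."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if dialect == "empatica_header":
            ts = series.start_time.timestamp() if series.start_time else 0.0
            writer.writerow([repr(ts)] * 3)
            writer.writerow([repr(float(series.sampling_rate))] * 3)
        elif dialect != "plain_xyz":
            raise ValueError(f"unknown dialect {dialect!r}")
        for xi, yi, zi in zip(series.x, series.y, series.z):
            writer.writerow([repr(float(xi)), repr(float(yi)), repr(float(zi))])


def read_minute_csv(path, subject_id: str | None = None, state: str = "unlabelled") -> ActivitySeries:
    """Read a per-minute series CSV (``timestamp,counts``; empty field = missing).

    Leading lines starting with ``#`` (provenance headers) are skipped.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if list(df.columns[:2]) != ["timestamp", "counts"]:
        raise ParseError(f"{path}: expected header 'timestamp,counts', got {list(df.columns)}")
    counts = pd.to_numeric(df["counts"], errors="coerce").to_numpy(dtype=float)
    mask = np.isnan(counts)
    counts = np.where(mask, 0.0, counts)
    ts = pd.to_datetime(df["timestamp"])
    start = ts.iloc[0].to_pydatetime() if len(ts) else None
    return ActivitySeries(counts=counts, missing_mask=mask, start_time=start,
                          subject_id=subject_id, state=state)


def write_minute_csv(series: ActivitySeries, path, header_comment: str | None = None) -> None:
    """Write a per-minute series CSV; missing minutes get an empty counts field."""
    start = series.start_time or datetime(2000, 1, 1)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("timestamp,counts\n")
        for i, (c, miss) in enumerate(zip(series.counts, series.missing_mask)):
            stamp = (start + timedelta(minutes=i)).strftime("%Y-%m-%dT%H:%M")
            fh.write(f"{stamp},{'' if miss else repr(float(c))}\n")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def minute_counts(raw: RawAccelSeries, gravity: float = 1.0) -> ActivitySeries:
    """Collapse a raw series into per-minute activity counts.

    Each count is the mean of ``|magnitude - gravity|`` over one full minute
    (``sampling_rate * 60`` samples, 1920 at 32 Hz).  A trailing partial
    minute is discarded.
    """
    spm = int(round(raw.sampling_rate * 60))
    if spm <= 0:
        raise ValueError("sampling_rate too small to define a minute")
    n_min = len(raw) // spm
    if n_min < 1:
        raise ValueError(
            f"raw series has {len(raw)} samples, fewer than one minute ({spm})"
        )
    dev = np.abs(raw.magnitude[: n_min * spm] - gravity)
    counts = dev.reshape(n_min, spm).mean(axis=1)
    return ActivitySeries(counts=counts, start_time=raw.start_time)


def impute_missing(series: ActivitySeries, max_missing_frac: float = 0.05) -> ActivitySeries:
    """Replace missing minutes by the mean of the observed minutes.

    Acceptable only when the missing fraction is strictly below
    ``max_missing_frac`` (default 5%); otherwise the recording is rejected
    with a :class:`MissingDataError` carrying the fraction.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    frac = series.missing_frac
    if not series.missing_mask.any():
        return replace(series)
    if series.missing_mask.all():
        raise MissingDataError("all minutes are missing", frac)
    if frac >= max_missing_frac:
        raise MissingDataError(
            f"missing fraction {frac:.4f} >= threshold {max_missing_frac}", frac
        )
    observed_mean = series.counts[~series.missing_mask].mean()
    counts = np.where(series.missing_mask, observed_mean, series.counts)
    return replace(series, counts=counts, missing_mask=np.zeros(len(series), dtype=bool))


def extract_epoch(series: ActivitySeries, spec: EpochSpec) -> ActivitySeries:
    """Return the contiguous sub-series ``[offset, offset + duration)``."""
    end = spec.offset_minutes + spec.duration_minutes
    if end > len(series):
        raise ValueError(
            f"epoch {spec.label!r} [{spec.offset_minutes}, {end}) exceeds "
            f"series length {len(series)}"
        )
    sl = slice(spec.offset_minutes, end)
    start = (
        series.start_time + timedelta(minutes=spec.offset_minutes)
        if series.start_time else None
    )
    return replace(
        series,
        counts=series.counts[sl].copy(),
        missing_mask=series.missing_mask[sl].copy(),
        start_time=start,
        epoch=spec.label or series.epoch,
    )


class MinuteCountExtractor(TransformerMixin, BaseEstimator):
    """Transformer mapping raw tri-axial recordings to per-minute counts.

    ``transform`` accepts a sequence of :class:`RawAccelSeries` (or
    ``(x, y, z)`` array triples, interpreted at ``sampling_rate``) and returns
    a list of :class:`ActivitySeries`.  Stateless: ``fit`` only validates
    parameters.
    """

    def __init__(self, gravity: float = 1.0, sampling_rate: float = 32.0):
        self.gravity = gravity
        self.sampling_rate = sampling_rate

    def fit(self, X, y=None):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        self.n_features_in_ = 3
        return self

    def transform(self, X: Sequence) -> list[ActivitySeries]:
        out = []
        for item in X:
            if not isinstance(item, RawAccelSeries):
                x, y, z = item
                item = RawAccelSeries(x=x, y=y, z=z, sampling_rate=self.sampling_rate)
            out.append(minute_counts(item, gravity=self.gravity))
        return out
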