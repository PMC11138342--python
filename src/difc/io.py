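"""Scan and detection-table data model and columnar text I/O.

A *scan* is a uniformly sampled four-channel fluorescence intensity time
series: two fiber probes (1 and 2) separated by a few millimeters along a
blood vessel, each with a green (GFP-band) and an orange (tdTomato-band)
photomultiplier channel, in millivolts.

The on-disk trace format is plain columnar text: ``# key: value`` metadata
lines followed by a CSV header
``time_s,p1_green_mV,p1_orange_mV,p2_green_mV,p2_orange_mV`` and one row per
sample.  Time is defined by sample index at a fixed sampling rate; an
explicit time column is validated against it on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GREEN",
    "ORANGE",
    "COLORS",
    "CHANNELS",
    "ChannelId",
    "Scan",
    "DetectionRecord",
    "FormatError",
    "DEFAULT_PROBE_SEPARATION_MM",
    "DEFAULT_SAMPLING_RATE_HZ",
    "CLASSIFICATIONS",
    "read_scan",
    "write_scan",
    "read_detections",
    "write_detections",
]

GREEN = "green"
ORANGE = "orange"
COLORS = (GREEN, ORANGE)

#: Physical distance between the two fiber probes along the vessel.
DEFAULT_PROBE_SEPARATION_MM = 3.0
#: Used when a trace file does not declare a rate; kHz-class PMT sampling.
DEFAULT_SAMPLING_RATE_HZ = 2000.0

#: Detection classification labels carried by :class:`DetectionRecord`.
CLASSIFICATIONS = ("single_1FP", "cluster_1FP", "cluster_2FP", "indeterminate")

_FLAGS = ("saturated", "artifact")


class FormatError(ValueError):
    """A scan or detection file violates the expected layout."""


@dataclass(frozen=True, order=True)
class ChannelId:
    """One of the four detector channels (probe x color)."""

    probe: int
    color: str

    def __post_init__(self) -> None:
        if self.probe not in (1, 2):
            raise ValueError(f"probe must be 1 or 2, got {self.probe!r}")
        if self.color not in COLORS:
            raise ValueError(f"color must be one of {COLORS}, got {self.color!r}")

    @property
    def label(self) -> str:
        """Short instrument-style label, e.g. ``P1-G``."""
        return f"P{self.probe}-{'G' if self.color == GREEN else 'O'}"

    @property
    def column(self) -> str:
        """Trace-file column name, e.g. ``p1_green_mV``."""
        return f"p{self.probe}_{self.color}_mV"


#: The four channels of every scan, in file-column order.
CHANNELS = (
    ChannelId(1, GREEN),
    ChannelId(1, ORANGE),
    ChannelId(2, GREEN),
    ChannelId(2, ORANGE),
)


@dataclass
class Scan:
    """A four-channel mV time series with probe geometry metadata.

    Parameters
    ----------
    sampling_rate : float
        Samples per second; strictly positive.
    signal : mapping of ChannelId -> ndarray
        One mV vector per channel; all four channels present with equal
        length and finite values.
    probe_separation_mm : float
        Distance between probe sensing regions along the vessel.
    metadata : dict
        Free-form scan id / subject id / scenario tag entries.
    """

    sampling_rate: float
    signal: Mapping[ChannelId, np.ndarray]
    probe_separation_mm: float = DEFAULT_PROBE_SEPARATION_MM
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        if not self.probe_separation_mm > 0:
            raise ValueError("probe_separation_mm must be > 0")
        sig = {}
        lengths = set()
        for ch in CHANNELS:
            if ch not in self.signal:
                raise ValueError(f"missing channel {ch.label}")
            v = np.asarray(self.signal[ch], dtype=float)
            if v.ndim != 1:
                raise ValueError(f"channel {ch.label} is not a 1-D series")
            sig[ch] = v
            lengths.add(v.size)
        if len(lengths) != 1:
            raise ValueError(f"channel lengths differ: {sorted(lengths)}")
        object.__setattr__(self, "signal", sig)

    @property
    def n_samples(self) -> int:
        return next(iter(self.signal.values())).size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (index / sampling_rate)."""
        return np.arange(self.n_samples) / self.sampling_rate

    def validate_finite(self) -> None:
        for ch, v in self.signal.items():
            if v.size and not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite samples in channel {ch.label}")


@dataclass(frozen=True)
class DetectionRecord:
    """One counted cell or cluster detection after the full pipeline."""

    time_s: float
    color: str
    direction: str  # "forward" (arterial) or "reverse" (venous)
    amplitude_mV: float
    amplitude_sigma: float  # in local-noise-sigma units; >= 5 when retained
    width_s: float
    classification: str
    n_green: int = 0
    n_orange: int = 0
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.color not in COLORS:
            raise ValueError(f"unknown color {self.color!r}")
        if self.n_green < 0 or self.n_orange < 0:
            raise ValueError("cell counts must be >= 0")
        bad = set(self.flags) - set(_FLAGS)
        if bad:
            raise ValueError(f"unknown flags {sorted(bad)}")


# ---------------------------------------------------------------------------
# scan files

_SCAN_COLUMNS = ["time_s"] + [ch.column for ch in CHANNELS]


def write_scan(scan: Scan, path: str | Path) -> None:
    """Write *scan* as self-describing columnar text (lossless round trip)."""
    scan.validate_finite()
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sampling_rate_hz: {scan.sampling_rate!r}\n")
        fh.write(f"# probe_separation_mm: {scan.probe_separation_mm!r}\n")
        for key, val in scan.metadata.items():
            fh.write(f"# {key}: {val}\n")
        fh.write(",".join(_SCAN_COLUMNS) + "\n")
        data = np.column_stack(
            [scan.times] + [scan.signal[ch] for ch in CHANNELS]
        )
        # %.17g preserves doubles bit-exactly through the text round trip
        np.savetxt(fh, data, fmt="%.17g", delimiter=",")


def _parse_sidecar(lines: Iterable[str]) -> dict:
    meta = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            meta[key.strip()] = val.strip()
    return meta


def read_scan(path: str | Path, sampling_rate: float | None = None) -> Scan:
    """Read a columnar-text scan file.

    ``sampling_rate`` overrides the sidecar value; when neither is present
    the default of 2000 samples/s is used.  A missing
    ``probe_separation_mm`` falls back to the 3 mm physical separation of
    the instrument.
    """
    path = Path(path)
    header_lines: list[str] = []
    with path.open() as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                header_lines.append(line)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        try:
            df = pd.read_csv(fh, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            raise FormatError(f"{path}: no column header found")
    meta = _parse_sidecar(header_lines)

    missing = [c for c in _SCAN_COLUMNS[1:] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing channel column(s) {missing}")

    if sampling_rate is None:
        sampling_rate = float(meta.pop("sampling_rate_hz", DEFAULT_SAMPLING_RATE_HZ))
    else:
        meta.pop("sampling_rate_hz", None)
    sep = float(meta.pop("probe_separation_mm", DEFAULT_PROBE_SEPARATION_MM))

    n = len(df)
    if "time_s" in df.columns and n:
        expected = np.arange(n) / sampling_rate
        tol = 1.0 / sampling_rate
        if np.max(np.abs(df["time_s"].to_numpy() - expected)) > tol:
            raise FormatError(
                f"{path}: time column deviates from uniform sampling at "
                f"{sampling_rate} Hz by more than one sample period"
            )

    signal = {ch: df[ch.column].to_numpy(dtype=float) for ch in CHANNELS}
    return Scan(
        sampling_rate=sampling_rate,
        signal=signal,
        probe_separation_mm=sep,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# detection tables

_DET_COLUMNS = [
    "time_s",
    "color",
    "direction",
    "amplitude_mV",
    "amplitude_sigma",
    "width_s",
    "classification",
    "n_green",
    "n_orange",
    "flags",
]


def write_detections(records: Sequence[DetectionRecord], path: str | Path) -> None:
    """Write detection records as a CSV table (flags semicolon-joined)."""
    rows = [
        {
            "time_s": r.time_s,
            "color": r.color,
            "direction": r.direction,
            "amplitude_mV": r.amplitude_mV,
            "amplitude_sigma": r.amplitude_sigma,
            "width_s": r.width_s,
            "classification": r.classification,
            "n_green": r.n_green,
            "n_orange": r.n_orange,
            "flags": ";".join(sorted(r.flags)),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=_DET_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_detections(path: str | Path) -> list[DetectionRecord]:
    df = pd.read_csv(Path(path), keep_default_na=False, float_precision="round_trip")
    missing = [c for c in _DET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    records = []
    for row in df.itertuples(index=False):
        if row.classification not in CLASSIFICATIONS:
            raise FormatError(
                f"{path}: unknown classification label {row.classification!r}"
            )
        flags = frozenset(f for f in str(row.flags).split(";") if f)
        records.append(
            DetectionRecord(
                time_s=float(row.time_s),
                color=str(row.color),
                direction=str(row.direction),
                amplitude_mV=float(row.amplitude_mV),
                amplitude_sigma=float(row.amplitude_sigma),
                width_s=float(row.width_s),
                classification=str(row.classification),
                n_green=int(row.n_green),
                n_orange=int(row.n_orange),
                flags=flags,
            )
        )
    return records
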