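"""Minimal standard-EDF (16-bit) writing and header inspection.

Reading of EDF signal data is delegated to :mod:`mne` (see
:func:`qeegprog.eeg_io.read_edf`).  This module provides the two pieces
mne does not: a standards-compliant writer used to build synthetic
fixtures, and a light header peek used to validate label uniqueness and
per-signal sampling rates before decoding (mne silently renames duplicate
labels instead of rejecting them).

The EDF container is a 256-byte fixed-width ASCII header, 256 bytes of
per-signal header fields, and little-endian int16 data records.  Physical
values are mapped linearly onto the digital range; one quantization step
is ``(phys_max - phys_min) / (dig_max - dig_min)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

DIG_MIN = -32768
DIG_MAX = 32767


class EdfFormatError(ValueError):
    """Raised when a file does not parse as standard EDF."""


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    """Format a number into a fixed-width ASCII field, maximising precision."""
    for fmt in (f"%.{p}g" for p in range(10, 0, -1)):
        s = fmt % value
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise ValueError(f"cannot format {value} in {width} chars")


@dataclass
class EdfSignalHeader:
    label: str
    n_samples_per_record: int
    physical_min: float
    physical_max: float
    digital_min: int = DIG_MIN
    digital_max: int = DIG_MAX
    physical_dimension: str = "uV"

    @property
    def quantization_step(self) -> float:
        return (self.physical_max - self.physical_min) / (
            self.digital_max - self.digital_min
        )


@dataclass
class EdfHeader:
    n_records: int
    record_duration_s: float
    signals: list[EdfSignalHeader]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.signals]

    def sampling_rate(self, i: int) -> float:
        return self.signals[i].n_samples_per_record / self.record_duration_s


def peek_header(path: str | Path) -> EdfHeader:
    """Parse only the EDF header (no signal data)."""
    path = Path(path)
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise EdfFormatError(f"{path}: truncated EDF header")
        try:
            version = fixed[0:8].decode("ascii").strip()
            n_records = int(fixed[236:244].decode("ascii").strip())
            record_duration = float(fixed[244:252].decode("ascii").strip())
            ns = int(fixed[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise EdfFormatError(f"{path}: malformed EDF header ({exc})") from exc
        if version != "0":
            raise EdfFormatError(f"{path}: unsupported EDF version {version!r}")
        if ns < 1:
            raise EdfFormatError(f"{path}: header declares {ns} signals")
        per = fh.read(256 * ns)
        if len(per) < 256 * ns:
            raise EdfFormatError(f"{path}: truncated signal headers")

    def col(offset: int, width: int) -> list[str]:
        base = offset * ns
        return [
            per[base + i * width : base + (i + 1) * width].decode("ascii").strip()
            for i in range(ns)
        ]

    labels = col(0, 16)
    dims = col(16 + 80, 8)
    pmin = [float(x) for x in col(16 + 80 + 8, 8)]
    pmax = [float(x) for x in col(16 + 80 + 8 + 8, 8)]
    dmin = [int(x) for x in col(16 + 80 + 8 + 8 + 8, 8)]
    dmax = [int(x) for x in col(16 + 80 + 8 + 8 + 8 + 8, 8)]
    nspr = [int(x) for x in col(16 + 80 + 8 * 5 + 80, 8)]
    signals = [
        EdfSignalHeader(
            label=labels[i],
            n_samples_per_record=nspr[i],
            physical_min=pmin[i],
            physical_max=pmax[i],
            digital_min=dmin[i],
            digital_max=dmax[i],
            physical_dimension=dims[i],
        )
        for i in range(ns)
    ]
    return EdfHeader(
        n_records=n_records, record_duration_s=record_duration, signals=signals
    )


def write_edf(
    path: str | Path,
    data_uv: np.ndarray,
    labels: list[str],
    fs: float,
    physical_range_uv: tuple[float, float] | None = None,
    record_duration_s: float = 1.0,
) -> Path:
    """Write ``data_uv`` (channels x samples, µV) as a 16-bit EDF file.

    The sampling rate per record-duration must be an integer; trailing
    samples that do not fill a whole data record are dropped.  When
    ``physical_range_uv`` is None a symmetric range covering the data is
    chosen; data outside an explicit range raises, advising rescale.
    """
    path = Path(path)
    data_uv = np.asarray(data_uv, dtype=float)
    if data_uv.ndim != 2 or data_uv.size == 0:
        raise ValueError("data must be a non-empty channels x samples array")
    if len(labels) != data_uv.shape[0]:
        raise ValueError("one label per channel required")
    if not np.all(np.isfinite(data_uv)):
        raise ValueError("data contains non-finite samples")
    nspr = fs * record_duration_s
    if abs(nspr - round(nspr)) > 1e-9:
        raise ValueError(
            f"fs*record_duration = {nspr} is not an integer sample count"
        )
    nspr = int(round(nspr))
    n_records = data_uv.shape[1] // nspr
    if n_records < 1:
        raise ValueError("recording shorter than one data record")

    if physical_range_uv is None:
        amp = float(np.max(np.abs(data_uv)))
        amp = max(amp, 1e-6)
        # small headroom so the extreme sample is representable exactly
        pmin, pmax = -amp * 1.001, amp * 1.001
    else:
        pmin, pmax = physical_range_uv
        if data_uv.min() < pmin or data_uv.max() > pmax:
            raise ValueError(
                "signal amplitude exceeds the physical range "
                f"[{pmin}, {pmax}] µV; rescale the signal or widen the range"
            )

    gain = (DIG_MAX - DIG_MIN) / (pmax - pmin)
    digital = np.round((data_uv - pmin) * gain + DIG_MIN)
    digital = np.clip(digital, DIG_MIN, DIG_MAX).astype("<i2")

    ns = len(labels)
    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field("01.01.20", 8),
            _field("00.00.00", 8),
            _field(str(256 * (ns + 1)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _num(record_duration_s, 8),
            _field(str(ns), 4),
        ]
    )
    per = b"".join(
        [
            b"".join(_field(lab, 16) for lab in labels),
            b"".join(_field("", 80) for _ in labels),
            b"".join(_field("uV", 8) for _ in labels),
            b"".join(_num(pmin, 8) for _ in labels),
            b"".join(_num(pmax, 8) for _ in labels),
            b"".join(_field(str(DIG_MIN), 8) for _ in labels),
            b"".join(_field(str(DIG_MAX), 8) for _ in labels),
            b"".join(_field("", 80) for _ in labels),
            b"".join(_field(str(nspr), 8) for _ in labels),
            b"".join(_field("", 32) for _ in labels),
        ]
    )
    used = digital[:, : n_records * nspr].reshape(ns, n_records, nspr)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per)
        # records interleave channels: record r holds nspr samples per signal
        fh.write(np.ascontiguousarray(used.transpose(1, 0, 2)).tobytes())
    return path


def quantization_step(path: str | Path) -> float:
    """Largest per-signal quantization step of an EDF file, in physical units."""
    hdr = peek_header(path)
    return max(s.quantization_step for s in hdr.signals)
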