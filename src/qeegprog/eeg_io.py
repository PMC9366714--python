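"""EDF ingestion, 10–20 montage resolution and analysis-segment selection.

The prognostic features downstream are computed from a roughly 30-minute
stretch of the first continuous EEG monitoring session, so this module
reads an EDF recording into µV, resolves homologous left–right electrode
pairs (needed by the brain symmetry index) and cuts out the analysis
segment deterministically.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .edf import EdfFormatError, peek_header

__all__ = [
    "EegRecording",
    "MontageMap",
    "read_edf",
    "select_segment",
    "resolve_montage",
    "CHANNEL_ALIASES",
    "HOMOLOGOUS_PAIRS",
    "MIDLINE_LABELS",
]

#: modern 10–20 names mapped onto the older nomenclature used internally
CHANNEL_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

#: homologous (left, right) pairs of the 19-lead 10–20 montage
HOMOLOGOUS_PAIRS = [
    ("Fp1", "Fp2"),
    ("F3", "F4"),
    ("C3", "C4"),
    ("P3", "P4"),
    ("O1", "O2"),
    ("F7", "F8"),
    ("T3", "T4"),
    ("T5", "T6"),
]

MIDLINE_LABELS = ("Fz", "Cz", "Pz")

_AUX_PATTERN = re.compile(
    r"(EOG|ECG|EKG|EMG|RESP|SPO2|PULSE|STATUS|ANNOTATION|MARKER|EVENT|TRIG)",
    re.IGNORECASE,
)


@dataclass
class EegRecording:
    """Multichannel scalp EEG in physical units.

    Attributes
    ----------
    channel_labels : list of str
        10–20 electrode names, unique.
    fs : float
        Sampling rate in Hz.
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    start_offset : float
        Seconds from the start of the source record.
    aux_labels, aux_data
        Non-EEG channels (EOG/ECG/...) separated out of the montage but
        retained for optional artifact regression.
    """

    channel_labels: list[str]
    fs: float
    data: np.ndarray
    start_offset: float = 0.0
    aux_labels: list[str] = field(default_factory=list)
    aux_data: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        lowered = [c.lower() for c in self.channel_labels]
        if len(set(lowered)) != len(lowered):
            dupes = sorted({c for c in lowered if lowered.count(c) > 1})
            raise ValueError(f"duplicate channel labels: {dupes}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class MontageMap:
    """Left–right homologous electrode pairs of a recording.

    ``pairs`` hold canonical (old-nomenclature) labels; ``midline`` the
    z-line electrodes excluded from pairing; ``unpaired`` lateral
    electrodes whose homologue is absent.
    """

    pairs: list[tuple[str, str]]
    midline: list[str]
    unpaired: list[str] = field(default_factory=list)

    def pair_indices(self, channel_labels: list[str]) -> list[tuple[int, int]]:
        """Map pairs onto channel indices of ``channel_labels``."""
        canon = {
            _canonical(lab).lower(): i for i, lab in enumerate(channel_labels)
        }
        return [(canon[l.lower()], canon[r.lower()]) for l, r in self.pairs]


def _canonical(label: str) -> str:
    label = label.strip()
    # strip common EDF prefixes like "EEG Fp1-Ref"
    m = re.match(r"(?:EEG\s+)?([A-Za-z]{1,2}[0-9z]{1,2})(?:-\w+)?$", label)
    if m:
        label = m.group(1)
    label = label[0].upper() + label[1:]
    if label.lower().startswith("fp"):
        label = "Fp" + label[2:]
    if label.lower().endswith("z"):
        label = label[:-1].upper() + "z"
    for new, old in CHANNEL_ALIASES.items():
        if label.lower() == new.lower():
            return old
    return label


def read_edf(path: str | Path) -> EegRecording:
    """Read an EDF file into an :class:`EegRecording` in µV.

    Non-EEG channels (annotation/EOG/ECG/... by label) are split into the
    aux arrays.  Duplicate EEG labels or EEG channels with differing
    sampling rates are rejected before decoding.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    hdr = peek_header(path)

    labels = hdr.labels
    eeg_idx = [
        i
        for i, lab in enumerate(labels)
        if not _AUX_PATTERN.search(lab)
    ]
    if not eeg_idx:
        raise EdfFormatError(f"{path}: no EEG channels found")
    eeg_labels = [labels[i] for i in eeg_idx]
    lowered = [_canonical(c).lower() for c in eeg_labels]
    if len(set(lowered)) != len(lowered):
        dupes = sorted({c for c in lowered if lowered.count(c) > 1})
        raise ValueError(f"{path}: duplicate channel labels: {dupes}")
    rates = {labels[i]: hdr.sampling_rate(i) for i in eeg_idx}
    if len(set(rates.values())) > 1:
        raise ValueError(
            f"{path}: EEG channels with differing sampling rates: {rates}"
        )
    fs = next(iter(rates.values()))

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    # mne stores EDF µV channels in volts
    by_name = {name: raw.get_data(picks=[name])[0] * 1e6 for name in raw.ch_names}

    def _lookup(lab: str) -> np.ndarray:
        for cand in (lab, lab.strip()):
            if cand in by_name:
                return by_name[cand]
        # mne may have stripped prefixes differently; fall back to suffix match
        for name, sig in by_name.items():
            if name.strip().lower() == lab.strip().lower():
                return sig
        raise EdfFormatError(f"{path}: channel {lab!r} not decoded")

    data = np.vstack([_lookup(lab) for lab in eeg_labels])
    aux_labels = [
        labels[i]
        for i in range(len(labels))
        if i not in eeg_idx and "annotation" not in labels[i].lower()
    ]
    aux_rows = []
    for lab in aux_labels:
        try:
            aux_rows.append(_lookup(lab))
        except EdfFormatError:
            aux_rows.append(np.zeros(data.shape[1]))
    aux_data = np.vstack(aux_rows) if aux_rows else None
    return EegRecording(
        channel_labels=[_canonical(c) for c in eeg_labels],
        fs=fs,
        data=data,
        aux_labels=aux_labels,
        aux_data=aux_data,
    )


def select_segment(
    rec: EegRecording,
    target_minutes: float = 30.0,
    skip_minutes: float = 0.0,
    amplitude_ceiling_uv: float | None = None,
) -> EegRecording:
    """Select the earliest contiguous analysis segment of the recording.

    Starting after ``skip_minutes``, candidate start offsets are scanned in
    10-s steps; the first segment whose per-channel peak amplitude stays
    below ``amplitude_ceiling_uv`` (when given) is returned.  If no
    candidate passes the ceiling the earliest segment is returned with a
    warning — epoch-level rejection downstream still applies.
    """
    target_s = target_minutes * 60.0
    skip_s = skip_minutes * 60.0
    n_target = int(round(target_s * rec.fs))
    avail = rec.duration_s - skip_s
    if avail + 1e-9 < target_s:
        raise ValueError(
            f"insufficient duration: {avail / 60:.1f} min available after "
            f"skip, {target_minutes:.1f} min requested"
        )

    step = int(round(10 * rec.fs))
    first_start = int(round(skip_s * rec.fs))
    last_start = rec.n_samples - n_target
    starts = range(first_start, last_start + 1, step)
    chosen = first_start
    if amplitude_ceiling_uv is not None:
        for s in starts:
            if np.max(np.abs(rec.data[:, s : s + n_target])) <= amplitude_ceiling_uv:
                chosen = s
                break
        else:
            warnings.warn(
                "no segment below the amplitude ceiling; using the earliest "
                "segment and relying on epoch rejection",
                stacklevel=2,
            )
    sl = slice(chosen, chosen + n_target)
    return EegRecording(
        channel_labels=list(rec.channel_labels),
        fs=rec.fs,
        data=rec.data[:, sl].copy(),
        start_offset=rec.start_offset + chosen / rec.fs,
        aux_labels=list(rec.aux_labels),
        aux_data=None if rec.aux_data is None else rec.aux_data[:, sl].copy(),
    )


def resolve_montage(rec: EegRecording) -> MontageMap:
    """Resolve the recording's labels into homologous left–right pairs.

    Accepts both old (T3/T4/T5/T6) and new (T7/T8/P7/P8) temporal names;
    invariant to channel order and label case.  Raises when no complete
    pair exists, since the brain symmetry index is undefined then.
    """
    present = {_canonical(lab).lower() for lab in rec.channel_labels}
    pairs = [
        (l, r)
        for l, r in HOMOLOGOUS_PAIRS
        if l.lower() in present and r.lower() in present
    ]
    midline = [m for m in MIDLINE_LABELS if m.lower() in present]
    paired = {x.lower() for p in pairs for x in p} | {m.lower() for m in midline}
    unpaired = sorted(
        _canonical(lab)
        for lab in rec.channel_labels
        if _canonical(lab).lower() not in paired
    )
    if not pairs:
        raise ValueError(
            "no left–right electrode pair among channels "
            f"{rec.channel_labels}; brain symmetry index undefined"
        )
    return MontageMap(pairs=pairs, midline=midline, unpaired=unpaired)
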