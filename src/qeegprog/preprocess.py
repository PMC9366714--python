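"""Filtering, windowing/epoching and amplitude-based artifact rejection.

The preprocessing chain is a 50 Hz notch (power-line), a 3rd-order
Butterworth high-pass at 1 Hz and an 8th-order Butterworth low-pass at
30 Hz, all applied forward–backward (zero phase).  The filtered segment is
cut into non-overlapping 10-min windows of 60 non-overlapping 10-s
epochs; epochs with gross amplitude excursions or flatlines are masked and
excluded from every downstream statistic.

Ocular-artifact handling: epochs dominated by eye or movement artifact are
caught by the amplitude ceiling, and when EOG channels are present an
optional linear regression of each EEG channel on the EOG channels can be
applied first.  This is a deterministic, conservative stand-in for
adaptive ocular noise reduction; runs are labelled with it in provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .eeg_io import EegRecording

__all__ = [
    "PreprocessConfig",
    "EpochedWindows",
    "filter_chain",
    "epoch_windows",
    "reject_artifacts",
    "regress_out_eog",
    "preprocess_recording",
]


@dataclass
class PreprocessConfig:
    """Numeric settings of the preprocessing chain (frequencies in Hz)."""

    notch_hz: float = 50.0
    notch_q: float = 30.0
    hp_order: int = 3
    hp_cutoff_hz: float = 1.0
    lp_order: int = 8
    lp_cutoff_hz: float = 30.0
    window_s: float = 600.0
    epoch_s: float = 10.0
    reject_uv: float = 500.0

    def __post_init__(self) -> None:
        if not (0 < self.hp_cutoff_hz < self.lp_cutoff_hz):
            raise ValueError("require 0 < hp_cutoff < lp_cutoff")
        if self.window_s <= 0 or self.epoch_s <= 0:
            raise ValueError("window and epoch lengths must be positive")
        ratio = self.window_s / self.epoch_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("window_s must be divisible by epoch_s")

    @property
    def epochs_per_window(self) -> int:
        return int(round(self.window_s / self.epoch_s))


@dataclass
class EpochedWindows:
    """Windowed/epoched signal tensor plus a rejection mask.

    ``data`` has shape (n_windows, epochs_per_window, n_channels,
    samples_per_epoch) in µV.  ``rejected[w, e]`` is True when epoch e of
    window w is excluded from every downstream statistic.
    """

    data: np.ndarray
    rejected: np.ndarray
    fs: float
    channel_labels: list[str]
    config: PreprocessConfig = field(default_factory=PreprocessConfig)

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    def usable_windows(self) -> np.ndarray:
        """Boolean per-window flag: at least one unmasked epoch."""
        return ~self.rejected.all(axis=1)

    def rejection_report(self) -> dict:
        return {
            "n_windows": int(self.n_windows),
            "epochs_per_window": int(self.n_epochs),
            "n_rejected_epochs": int(self.rejected.sum()),
            "rejected_per_window": self.rejected.sum(axis=1).astype(int).tolist(),
            "unusable_windows": int((~self.usable_windows()).sum()),
            "artifact_method": "amplitude/flatline epoch rejection",
        }


def filter_chain(rec: EegRecording, cfg: PreprocessConfig | None = None) -> EegRecording:
    """Apply notch + Butterworth band limits, zero phase, to all channels."""
    cfg = cfg or PreprocessConfig()
    if rec.fs < 2 * cfg.lp_cutoff_hz:
        raise ValueError(
            f"sampling rate {rec.fs} Hz too low for a {cfg.lp_cutoff_hz} Hz "
            "low-pass"
        )
    if not np.all(np.isfinite(rec.data)):
        raise ValueError("recording contains NaN/inf samples")

    x = rec.data
    if cfg.notch_hz and cfg.notch_hz < rec.fs / 2:
        b, a = signal.iirnotch(cfg.notch_hz, cfg.notch_q, fs=rec.fs)
        x = signal.filtfilt(b, a, x, axis=-1)
    sos_hp = signal.butter(
        cfg.hp_order, cfg.hp_cutoff_hz, btype="highpass", fs=rec.fs, output="sos"
    )
    sos_lp = signal.butter(
        cfg.lp_order, cfg.lp_cutoff_hz, btype="lowpass", fs=rec.fs, output="sos"
    )
    x = signal.sosfiltfilt(sos_hp, x, axis=-1)
    x = signal.sosfiltfilt(sos_lp, x, axis=-1)
    return EegRecording(
        channel_labels=list(rec.channel_labels),
        fs=rec.fs,
        data=x,
        start_offset=rec.start_offset,
        aux_labels=list(rec.aux_labels),
        aux_data=rec.aux_data,
    )


def regress_out_eog(rec: EegRecording) -> EegRecording:
    """Subtract the least-squares EOG projection from every EEG channel.

    A no-op when the recording carries no EOG aux channels.
    """
    if rec.aux_data is None:
        return rec
    eog_rows = [i for i, lab in enumerate(rec.aux_labels) if "eog" in lab.lower()]
    if not eog_rows:
        return rec
    eog = rec.aux_data[eog_rows]
    eog = eog - eog.mean(axis=1, keepdims=True)
    x = rec.data - rec.data.mean(axis=1, keepdims=True)
    beta, *_ = np.linalg.lstsq(eog.T, x.T, rcond=None)
    cleaned = x - (eog.T @ beta).T
    return EegRecording(
        channel_labels=list(rec.channel_labels),
        fs=rec.fs,
        data=cleaned,
        start_offset=rec.start_offset,
        aux_labels=list(rec.aux_labels),
        aux_data=rec.aux_data,
    )


def epoch_windows(rec: EegRecording, cfg: PreprocessConfig | None = None) -> EpochedWindows:
    """Cut into non-overlapping windows of non-overlapping epochs.

    A trailing partial window is dropped; a recording shorter than one
    window raises.
    """
    cfg = cfg or PreprocessConfig()
    n_epoch = int(round(cfg.epoch_s * rec.fs))
    epw = cfg.epochs_per_window
    n_window = n_epoch * epw
    n_windows = rec.n_samples // n_window
    if n_windows < 1:
        raise ValueError(
            f"recording of {rec.duration_s / 60:.1f} min shorter than one "
            f"{cfg.window_s / 60:.0f}-min window"
        )
    used = rec.data[:, : n_windows * n_window]
    tensor = (
        used.reshape(rec.n_channels, n_windows, epw, n_epoch)
        .transpose(1, 2, 0, 3)
        .copy()
    )
    rejected = np.zeros((n_windows, epw), dtype=bool)
    return EpochedWindows(
        data=tensor,
        rejected=rejected,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        config=cfg,
    )


def reject_artifacts(ep: EpochedWindows, cfg: PreprocessConfig | None = None) -> EpochedWindows:
    """Mask epochs with amplitude excursions or flatline channels.

    An epoch is rejected when any channel's peak absolute amplitude
    exceeds ``reject_uv`` or any channel is constant over the epoch.
    Raises when no window retains a usable epoch.
    """
    cfg = cfg or ep.config
    peak = np.abs(ep.data).max(axis=(2, 3))
    flat = (ep.data.max(axis=3) - ep.data.min(axis=3) == 0).any(axis=2)
    rejected = ep.rejected | (peak > cfg.reject_uv) | flat
    out = EpochedWindows(
        data=ep.data,
        rejected=rejected,
        fs=ep.fs,
        channel_labels=list(ep.channel_labels),
        config=cfg,
    )
    if not out.usable_windows().any():
        raise ValueError("all epochs of every window rejected; no usable data")
    return out


def preprocess_recording(
    rec: EegRecording, cfg: PreprocessConfig | None = None, eog_regression: bool = False
) -> EpochedWindows:
    """Full chain: (optional EOG regression) → filters → epochs → rejection."""
    cfg = cfg or PreprocessConfig()
    if eog_regression:
        rec = regress_out_eog(rec)
    filtered = filter_chain(rec, cfg)
    ep = epoch_windows(filtered, cfg)
    return reject_artifacts(ep, cfg)


def config_dict(cfg: PreprocessConfig) -> dict:
    return asdict(cfg)
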