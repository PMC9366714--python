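"""Quantitative EEG parameters per 10-min window and per subject.

Nine parameter families are computed from the epoched, filtered signal:

* absolute band power (delta 0.5–4, theta 4–8, alpha 8–13, beta 13–20 Hz),
  by integrating the Welch PSD over the band;
* total power, the sum of the four band powers (0.5–20 Hz);
* relative band power ("power rate"), band power over total power;
* alpha/delta ratio (ADR);
* band-power variability, MAD over median of the per-epoch band powers,
  clipped to [0, 1];
* pairwise-derived brain symmetry index (BSI) over 0.5–20 Hz and over the
  delta band, 0 = symmetric, 1 = maximally asymmetric;
* mean amplitude, the standard deviation of the filtered signal;
* regularity (REG), a [0, 1] continuity measure of the amplitude envelope
  (1 for a constant-amplitude signal, → 0 for isolated bursts).

Windows are summarised per subject by the element-wise median.  Channel
aggregation (plain mean over channels) happens before the subject-level
median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .eeg_io import MontageMap
from .preprocess import EpochedWindows

__all__ = [
    "FrequencyBand",
    "CANONICAL_BANDS",
    "TOTAL_RANGE",
    "SpectralEstimate",
    "QEEG_FEATURES",
    "MODEL_QEEG_FEATURES",
    "welch_psd",
    "band_power",
    "epoch_band_power",
    "total_and_relative_power",
    "alpha_delta_ratio",
    "band_variability",
    "brain_symmetry_index",
    "mean_amplitude",
    "regularity",
    "window_features",
    "subject_features",
]


@dataclass(frozen=True)
class FrequencyBand:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.lo_hz < self.hi_hz:
            raise ValueError("require 0 < lo < hi")


CANONICAL_BANDS = (
    FrequencyBand("delta", 0.5, 4.0),
    FrequencyBand("theta", 4.0, 8.0),
    FrequencyBand("alpha", 8.0, 13.0),
    FrequencyBand("beta", 13.0, 20.0),
)
TOTAL_RANGE = FrequencyBand("all", 0.5, 20.0)

#: every feature column of the per-subject vector, in canonical order
QEEG_FEATURES = [
    "abs_power_delta",
    "abs_power_theta",
    "abs_power_alpha",
    "abs_power_beta",
    "total_power",
    "rel_power_delta",
    "rel_power_theta",
    "rel_power_alpha",
    "rel_power_beta",
    "adr",
    "variability_delta",
    "variability_theta",
    "variability_alpha",
    "variability_beta",
    "variability_all",
    "bsi_all",
    "bsi_delta",
    "mean_amp",
    "reg",
]

#: the 14 scale-free parameters entering the prognostic models
MODEL_QEEG_FEATURES = [
    "rel_power_delta",
    "rel_power_theta",
    "rel_power_alpha",
    "rel_power_beta",
    "adr",
    "variability_delta",
    "variability_theta",
    "variability_alpha",
    "variability_beta",
    "variability_all",
    "bsi_all",
    "bsi_delta",
    "mean_amp",
    "reg",
]


@dataclass
class SpectralEstimate:
    """Welch PSD per window (epoch-averaged) and per epoch.

    ``psd`` is (n_windows, n_channels, n_bins) in µV²/Hz, the mean over
    unmasked epochs; ``psd_epochs`` keeps the per-epoch estimates
    (n_windows, n_epochs, n_channels, n_bins) with masked epochs NaN.
    Density-normalised: the integral over [0, fs/2] estimates variance.
    """

    freqs_hz: np.ndarray
    psd: np.ndarray
    psd_epochs: np.ndarray
    n_epochs_used: np.ndarray
    channel_labels: list[str]

    @property
    def df(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])


def welch_psd(ep: EpochedWindows, seg_s: float = 2.0) -> SpectralEstimate:
    """Welch PSD per epoch (Hamming sub-segments, 50% overlap), averaged
    over the unmasked epochs of each window.

    ``seg_s`` = 2 s gives the 0.5 Hz resolution needed to resolve the
    0.5 Hz delta edge.
    """
    nperseg = int(round(seg_s * ep.fs))
    freqs, pxx = signal.welch(
        ep.data,
        fs=ep.fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    pxx = np.asarray(pxx)  # (win, epoch, chan, bin)
    masked = ep.rejected
    pxx_epochs = pxx.copy()
    pxx_epochs[masked] = np.nan
    n_used = (~masked).sum(axis=1)
    with np.errstate(invalid="ignore"):
        psd = np.nanmean(pxx_epochs, axis=1)
    psd[n_used == 0] = np.nan
    return SpectralEstimate(
        freqs_hz=freqs,
        psd=psd,
        psd_epochs=pxx_epochs,
        n_epochs_used=n_used,
        channel_labels=list(ep.channel_labels),
    )


def _band_slice(sp: SpectralEstimate, band: FrequencyBand) -> np.ndarray:
    if band.hi_hz > sp.freqs_hz[-1] + 1e-9:
        raise ValueError(
            f"band {band.name} [{band.lo_hz}, {band.hi_hz}) outside the "
            f"spectral support (max {sp.freqs_hz[-1]} Hz)"
        )
    sel = (sp.freqs_hz >= band.lo_hz - 1e-9) & (sp.freqs_hz < band.hi_hz - 1e-9)
    if sel.sum() < 2:
        raise ValueError(
            f"band {band.name} narrower than the spectral resolution"
        )
    return sel


def band_power(sp: SpectralEstimate, band: FrequencyBand) -> np.ndarray:
    """Trapezoidal integral of the window PSD over the band's bins.

    Returns (n_windows, n_channels) in µV².  Bands are half-open
    [lo, hi) so adjacent bands never share a bin.
    """
    sel = _band_slice(sp, band)
    return np.trapezoid(sp.psd[..., sel], sp.freqs_hz[sel], axis=-1)


def epoch_band_power(sp: SpectralEstimate, band: FrequencyBand) -> np.ndarray:
    """Per-epoch, channel-averaged band power, (n_windows, n_epochs).

    Masked epochs are NaN.
    """
    sel = _band_slice(sp, band)
    per = np.trapezoid(sp.psd_epochs[..., sel], sp.freqs_hz[sel], axis=-1)
    return per.mean(axis=-1)  # mean over channels


def total_and_relative_power(
    sp: SpectralEstimate,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Total power (sum of the four canonical band powers, channel-averaged,
    per window) and relative powers per band.

    Windows with zero total power come back NaN (feature missing).
    """
    bands = {b.name: band_power(sp, b).mean(axis=-1) for b in CANONICAL_BANDS}
    total = np.sum([bands[b.name] for b in CANONICAL_BANDS], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = {
            name: np.where(total > 0, p / total, np.nan)
            for name, p in bands.items()
        }
    total = np.where(total > 0, total, np.nan)
    return total, rel


def alpha_delta_ratio(abs_powers: dict[str, np.ndarray]) -> np.ndarray:
    """ADR = alpha power / delta power; NaN where delta power is zero."""
    delta = np.asarray(abs_powers["delta"], dtype=float)
    alpha = np.asarray(abs_powers["alpha"], dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(delta > 0, alpha / delta, np.nan)


def mad(x: np.ndarray, axis=None) -> np.ndarray:
    """Raw median absolute deviation (no consistency factor)."""
    med = np.nanmedian(x, axis=axis, keepdims=True)
    return np.nanmedian(np.abs(x - med), axis=axis)


def band_variability(epoch_powers: np.ndarray) -> np.ndarray:
    """MAD / median of per-epoch band powers, per window, clipped to [0, 1].

    ``epoch_powers`` is (n_windows, n_epochs) with masked epochs NaN.
    NaN where fewer than two epochs are usable or the median is zero.
    """
    epoch_powers = np.asarray(epoch_powers, dtype=float)
    n_ok = np.sum(~np.isnan(epoch_powers), axis=1)
    med = np.nanmedian(
        np.where(np.isnan(epoch_powers), np.nan, epoch_powers), axis=1
    )
    m = mad(epoch_powers, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where((med > 0) & (n_ok >= 2), m / med, np.nan)
    return np.clip(v, 0.0, 1.0)


def brain_symmetry_index(
    sp: SpectralEstimate,
    montage: MontageMap,
    lo_hz: float = 0.5,
    hi_hz: float = 20.0,
) -> np.ndarray:
    """Pairwise-derived BSI per window over [lo, hi).

    For each homologous pair p and frequency bin f,
    ``s(p, f) = |R(p, f) − L(p, f)| / (R(p, f) + L(p, f))``; the BSI is
    the plain mean of s over pairs and bins, skipping bins where
    R + L = 0.  0 means symmetric hemispheres, 1 a silent hemisphere.
    """
    idx = montage.pair_indices(sp.channel_labels)
    if not idx:
        raise ValueError("no left–right pairs; BSI undefined")
    sel = (sp.freqs_hz >= lo_hz - 1e-9) & (sp.freqs_hz < hi_hz - 1e-9)
    left = sp.psd[:, [i for i, _ in idx], :][..., sel]
    right = sp.psd[:, [j for _, j in idx], :][..., sel]
    tot = right + left
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(tot > 0, np.abs(right - left) / tot, np.nan)
    with np.errstate(invalid="ignore"):
        return np.nanmean(s, axis=(1, 2))


def mean_amplitude(ep: EpochedWindows) -> np.ndarray:
    """Mean amplitude per window: per-channel SD of the filtered signal
    over the window's unmasked epochs, averaged over channels (µV)."""
    out = np.full(ep.n_windows, np.nan)
    for w in range(ep.n_windows):
        keep = ~ep.rejected[w]
        if not keep.any():
            continue
        x = ep.data[w, keep]  # (n_keep, chan, samp)
        per_chan = x.transpose(1, 0, 2).reshape(x.shape[1], -1).std(axis=1)
        out[w] = per_chan.mean()
    return out


def regularity_epoch(
    x: np.ndarray, fs: float | None = None, smooth_s: float = 0.5
) -> float:
    """REG of one epoch of one channel.

    The squared signal, optionally smoothed into an amplitude envelope by
    an edge-normalised ``smooth_s``-second moving average, is sorted in
    descending order into q(1..N); the statistic is
    ``sqrt( Σ i²·q(i) / ((N²/3)·Σ q(i)) )``.

    With smoothing, a constant-envelope oscillation gives ≈ 1 and a 10%
    duty-cycle burst pattern ≈ 0.1.  Without smoothing (``smooth_s = 0``)
    the statistic has the closed form √3/N for a single spike among N
    zeros, which anchors its normalising constant.
    """
    x2 = np.asarray(x, dtype=float) ** 2
    if smooth_s and fs:
        win = max(int(round(smooth_s * fs)), 1)
        if win > 1:
            kernel = np.ones(win)
            num = np.convolve(x2, kernel, mode="same")
            den = np.convolve(np.ones_like(x2), kernel, mode="same")
            x2 = num / den
    q = np.sort(x2)[::-1]
    total = q.sum()
    if total <= 0:
        return np.nan
    n = q.size
    i = np.arange(1, n + 1, dtype=float)
    return float(np.sqrt((i * i * q).sum() / ((n * n / 3.0) * total)))


def regularity(ep: EpochedWindows, smooth_s: float = 0.5) -> np.ndarray:
    """REG per window: mean over unmasked epochs and channels, clipped to
    [0, 1].  Zero-energy epochs are excluded."""
    out = np.full(ep.n_windows, np.nan)
    for w in range(ep.n_windows):
        keep = np.flatnonzero(~ep.rejected[w])
        if keep.size == 0:
            continue
        vals = [
            regularity_epoch(ep.data[w, e, c], fs=ep.fs, smooth_s=smooth_s)
            for e in keep
            for c in range(ep.data.shape[2])
        ]
        vals = [v for v in vals if not np.isnan(v)]
        if vals:
            out[w] = np.clip(np.mean(vals), 0.0, 1.0)
    return out


def window_features(
    ep: EpochedWindows, montage: MontageMap | None = None
) -> pd.DataFrame:
    """All QEEG parameters per usable 10-min window (one row per window).

    BSI columns are NaN when no montage is supplied.
    """
    sp = welch_psd(ep)
    abs_pow = {b.name: band_power(sp, b).mean(axis=-1) for b in CANONICAL_BANDS}
    total, rel = total_and_relative_power(sp)
    adr = alpha_delta_ratio(abs_pow)
    variab = {
        b.name: band_variability(epoch_band_power(sp, b)) for b in CANONICAL_BANDS
    }
    variab["all"] = band_variability(epoch_band_power(sp, TOTAL_RANGE))
    if montage is not None:
        bsi_all = brain_symmetry_index(sp, montage, 0.5, 20.0)
        bsi_delta = brain_symmetry_index(sp, montage, 0.5, 4.0)
    else:
        bsi_all = bsi_delta = np.full(ep.n_windows, np.nan)
    amp = mean_amplitude(ep)
    reg = regularity(ep)

    df = pd.DataFrame(
        {
            "abs_power_delta": abs_pow["delta"],
            "abs_power_theta": abs_pow["theta"],
            "abs_power_alpha": abs_pow["alpha"],
            "abs_power_beta": abs_pow["beta"],
            "total_power": total,
            "rel_power_delta": rel["delta"],
            "rel_power_theta": rel["theta"],
            "rel_power_alpha": rel["alpha"],
            "rel_power_beta": rel["beta"],
            "adr": adr,
            "variability_delta": variab["delta"],
            "variability_theta": variab["theta"],
            "variability_alpha": variab["alpha"],
            "variability_beta": variab["beta"],
            "variability_all": variab["all"],
            "bsi_all": bsi_all,
            "bsi_delta": bsi_delta,
            "mean_amp": amp,
            "reg": reg,
        }
    )
    df["n_epochs_used"] = sp.n_epochs_used
    return df[ep.usable_windows()].reset_index(drop=True)


def subject_features(window_df: pd.DataFrame) -> pd.Series:
    """Element-wise median over windows → one subject-level vector.

    A feature missing (NaN) in some windows is the median of the
    remaining ones; a subject with no usable window raises.
    """
    if len(window_df) == 0:
        raise ValueError("subject has no usable window; excluded")
    med = window_df[QEEG_FEATURES].median(axis=0, skipna=True)
    med["n_windows_used"] = float(len(window_df))
    med["n_epochs_used"] = float(window_df["n_epochs_used"].sum())
    return med
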