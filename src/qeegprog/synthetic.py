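"""Synthetic EEG recordings and cohorts with designed statistical structure.

No public cohort accompanies this problem, so the generators emulate the
regimes the analysis is sensitive to:

* ``gen_eeg`` — multichannel band-limited Gaussian noise with controllable
  relative band powers, right/left hemispheric amplitude asymmetry,
  epoch-to-epoch power jitter and a continuous or burst-suppression
  amplitude envelope.  A sinusoid carrier mode is kept for analytic tests.
* ``gen_cohort`` — subjects with class-conditional Gaussian QEEG-style
  features at a designed Mahalanobis separation δ (theoretical optimum
  AUC = Φ(δ/√2)), 3-month-mortality outcomes at a set prevalence, and
  binary clinical covariates at class-specific prevalences patterned on a
  neuro-ICU case mix (≈34% mortality; higher APACHE II, lower GCS and
  more diabetes among non-survivors).

All randomness flows from a single integer seed per call; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

from .edf import write_edf
from .eeg_io import EegRecording, HOMOLOGOUS_PAIRS
from .features import CANONICAL_BANDS, MODEL_QEEG_FEATURES

__all__ = ["EegSimSpec", "CohortSimSpec", "gen_eeg", "gen_cohort", "write_edf_fixture"]


@dataclass
class EegSimSpec:
    """Recipe for one synthetic EEG recording."""

    fs: float = 250.0
    duration_s: float = 1800.0
    n_channel_pairs: int = 4
    #: target relative power per canonical band (delta, theta, alpha, beta)
    band_weights: tuple[float, float, float, float] = (0.45, 0.25, 0.2, 0.1)
    #: right/left amplitude ratio (1 = symmetric hemispheres)
    asymmetry: float = 1.0
    #: "continuous" or "burst_suppression"
    envelope: str = "continuous"
    burst_duty: float = 0.1
    burst_period_s: float = 10.0
    suppression_floor: float = 0.02
    #: sd of the log-normal per-epoch amplitude factor (0 = stationary)
    epoch_power_jitter: float = 0.0
    epoch_s: float = 10.0
    #: broadband white-noise floor as an amplitude fraction
    noise_floor: float = 0.01
    #: overall amplitude scale, µV RMS of the composite signal
    amplitude_uv: float = 30.0
    #: "noise" (band-limited Gaussian noise) or "sine" (band-centre tones)
    carrier: str = "noise"
    #: reuse the left-channel noise for the right channel of each pair
    mirror_hemispheres: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.band_weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("band weights must be non-negative, not all zero")
        if abs(w.sum() - 1) > 1e-9:
            raise ValueError("band weights must sum to 1")
        if self.asymmetry <= 0:
            raise ValueError("asymmetry must be positive")
        if not 0 < self.burst_duty <= 1:
            raise ValueError("burst duty must be in (0, 1]")
        if self.envelope not in ("continuous", "burst_suppression"):
            raise ValueError(f"unknown envelope {self.envelope!r}")
        if self.carrier not in ("noise", "sine"):
            raise ValueError(f"unknown carrier {self.carrier!r}")


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [lo, hi] Hz."""
    x = rng.standard_normal(n)
    sos = signal.butter(4, [lo, min(hi, 0.999 * fs / 2)], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _one_channel(rng: np.random.Generator, spec: EegSimSpec, n: int) -> np.ndarray:
    parts = []
    for w, band in zip(spec.band_weights, CANONICAL_BANDS):
        if w <= 0:
            continue
        if spec.carrier == "sine":
            f = 0.5 * (band.lo_hz + band.hi_hz)
            phase = rng.uniform(0, 2 * np.pi)
            comp = np.sqrt(2.0) * np.sin(
                2 * np.pi * f * np.arange(n) / spec.fs + phase
            )
        else:
            comp = _band_noise(rng, n, spec.fs, band.lo_hz, band.hi_hz)
        parts.append(np.sqrt(w) * comp)
    x = np.sum(parts, axis=0)
    if spec.noise_floor > 0:
        x = x + spec.noise_floor * rng.standard_normal(n)
    return x


def _envelope(spec: EegSimSpec, n: int) -> np.ndarray:
    if spec.envelope == "continuous":
        return np.ones(n)
    t = np.arange(n) / spec.fs
    phase = np.mod(t, spec.burst_period_s) / spec.burst_period_s
    env = np.where(phase < spec.burst_duty, 1.0, spec.suppression_floor)
    return env


def gen_eeg(spec: EegSimSpec) -> EegRecording:
    """Generate a synthetic multichannel EEG recording (µV).

    Channels come in homologous 10–20 pairs; each channel is a weighted
    sum of band-limited components, scaled per epoch by the jitter factor,
    with right-hemisphere channels multiplied by the asymmetry ratio and
    the whole signal by the amplitude envelope.
    """
    if spec.n_channel_pairs < 1 or spec.n_channel_pairs > len(HOMOLOGOUS_PAIRS):
        raise ValueError(
            f"n_channel_pairs must be in [1, {len(HOMOLOGOUS_PAIRS)}]"
        )
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    pairs = HOMOLOGOUS_PAIRS[: spec.n_channel_pairs]
    labels: list[str] = []
    rows: list[np.ndarray] = []
    env = _envelope(spec, n)
    n_epoch = int(round(spec.epoch_s * spec.fs))
    n_epochs = max(n // n_epoch, 1)
    for left, right in pairs:
        base_l = _one_channel(rng, spec, n)
        base_r = base_l if spec.mirror_hemispheres else _one_channel(rng, spec, n)
        for lab, base, gain in ((left, base_l, 1.0), (right, base_r, spec.asymmetry)):
            x = base.copy()
            if spec.epoch_power_jitter > 0:
                factors = np.exp(
                    spec.epoch_power_jitter * rng.standard_normal(n_epochs)
                )
                mult = np.repeat(factors, n_epoch)[:n]
                if len(mult) < n:
                    mult = np.pad(mult, (0, n - len(mult)), mode="edge")
                x = x * mult
            labels.append(lab)
            rows.append(gain * spec.amplitude_uv * x * env)
    return EegRecording(channel_labels=labels, fs=spec.fs, data=np.vstack(rows))


@dataclass
class CohortSimSpec:
    """Recipe for a synthetic subjects × features cohort.

    Defaults mirror the class structure of a neuro-ICU case mix: 33.75%
    3-month mortality, APACHE II higher and GCS lower among
    non-survivors, diabetes far more prevalent among non-survivors, and
    QEEG features separated by Mahalanobis distance δ = 1.19 along the
    four relative band powers (optimal AUC Φ(δ/√2) ≈ 0.80).
    """

    n_subjects: int = 110
    mortality_prevalence: float = 0.3375
    separation: float = 1.19
    informative_features: tuple[str, ...] = (
        "rel_power_delta",
        "rel_power_beta",
        "rel_power_theta",
        "rel_power_alpha",
    )
    feature_names: tuple[str, ...] = tuple(MODEL_QEEG_FEATURES)
    #: (survivor prevalence, non-survivor prevalence) per binary covariate
    covariate_prevalences: dict = field(
        default_factory=lambda: {
            "sex": (0.698, 0.333),
            "hypertension": (0.472, 0.630),
            "chd": (0.170, 0.296),
            "diabetes": (0.038, 0.333),
        }
    )
    apache2_params: tuple[tuple[float, float], tuple[float, float]] = (
        (16.0, 4.0),
        (21.0, 5.5),
    )
    gcs_params: tuple[tuple[float, float], tuple[float, float]] = (
        (5.3, 3.0),
        (3.9, 2.0),
    )
    age_params: tuple[float, float] = (55.0, 18.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.mortality_prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        missing = set(self.informative_features) - set(self.feature_names)
        if missing:
            raise ValueError(f"informative features not in feature set: {missing}")

    @property
    def optimal_auc(self) -> float:
        return float(stats.norm.cdf(self.separation / np.sqrt(2)))


def gen_cohort(spec: CohortSimSpec) -> tuple[pd.DataFrame, dict]:
    """Generate a cohort table and its design metadata.

    Features are class-conditionally Gaussian with identity covariance;
    non-survivors are shifted by δ·u along the unit vector u spread
    equally over the informative features, so the Mahalanobis separation
    of the full vector is exactly δ.  Returns ``(df, meta)`` where meta
    records the theoretical optimum AUC.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    if n < 4:
        raise ValueError("need at least 4 subjects")
    y = (rng.random(n) < spec.mortality_prevalence).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError(
            f"n={n} too small to realise both classes at prevalence "
            f"{spec.mortality_prevalence}; increase n"
        )

    p = len(spec.feature_names)
    shift = np.zeros(p)
    idx = [spec.feature_names.index(f) for f in spec.informative_features]
    shift[idx] = spec.separation / np.sqrt(len(idx))
    X = rng.standard_normal((n, p)) + np.outer(y, shift)

    df = pd.DataFrame(X, columns=list(spec.feature_names))
    df.insert(0, "id", [f"S{i:04d}" for i in range(n)])
    df["age"] = np.clip(
        np.round(rng.normal(*spec.age_params, size=n)), 18, 95
    ).astype(int)
    for name, (p0, p1) in spec.covariate_prevalences.items():
        prob = np.where(y == 1, p1, p0)
        df[name] = (rng.random(n) < prob).astype(int)
    ap = np.where(
        y == 1,
        rng.normal(*spec.apache2_params[1], size=n),
        rng.normal(*spec.apache2_params[0], size=n),
    )
    df["apache2"] = np.clip(np.round(ap), 0, 71).astype(int)
    gc = np.where(
        y == 1,
        rng.normal(*spec.gcs_params[1], size=n),
        rng.normal(*spec.gcs_params[0], size=n),
    )
    df["gcs"] = np.clip(np.round(gc), 3, 15).astype(int)
    df["outcome"] = y
    meta = {
        "optimal_auc": spec.optimal_auc,
        "separation": spec.separation,
        "n_subjects": n,
        "n_died": int(y.sum()),
        "seed": spec.seed,
    }
    return df, meta


def write_edf_fixture(
    rec: EegRecording, path: str | Path, physical_range_uv=None
) -> Path:
    """Write a recording as a standard EDF round-trippable by
    :func:`qeegprog.eeg_io.read_edf` (1-s records, fs samples per record
    per channel)."""
    return write_edf(
        path,
        rec.data,
        list(rec.channel_labels),
        rec.fs,
        physical_range_uv=physical_range_uv,
    )


def make_fixture_spec(**overrides) -> EegSimSpec:
    """Convenience: a small, fast EegSimSpec for fixtures and examples."""
    base = EegSimSpec(fs=250.0, duration_s=600.0, n_channel_pairs=2)
    return replace(base, **overrides)
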