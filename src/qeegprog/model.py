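"""Fisher linear discriminant prognosis of 3-month mortality.

The discriminant direction is the classical w = S_W⁻¹ (μ₁ − μ₀) on
z-scored features, with S_W the pooled within-class covariance optionally
shrunk toward its diagonal (Ledoit–Wolf intensity).  The intercept places
the score on the posterior log-odds scale under the equal-covariance
Gaussian model with empirical class priors, so ``expit(score)`` is a
predicted mortality probability.  Stratified k-fold cross-validation
re-estimates standardisation and shrinkage inside each training fold and
pools the out-of-fold scores into a single ROC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.covariance import ledoit_wolf_shrinkage
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "Cohort",
    "FeatureSet",
    "LdaModel",
    "CvResult",
    "fit_lda",
    "predict",
    "feature_importance",
    "cross_validate",
]


@dataclass
class Cohort:
    """Subjects × (features + covariates + binary outcome) table.

    ``df`` must contain ``id_col`` (unique) and ``outcome_col`` (0/1,
    1 = died within 3 months); an optional ``split`` column tags
    training/validation membership.
    """

    df: pd.DataFrame
    outcome_col: str = "outcome"
    id_col: str = "id"

    def __post_init__(self) -> None:
        if self.outcome_col not in self.df.columns:
            raise ValueError(f"missing outcome column {self.outcome_col!r}")
        if self.id_col in self.df.columns and self.df[self.id_col].duplicated().any():
            raise ValueError("subject ids are not unique")
        bad = set(self.df[self.outcome_col].dropna().unique()) - {0, 1}
        if bad:
            raise ValueError(f"outcome must be 0/1, found {sorted(bad)}")

    @property
    def outcome(self) -> np.ndarray:
        return self.df[self.outcome_col].to_numpy(dtype=int)

    def subset(self, mask) -> "Cohort":
        return Cohort(
            self.df[mask].reset_index(drop=True), self.outcome_col, self.id_col
        )


@dataclass(frozen=True)
class FeatureSet:
    name: str
    features: tuple[str, ...]

    def validate(self, cohort: Cohort) -> None:
        missing = [f for f in self.features if f not in cohort.df.columns]
        if missing:
            raise ValueError(
                f"feature set {self.name!r}: columns missing from cohort: "
                f"{missing}"
            )


@dataclass
class LdaModel:
    feature_names: list[str]
    standardize_mean: np.ndarray
    standardize_scale: np.ndarray
    impute_values: np.ndarray
    w: np.ndarray
    b: float
    class_means: np.ndarray  # (2, p) in z-space
    pooled_cov: np.ndarray
    shrinkage_intensity: float
    priors: np.ndarray

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "feature_names": self.feature_names,
            "standardize_mean": self.standardize_mean.tolist(),
            "standardize_scale": self.standardize_scale.tolist(),
            "impute_values": self.impute_values.tolist(),
            "w": self.w.tolist(),
            "b": self.b,
            "class_means": self.class_means.tolist(),
            "shrinkage_intensity": self.shrinkage_intensity,
            "priors": self.priors.tolist(),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "LdaModel":
        d = json.loads(Path(path).read_text())
        p = len(d["feature_names"])
        return cls(
            feature_names=d["feature_names"],
            standardize_mean=np.asarray(d["standardize_mean"]),
            standardize_scale=np.asarray(d["standardize_scale"]),
            impute_values=np.asarray(d["impute_values"]),
            w=np.asarray(d["w"]),
            b=float(d["b"]),
            class_means=np.asarray(d["class_means"]).reshape(2, p),
            pooled_cov=np.full((p, p), np.nan),
            shrinkage_intensity=float(d["shrinkage_intensity"]),
            priors=np.asarray(d["priors"]),
        )


def _design_matrix(cohort: Cohort, fs: FeatureSet) -> np.ndarray:
    fs.validate(cohort)
    return cohort.df[list(fs.features)].to_numpy(dtype=float)


def fit_lda(
    cohort: Cohort, fs: FeatureSet, shrinkage: float | str | None = "auto"
) -> LdaModel:
    """Fit the Fisher discriminant on a cohort.

    ``shrinkage``: None/0 disables (singular S_W then raises, advising
    shrinkage); a float in [0, 1] is used as-is; "auto" estimates the
    Ledoit–Wolf intensity on the class-centred standardised data.
    Missing feature values are imputed with the fitting-data median.
    """
    X = _design_matrix(cohort, fs)
    y = cohort.outcome
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both outcome classes required to fit")

    impute = np.nanmedian(X, axis=0)
    if np.isnan(impute).any():
        bad = [fs.features[j] for j in np.flatnonzero(np.isnan(impute))]
        raise ValueError(f"features entirely missing: {bad}")
    X = np.where(np.isnan(X), impute, X)

    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (X - mean) / scale

    z0, z1 = Z[y == 0], Z[y == 1]
    mu0, mu1 = z0.mean(axis=0), z1.mean(axis=0)
    n0, n1 = len(z0), len(z1)
    centred = np.vstack([z0 - mu0, z1 - mu1])
    s_w = centred.T @ centred / (n0 + n1 - 2)

    if shrinkage in (None, 0, 0.0):
        gamma = 0.0
    elif shrinkage == "auto":
        gamma = float(ledoit_wolf_shrinkage(centred, assume_centered=True))
    else:
        gamma = float(shrinkage)
        if not 0 <= gamma <= 1:
            raise ValueError("shrinkage intensity must be in [0, 1]")
    p = Z.shape[1]
    s = (1 - gamma) * s_w + gamma * np.diag(np.diag(s_w))
    try:
        cond = np.linalg.cond(s)
        if not np.isfinite(cond) or cond > 1e10:
            raise np.linalg.LinAlgError
        w = np.linalg.solve(s, mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"pooled within-class covariance is singular (p={p}, "
            f"n={n0 + n1}); enable shrinkage (shrinkage='auto')"
        ) from exc

    priors = np.array([n0, n1]) / (n0 + n1)
    b = float(-0.5 * w @ (mu0 + mu1) + np.log(priors[1] / priors[0]))
    return LdaModel(
        feature_names=list(fs.features),
        standardize_mean=mean,
        standardize_scale=scale,
        impute_values=impute,
        w=w,
        b=b,
        class_means=np.vstack([mu0, mu1]),
        pooled_cov=s,
        shrinkage_intensity=gamma,
        priors=priors,
    )


def predict(model: LdaModel, cohort: Cohort | pd.DataFrame) -> pd.DataFrame:
    """Posterior log-odds score and mortality probability per subject."""
    df = cohort.df if isinstance(cohort, Cohort) else cohort
    missing = [f for f in model.feature_names if f not in df.columns]
    if missing:
        raise ValueError(f"cohort lacks model features: {missing}")
    X = df[model.feature_names].to_numpy(dtype=float)
    X = np.where(np.isnan(X), model.impute_values, X)
    Z = (X - model.standardize_mean) / model.standardize_scale
    score = Z @ model.w + model.b
    return pd.DataFrame({"score": score, "probability": expit(score)})


def feature_importance(model: LdaModel) -> pd.DataFrame:
    """|w_j| on the standardised scale, raw and rescaled to max = 100.

    The ranking, not the absolute scale, is the deliverable.
    """
    imp = np.abs(model.w)
    top = imp.max() if imp.max() > 0 else 1.0
    out = pd.DataFrame(
        {
            "feature": model.feature_names,
            "importance": imp,
            "importance_scaled": 100.0 * imp / top,
        }
    ).sort_values("importance", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


@dataclass
class CvResult:
    feature_set: str
    k: int
    seed: int
    fold_assignment: np.ndarray
    oof_scores: np.ndarray
    labels: np.ndarray
    pooled_auc: float
    fold_aucs: list[float]
    models: list[LdaModel] = field(default_factory=list, repr=False)


def cross_validate(
    cohort: Cohort,
    fs: FeatureSet,
    k: int = 5,
    seed: int = 0,
    shrinkage: float | str | None = "auto",
) -> CvResult:
    """Stratified k-fold CV; standardisation, imputation and shrinkage are
    re-estimated inside each training fold; out-of-fold scores are pooled
    into one ROC and per-fold AUCs are also reported."""
    from .evaluation import roc_and_auc

    y = cohort.outcome
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2 or (k < len(y) and counts.min() < k):
        raise ValueError(
            f"class counts {counts.tolist()} too small for {k}-fold "
            "stratified CV"
        )
    if k >= len(y):  # leave-one-out: stratification degenerates
        folds = [
            (np.delete(np.arange(len(y)), i), np.array([i]))
            for i in range(len(y))
        ]
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(splitter.split(np.zeros(len(y)), y))

    oof = np.full(len(y), np.nan)
    assignment = np.full(len(y), -1, dtype=int)
    fold_aucs: list[float] = []
    models: list[LdaModel] = []
    for f, (tr, te) in enumerate(folds):
        sub = cohort.subset(np.isin(np.arange(len(y)), tr))
        model = fit_lda(sub, fs, shrinkage=shrinkage)
        models.append(model)
        scores = predict(model, cohort.df.iloc[te]).score.to_numpy()
        oof[te] = scores
        assignment[te] = f
        if len(np.unique(y[te])) == 2:
            fold_aucs.append(roc_and_auc(scores, y[te]).auc)
    pooled = roc_and_auc(oof, y).auc
    return CvResult(
        feature_set=fs.name,
        k=len(folds),
        seed=seed,
        fold_assignment=assignment,
        oof_scores=oof,
        labels=y,
        pooled_auc=pooled,
        fold_aucs=fold_aucs,
        models=models,
    )
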