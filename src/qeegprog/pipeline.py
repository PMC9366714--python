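"""End-to-end runs: batch feature extraction from EDFs, model fitting and
Table-style evaluation reports, all reproducible from a YAML config and a
seed.

Every artifact embeds the config hash and seed; identical config implies
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, features, model as model_mod
from .eeg_io import read_edf, resolve_montage, select_segment
from .model import Cohort, FeatureSet, cross_validate, fit_lda, predict
from .preprocess import PreprocessConfig, preprocess_recording

logger = logging.getLogger("qeegprog")

__all__ = ["RunConfig", "run_extract", "run_fit_evaluate", "FEATURE_SETS"]

#: the two named feature sets: the four "power rates", and the full model
#: (all 14 scale-free QEEG parameters + APACHE II + sex + histories; GCS
#: and age excluded because APACHE II already incorporates them)
FEATURE_SETS = {
    "qeeg4": FeatureSet(
        "qeeg4",
        (
            "rel_power_delta",
            "rel_power_beta",
            "rel_power_theta",
            "rel_power_alpha",
        ),
    ),
    "full": FeatureSet(
        "full",
        tuple(features.MODEL_QEEG_FEATURES)
        + ("apache2", "sex", "hypertension", "chd", "diabetes"),
    ),
}

#: raw severity scores evaluated directly as single-feature classifiers
SCORE_BASELINES = {"apache2": +1, "gcs": -1}  # sign orients toward mortality


@dataclass
class RunConfig:
    edf_dir: str = "."
    clinical_csv: str | None = None
    out_dir: str = "out"
    segment_minutes: float = 30.0
    skip_minutes: float = 0.0
    amplitude_ceiling_uv: float | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    feature_sets: tuple[str, ...] = ("qeeg4", "full")
    folds: int = 5
    seed: int = 0
    shrinkage: str | float | None = "auto"
    ci_level: float = 0.95
    bootstrap_reps: int = 1000
    eog_regression: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        pp = PreprocessConfig(**raw.pop("preprocess", {}))
        if "feature_sets" in raw:
            raw["feature_sets"] = tuple(raw["feature_sets"])
        return cls(preprocess=pp, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature_sets"] = list(self.feature_sets)
        return d

    @property
    def config_hash(self) -> str:
        """Hash of the analysis parameters (I/O paths excluded, so the
        same analysis hashes identically wherever it runs)."""
        d = self.to_dict()
        for key in ("edf_dir", "clinical_csv", "out_dir"):
            d.pop(key, None)
        canonical = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _extract_one(path: Path, cfg: RunConfig) -> pd.Series:
    rec = read_edf(path)
    seg = select_segment(
        rec,
        target_minutes=cfg.segment_minutes,
        skip_minutes=cfg.skip_minutes,
        amplitude_ceiling_uv=cfg.amplitude_ceiling_uv,
    )
    ep = preprocess_recording(seg, cfg.preprocess, eog_regression=cfg.eog_regression)
    try:
        montage = resolve_montage(seg)
    except ValueError:
        montage = None
    win = features.window_features(ep, montage)
    subj = features.subject_features(win)
    subj["n_epochs_rejected"] = float(ep.rejected.sum())
    subj["segment_offset_s"] = seg.start_offset
    return subj


def run_extract(cfg: RunConfig) -> tuple[pd.DataFrame, list[str]]:
    """Extract one QEEG feature row per EDF file in ``cfg.edf_dir``.

    Per-file failures are logged and collected; the run continues.
    Writes ``features.csv`` into ``cfg.out_dir`` with provenance columns
    and returns ``(df, failures)``.
    """
    edf_dir = Path(cfg.edf_dir)
    paths = sorted(edf_dir.glob("*.edf"))
    if not paths:
        raise FileNotFoundError(f"no .edf files under {edf_dir}")
    rows, failures = [], []
    for path in paths:
        try:
            subj = _extract_one(path, cfg)
        except Exception as exc:  # noqa: BLE001 - per-file isolation
            logger.error("extraction failed for %s: %s", path.name, exc)
            failures.append(f"{path.name}: {exc}")
            continue
        subj["id"] = path.stem
        rows.append(subj)
    df = pd.DataFrame(rows)
    if len(df):
        cols = ["id"] + [c for c in df.columns if c != "id"]
        df = df[cols]
    df["config_hash"] = cfg.config_hash
    df["seed"] = cfg.seed
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "features.csv", index=False, float_format="%.12g")
    report = {
        "n_files": len(paths),
        "n_extracted": len(rows),
        "n_failed": len(failures),
        "failures": failures,
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "artifact_method": "amplitude/flatline epoch rejection"
        + (" + EOG regression" if cfg.eog_regression else ""),
    }
    (out / "extract_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return df, failures


def _evaluate_scores(
    name: str, scores: np.ndarray, labels: np.ndarray, cfg: RunConfig
) -> dict:
    roc = evaluation.roc_and_auc(scores, labels)
    op = evaluation.best_operating_point(scores, labels)
    lo, hi = evaluation.bootstrap_ci(
        lambda s, l: evaluation.roc_and_auc(s, l).auc,
        scores,
        labels,
        level=cfg.ci_level,
        reps=cfg.bootstrap_reps,
        seed=cfg.seed,
    )
    return {
        "model": name,
        "auc": roc.auc,
        "auc_ci_lo": lo,
        "auc_ci_hi": hi,
        "threshold": op.threshold,
        "sensitivity": op.sensitivity,
        "specificity": op.specificity,
        "ppv": op.ppv,
        "npv": op.npv,
        "youden_j": op.youden_j,
    }


def run_fit_evaluate(
    cfg: RunConfig,
    cohort_df: pd.DataFrame | None = None,
) -> dict:
    """Fit the configured feature sets plus GCS/APACHE-II single-score
    baselines, evaluate (pooled CV ROC; a held-out validation split when a
    ``split`` column tags it), run pairwise DeLong comparisons, and write a
    diagnostic-table report (AUC with CI, threshold, sens/spec/PPV/NPV per
    model).

    ``cohort_df`` may be given directly; otherwise ``features.csv`` from
    ``out_dir`` is joined with the clinical CSV on ``id``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort_df is None:
        feats = pd.read_csv(out / "features.csv")
        if cfg.clinical_csv is None:
            raise ValueError("clinical_csv required to join outcomes")
        clin = pd.read_csv(cfg.clinical_csv)
        missing = set(feats["id"]) ^ set(clin["id"])
        if missing:
            logger.warning("ids without a join partner: %s", sorted(missing))
        cohort_df = feats.merge(clin, on="id", how="inner")
        if not len(cohort_df):
            raise ValueError("feature/clinical join produced no subjects")
    cohort_df = cohort_df.dropna(subset=["outcome"]).reset_index(drop=True)

    has_split = "split" in cohort_df.columns
    train_df = (
        cohort_df[cohort_df["split"] == "training"].reset_index(drop=True)
        if has_split
        else cohort_df
    )
    valid_df = (
        cohort_df[cohort_df["split"] == "validation"].reset_index(drop=True)
        if has_split
        else None
    )
    train = Cohort(train_df)

    report_rows = []
    cv_scores: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for fs_name in cfg.feature_sets:
        fset = FEATURE_SETS[fs_name]
        cv = cross_validate(
            train, fset, k=cfg.folds, seed=cfg.seed, shrinkage=cfg.shrinkage
        )
        row = _evaluate_scores(fs_name, cv.oof_scores, cv.labels, cfg)
        row["evaluation"] = "pooled_cv"
        row["fold_aucs"] = [round(a, 6) for a in cv.fold_aucs]
        report_rows.append(row)
        cv_scores[fs_name] = (cv.oof_scores, cv.labels)

        final = fit_lda(train, fset, shrinkage=cfg.shrinkage)
        final.to_json(out / f"model_{fs_name}.json")
        imp = model_mod.feature_importance(final)
        imp.to_csv(out / f"importance_{fs_name}.csv", index=False,
                   float_format="%.12g")
        if valid_df is not None and len(valid_df):
            vscores = predict(final, valid_df).score.to_numpy()
            vrow = _evaluate_scores(
                fs_name, vscores, valid_df["outcome"].to_numpy(int), cfg
            )
            vrow["evaluation"] = "validation"
            report_rows.append(vrow)

    for score_name, sign in SCORE_BASELINES.items():
        if score_name not in train_df.columns:
            continue
        s = sign * train_df[score_name].to_numpy(float)
        row = _evaluate_scores(score_name, s, train.outcome, cfg)
        row["evaluation"] = "pooled_cv"  # raw score: no fitting involved
        report_rows.append(row)
        cv_scores[score_name] = (s, train.outcome)
        if valid_df is not None and len(valid_df):
            sv = sign * valid_df[score_name].to_numpy(float)
            vrow = _evaluate_scores(
                score_name, sv, valid_df["outcome"].to_numpy(int), cfg
            )
            vrow["evaluation"] = "validation"
            report_rows.append(vrow)

    names = list(cv_scores)
    delong = pd.DataFrame(index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        delong.loc[a, a] = 1.0
        for b in names[i + 1 :]:
            sa, la = cv_scores[a]
            sb, lb = cv_scores[b]
            res = evaluation.delong_test(sa, sb, la)
            delong.loc[a, b] = res.p_value
            delong.loc[b, a] = res.p_value

    report_df = pd.DataFrame(report_rows)
    report_df.to_csv(out / "report.csv", index=False, float_format="%.12g")
    delong.to_csv(out / "delong_pvalues.csv", float_format="%.12g")
    payload = {
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "n_train": int(len(train_df)),
        "n_validation": int(len(valid_df)) if valid_df is not None else 0,
        "models": report_rows,
        "delong_pvalues": {
            a: {b: (None if pd.isna(delong.loc[a, b]) else float(delong.loc[a, b]))
                for b in names}
            for a in names
        },
    }
    (out / "report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=float) + "\n"
    )
    return payload
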