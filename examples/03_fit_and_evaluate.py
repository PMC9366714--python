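"""Fit the Fisher LDA mortality models on a synthetic neuro-ICU cohort
and reproduce the full evaluation report: cross-validated and
validation-split AUCs with bootstrap CIs, Youden operating points, and
pairwise DeLong comparisons against the APACHE II and GCS baselines.

The cohort is drawn at a designed Mahalanobis separation of 1.19 along
the four power rates, so the best achievable AUC from QEEG features
alone is Phi(1.19/sqrt(2)) ~ 0.80.
"""

import tempfile

from qeegprog import CohortSimSpec, RunConfig, gen_cohort, run_fit_evaluate

df, meta = gen_cohort(CohortSimSpec(n_subjects=110, seed=7))
df["split"] = ["training"] * 80 + ["validation"] * 30
print(f"cohort: {meta['n_subjects']} subjects, {meta['n_died']} died, "
      f"designed optimal AUC {meta['optimal_auc']:.3f}")

cfg = RunConfig(out_dir=tempfile.mkdtemp(), seed=7, bootstrap_reps=500)
payload = run_fit_evaluate(cfg, cohort_df=df)

print(f"\n{'model':>10s} {'eval':>10s} {'AUC':>6s} {'95% CI':>15s} "
      f"{'sens':>5s} {'spec':>5s}")
for row in payload["models"]:
    print(f"{row['model']:>10s} {row['evaluation']:>10s} {row['auc']:6.3f} "
          f"[{row['auc_ci_lo']:.3f}, {row['auc_ci_hi']:.3f}] "
          f"{row['sensitivity']:5.2f} {row['specificity']:5.2f}")

print("\npairwise DeLong p-values (pooled CV / raw scores):")
for a, row in payload["delong_pvalues"].items():
    cells = " ".join(f"{b}:{p:.3f}" for b, p in row.items() if p is not None)
    print(f"  {a:>8s}  {cells}")
print("\nat n=80 training subjects, CIs are wide: model differences of this"
      "\nsize rarely reach DeLong significance, matching small-cohort reality.")
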