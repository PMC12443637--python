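"""Classify glioma grade from single spectra with leak-proof validation.

Builds the 23-patient synthetic cohort, runs leave-one-batch-and-patient-out
logistic classification over 5 seeds, cross-infers replicas from the
section-trained model, and prints the exact additive feature attribution.
"""

import numpy as np

from replicamap.grading import (
    audit_splits,
    build_cohort,
    cross_infer,
    evaluate,
    linear_attribution,
    make_splits,
    train_grade_model,
)
from replicamap.pipeline import standard_preprocess
from replicamap.preprocess import BinAxis
from replicamap.simulate import CohortSpec, generate_cohort

spec = CohortSpec(seed=1)
sections, replicas, _meta = generate_cohort(spec)
axis = BinAxis(600, 900, 0.5)
sec_items, rep_items = [], []
for (sds, _), (rds, _) in zip(sections, replicas):
    sres = standard_preprocess(sds, axis=axis)
    rres = standard_preprocess(rds, axis=axis)
    sec_items.append((sres.corrected, sres.mask))
    rep_items.append((rres.corrected, rres.mask))

cohort = build_cohort(sec_items)
rep_cohort = build_cohort(rep_items)
splits = make_splits(cohort)
audit = audit_splits(cohort, splits)  # raises if any split leaks
print(f"cohort: {cohort.X.shape[0]} spectra × {cohort.X.shape[1]} features, "
      f"{len(splits)} leak-audited splits")

report = evaluate(cohort, splits, seeds=list(range(5)))
print(f"pixel-level ROC AUC: {report.mean_auc:.3f} ± {report.sd_auc:.3f} "
      f"(5 seeds)")
cross, _sd, _ = cross_infer(cohort, rep_cohort, seeds=[0])
print(f"cross-inference (sections → replicas) AUC: {cross:.3f}")

model = train_grade_model(cohort.X, cohort.y, seed=0)
att = linear_attribution(model, cohort.X, cohort.feature_mz, cohort.X.mean(axis=0))
print("\ntop features by mean |contribution| (sign +1 pushes toward high grade):")
print(att.top_features(6)[["mz", "mean_abs_contribution", "sign"]]
      .to_string(index=False))
# The four planted grade markers (885.55/788.55 high, 790.55/834.53 low)
# dominate the attribution ranking with the planted signs.
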