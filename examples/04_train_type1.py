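"""Train under the randomized (Type I) 70/20/10 regime and report test metrics.

Type I mixes all subjects' samples before splitting, so samples from the
same minute appear on both sides — it measures how separable the feature
space is, not cross-subject generalization (that is Type II's job).
"""

from wearstate import (
    OptimizerConfig,
    assemble_feature_matrix,
    build_model,
    generate_cohort,
    split_type1,
    train_model,
)
from wearstate.synthetic import CohortParams, minute_aligned_durations

params = CohortParams(n_subjects=3, class_durations_s=minute_aligned_durations(600),
                      seed=7)
ds = assemble_feature_matrix(generate_cohort(params))
plan = split_type1(ds.n_samples, seed=1)
print(f"samples: train {len(plan.train)}, val {len(plan.val)}, test {len(plan.test)}")

model = train_model(build_model(), ds, plan,
                    OptimizerConfig(epochs=5, batch_size=256), seed=1)
print("\ntraining history (loss is categorical cross-entropy):")
print(model.history.round(4).to_string(index=False))

report = model.evaluate(ds, plan.test)
print(f"\ntest accuracy {report.accuracy:.4f}, macro recall {report.macro_recall:.4f}")
print("confusion matrix (rows = true class, columns = predicted):")
print(report.confusion)
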