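"""Patient-level 5-fold cross-validation of the full method at desk scale.

Trains the dual-branch model (random prompts + AFTO adapters on both
branches) on a 60-patient synthetic cohort and reports fold-mean clinical
metrics.  Takes a few minutes on one CPU.
"""

from dataclasses import replace

from ceusalnm import AftoConfig, cross_validate, decision_curve, generate_dataset
from ceusalnm.presets import desk_model_config, desk_synthetic_config, desk_train_config

samples = generate_dataset(desk_synthetic_config(n_patients=60, seed=0))
model_config = replace(desk_model_config(),
                       afto=AftoConfig(where="both", freeze_backbone=False))
train_config = desk_train_config(seed=0)

result = cross_validate(samples, model_config, train_config, k=5)
print("fold-mean metrics (mean +/- sd over 5 folds):")
for metric, (mean, sd) in result.summary().items():
    print(f"  {metric:>11}: {mean:.4f} +/- {sd:.4f}")

curve = decision_curve(result.y_true, result.y_score, thresholds=[0.21, 0.5, 0.71])
for pt, nb in zip(curve.thresholds, curve.net_benefit):
    print(f"  net benefit at p_t={pt:.2f}: {nb:.3f} (treat-none = 0)")
print("AUC near 1 means the pipeline recovers the class-dependent wash-in "
      "signal from the synthetic clips; net benefit > 0 means the classifier "
      "beats both treat-all and treat-none at that threshold.")
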