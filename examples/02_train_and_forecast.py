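"""Train a minimal-RNN forecaster with model filling and forecast a subject.

Fits the gated recurrent cell on 150 simulated subjects (missing inputs
filled by the model's own one-step predictions during training), then
rolls the model forward 36 months for one held-out subject.
"""

import numpy as np

import adprog as ap
from adprog.filling import fit_fallback_means

cohort, _ = ap.simulate_cohort(ap.SimConfig(n_subjects=150, seed=2))
ids = sorted(cohort.subject_ids)
train_c = cohort.subset(ids[:140])
test_c = cohort.subset(ids[140:])

stats = ap.fit_norm_stats(train_c)          # z-scores from training subjects only
train_n = ap.znormalize(train_c, stats)
test_n = ap.znormalize(test_c, stats)
means = fit_fallback_means(train_n)

cfg = ap.TrainConfig(hidden=64, epochs=40, seed=0)
model = ap.train(train_n, "model", cfg, stats, means)
print(f"training loss: {model.history[0]:.3f} -> {model.history[-1]:.3f}")

subject = test_n.subjects[0]
inp, _ = ap.split_input_target(subject, (subject.n_visits + 1) // 2)
fc = ap.forecast(model, inp, horizon_months=36)
print(f"\nsubject {subject.subject_id}: {inp.n_visits} input visits, "
      f"forecasting months {fc['month'].iloc[0]}..{fc['month'].iloc[-1]}")
cols = ["month", "p_NC", "p_MCI", "p_AD", "adas13", "ventricles_icv"]
print(fc[cols].iloc[[0, 11, 23, 35]].to_string(index=False,
      float_format=lambda x: f"{x:.4f}"))
print("\nEach row: diagnosis probabilities (sum to 1), predicted ADAS-Cog13"
      "\n(higher = worse cognition) and ventricle volume as a fraction of ICV"
      "\n(grows with atrophy).")
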