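"""Train the completion model, then drive a batchwise stop/continue loop.

The model is trained on a synthetic multi-molecule corpus of chi_new
trajectories (chi_new = Boltzmann weight of each newly re-optimized
structure against the running minimum; 0 for duplicates).  A fresh
molecule is then "re-optimized" in 5% batches; after each batch the model
reports a stop/continue call with a calibrated confidence, and the loop
ends once %Conf clears the recommended 80% cutoff.
"""

import numpy as np

from conftriage import build_feature_matrix, predict, train_model
from conftriage.completion import CompletionTrajectory, build_trajectory
from conftriage.prioritize import pipeline_mix
from conftriage.synthetic import (
    duplicate_flags_for,
    make_rotor_ensemble,
    make_trajectory_corpus,
    planted_p_gmt,
    simulate_outcomes,
)

corpus = make_trajectory_corpus(n_molecules=20, m_range=(15, 40), seed=8)
model = train_model(corpus.features, corpus.labels, groups=corpus.groups,
                    seed=8)
print(f"trained on {corpus.n_rows} descriptor rows "
      f"(held-out accuracy {model.holdout_accuracy:.2f}, "
      f"calibration MAE {model.calibration.mae:.1f}%)\n")

# a new molecule the model has never seen
ens, truth = make_rotor_ensemble(n_rotors=4, m=50, duplicate_rate=0.15,
                                 seed=99, allow_replacement=True)
features, _ = build_feature_matrix(ens)
priority = pipeline_mix(ens, features)
results = simulate_outcomes(ens, truth, seed=100)
stream = [results[int(i)] for i in priority.order]
flags = duplicate_flags_for(priority, truth)
full = build_trajectory(stream, ens.m, duplicate_flags=flags)

batch = max(1, int(np.ceil(0.05 * ens.m)))
k = 2  # start after the first two re-optimizations
while k <= ens.m:
    traj = CompletionTrajectory(full.points[:k], ens.m, full.temperature)
    label, p_lr, conf = predict(model, traj)
    print(f"r_opt = {k:2d}/{ens.m} = {k / ens.m:.2f}   "
          f"{label:8s} p_LR = {p_lr:.3f}  %Conf = {conf:5.1f}")
    if label == "stop" and conf > 80.0:
        break
    k += batch

true_p_gmt = planted_p_gmt(priority, truth)
found = k / ens.m >= true_p_gmt
print(f"\ntrue P_GMT of this list: {true_p_gmt:.2f} -> stopping at "
      f"r_opt = {k / ens.m:.2f} {'does' if found else 'does NOT'} "
      "capture the DFT global minimum")
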