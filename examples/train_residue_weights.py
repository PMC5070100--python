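"""Train per-residue weights against activities with a planted ground truth.

Generates a panel of deviation profiles whose activity depends ONLY on the
displacement in residues 40-60, plus an uncorrelated distractor region at
80-100, then runs the random-search hill climb.  Training should make the
score/activity correlation more negative and concentrate high weights inside
the causal window.
"""

import numpy as np

from modict import DomainSet, TrainingConfig, make_training_panel, train_weights

profiles, activities = make_training_panel(seed=0)
print(f"panel: {len(profiles)} profiles of {profiles[0].n} residues; "
      "causal window 40-60, distractor 80-100")

result = train_weights(
    profiles, activities, DomainSet(((1, 120),)),
    TrainingConfig(rounds=4000, seed=1000, perturb_fraction=1 / 120),
)
print(f"uniform-weight baseline r: {result.r_trace[0]:.3f}")
print(f"trained r:                 {result.best_r:.3f}")

top_decile = np.argsort(result.best_weights)[-12:] + 1
inside = np.mean([(40 <= i <= 60) for i in top_decile])
print(f"top-decile weight positions: {sorted(top_decile.tolist())}")
print(f"fraction inside the causal window: {inside:.0%}")
print("\nThe trace is monotone (greedy accept-if-improved) and the run is")
print("bit-reproducible for a fixed seed.")
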