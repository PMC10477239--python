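"""Validate the suitability map with the continuous Boyce index.

Scores are estimated on the upper half of the map and evaluated on the
lower half: the index is the Spearman correlation between the
predicted-to-expected presence ratio F and suitability, in [-1, 1]
(1 = perfect ranking, 0 = no better than chance).
"""

from invasim import (
    ScenarioSpec,
    continuous_boyce,
    holdout_split,
    kfold_scores,
    make_scenario,
    project_scores,
    sample_presence,
)

spec = ScenarioSpec(shape=(200, 200), seed=42, presence_rate=0.1)
lu, presence = make_scenario(spec)
lu_top, lu_bottom = holdout_split(lu, 0.5)
pres_top, pres_bottom = holdout_split(presence, 0.5)

scores = kfold_scores(lu_top, pres_top, k=5)
hsi_bottom = project_scores(lu_bottom, scores)
result = continuous_boyce(hsi_bottom, pres_bottom, window_width="auto", n_eval=100)

print(f"continuous Boyce index = {result.index:.3f} "
      f"(window width {result.window_width:.4f}, "
      f"{result.curve.F.size} of 100 windows retained)")

# null comparison: presence placed uniformly at random (20 replicates —
# a single null draw fluctuates widely around zero)
flat = {c: 1.0 for c in spec.true_scores}
nulls = [continuous_boyce(hsi_bottom, sample_presence(lu_bottom, flat, 0.1, seed=s)).index
         for s in range(20)]
import numpy as np

print(f"random-presence null index = {np.mean(nulls):+.3f} "
      f"(mean of 20 draws, sd {np.std(nulls):.3f})")
print("\nA high index on held-out ground confirms the frequency scores rank "
      "habitat correctly; the null mean near zero shows what 'no signal' "
      "looks like.")
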