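"""Generate a mainland-like mark-recapture dataset and inspect its anatomy.

The default scenario mirrors the study conditions: ~1,700 marked snails over
13 monthly occasions with sparse detection, bright unimodal colour, constant
stage-specific predation and permanent emigration.
"""

import numpy as np

from snailselect import records as rec
from snailselect.synthetic import SimulationScenario, simulate_population

ds = simulate_population(SimulationScenario(seed=8))
df = ds.records
n_marked = df["individual_id"].nunique()
reenc = df.groupby("individual_id").size() - 1
live = ((df["status"] == "live").groupby(df["individual_id"]).sum() - 1).sum()
dead = (df["status"] != "live").sum()
print(f"marked {n_marked} snails; {int((reenc > 0).sum())} re-encountered "
      f"({int(live)} live recaptures, {int(dead)} dead recoveries; "
      f"max {int(reenc.max())} re-encounters)")
# Compare: the field survey marked 1,714 snails and re-encountered 337.

hist = rec.histories_to_matrix(ds.histories)
codes, counts = np.unique(
    hist[[c for c in hist.columns if c.startswith("occ")]].to_numpy(),
    return_counts=True,
)
print("observation-code counts (1/4 live J/A, 2/5 dead-other, 3/6 predated, 7 unseen):")
print(dict(zip(codes.tolist(), counts.tolist())))

predated_latent = np.isin(ds.latent_states, [2, 5, 8, 11]).sum()
print(f"latent predation events: {predated_latent} "
      f"(only those recovered in site are ever observed)")
print("truth parameters retained for recovery scoring, e.g. "
      f"gamma_A = {ds.truth['gamma_A']}")
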