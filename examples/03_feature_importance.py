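"""Rank the 14 maternal features of a trained model by Garson importance.

Garson's equation attributes the network's input-output connection-weight
magnitude to each input and reports it as a percentage (the 14 values sum
to 100%).  On an oracle cohort the ranking reflects the ground-truth
network the targets came from, not clinical reality.
"""

from sgann import rank_features, relative_importance
from sgann.pipeline import run_recovery_experiment

res = run_recovery_experiment(seed=1, restarts=10)
ranking = relative_importance(res.pipeline.model)

print("relative importance (Garson equation):")
for name, pct in rank_features(ranking):
    print(f"  {name:>9s}  {pct:5.1f}%  {'#' * int(round(pct))}")
print(f"\nsum: {ranking.percents.sum():.6f}% (always 100 by construction)")
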