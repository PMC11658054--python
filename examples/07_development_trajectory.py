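"""The messaging syndrome's developmental trajectory and inflection age.

Builds syndrome rows (six messaging metrics per bee-day) with a planted
behavioural switch at 4 days of age, applies the within-day quantile
transform and pooled PCA, smooths the per-age (PC1, PC2) path, and locates
the maximum-curvature inflection point.
"""

import numpy as np
import pandas as pd

from queenrelay import pca_development, quantile_transform, smooth_and_inflect

rng = np.random.default_rng(3)
SWITCH = 4.0
rows = []
for day in range(7):
    for age in range(15):
        young = 1.0 / (1.0 + np.exp((age - SWITCH) / 0.7))
        peak = np.exp(-0.5 * ((age - SWITCH + 0.5) / 1.2) ** 2)
        for b in range(6):
            e = rng.normal(0, 0.08, 6)
            rows.append(
                {"colony": "c", "bee_id": f"d{day}a{age}b{b}", "day": day,
                 "age": age,
                 "m1": peak + e[0],            # queen attraction
                 "m2": 10 * peak + e[1],       # queen contacts
                 "m3": young + e[2],           # nurse affiliation
                 "m4": peak + e[3],            # bridging score
                 "m5": 8 * (1 - young) + e[4], # relay out-degree
                 "m6": 6 * (1 - young) - 2 + e[5]}  # degree difference
            )
syndrome = pd.DataFrame(rows)

transformed = quantile_transform(syndrome)
trajectories, loadings, _ = pca_development(transformed)
t = trajectories[0]
print("PC loadings of the six messaging metrics:")
print(loadings.round(2).to_string())
print(f"\nexplained variance: PC1 {t.explained_variance[0]:.0%}, "
      f"PC2 {t.explained_variance[1]:.0%}")

result = smooth_and_inflect(t)
print(f"\ninflection age of the smoothed (PC1, PC2) path: "
      f"{result['inflection_age']:.0f} d (planted switch at {SWITCH:.0f} d)")
print("workers bend sharpest in messaging space at the age when real bees "
      "peak in queen-rearing tasks.")
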