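#!/usr/bin/env python
"""Serial-passage screen simulation: neutral vs strong-selection regimes.

Runs the selection simulator in the two regimes the temperature screen
distinguishes — a neutral 30 degC control pool and a 42 degC culture in which
one guide carries a strong per-doubling growth advantage — and records how
often five picked clones are all distinct vs all identical.  Writes
results/screen_regimes.csv and the winner's frequency trajectory.
"""

import math
from pathlib import Path

import numpy as np
import pandas as pd

from screenstat.enrichment_stats import UniformLibraryNull, pattern_probabilities
from screenstat.screen_sim import ScreenSimConfig, simulate_screen

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

N_SCREENS = 2000
null = UniformLibraryNull(260, 12)
exact = pattern_probabilities(null, 5)

regimes = {
    "neutral_30C": dict(),
    "strong_selection_42C": dict(fitness={0: 8.0}, doublings=math.log2(100)),
}

rows = []
for name, kwargs in regimes.items():
    all_distinct = all_same = 0
    for seed in range(N_SCREENS):
        traj = simulate_screen(ScreenSimConfig(n_subcultures=5, seed=seed, **kwargs))
        all_distinct += traj.pick_pattern == (1, 1, 1, 1, 1)
        all_same += traj.pick_pattern == (5,)
    rows.append(
        {
            "regime": name,
            "screens": N_SCREENS,
            "freq_all_distinct": all_distinct / N_SCREENS,
            "freq_all_same": all_same / N_SCREENS,
        }
    )
table = pd.DataFrame(rows)
table.to_csv(OUT / "screen_regimes.csv", index=False)

traj = simulate_screen(
    ScreenSimConfig(fitness={0: 8.0}, doublings=math.log2(100), n_subcultures=5, seed=0)
)
pd.DataFrame(
    {"passage": range(len(traj.freq)), "winner_frequency": traj.freq[:, 0]}
).to_csv(OUT / "winner_trajectory.csv", index=False)

print(table.to_string(index=False))
print(f"\nexact null: P(all distinct) = {exact[(1, 1, 1, 1, 1)]:.3f}, "
      f"P(all same) = {exact[(5,)]:.3g}")
print("neutral picks sit on the exact null; strong selection drives the winner from "
      f"{traj.freq[0, 0]:.4f} to {traj.freq[-1, 0]:.4f} of the pool in five passages, "
      "so all five picks carry its guide")
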