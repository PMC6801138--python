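#!/usr/bin/env python
"""Logistic growth kinetics on synthetic plate-reader curves.

Generates quadruplicate OD600 curves for three strains whose half-transition
times differ (a thermotolerant strain transitions ~2.5 h earlier than its
controls at high temperature), fits the 4-parameter logistic model to every
well, and derives the time and height of the maximum growth rate from the
model's first derivative.  Writes results/growth_fits.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from screenstat.growth_model import LogisticFit, fit_many
from screenstat.screen_sim import gen_growth_curves

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

TIMES = np.arange(0.0, 25.0, 1.0)
STRAINS = {
    # overexpressing strain transitions earliest; controls lag by ~2.5 and ~3 h
    "overexpression": LogisticFit(A1=0.2, A2=1.8, x0=11.0, p=4.0),
    "blank_control": LogisticFit(A1=0.2, A2=1.6, x0=13.5, p=4.0),
    "knockdown": LogisticFit(A1=0.2, A2=1.5, x0=14.0, p=4.0),
}

frames = []
for i, (strain, truth) in enumerate(STRAINS.items()):
    df = gen_growth_curves(truth, TIMES, noise_sd=0.02, n_replicates=4, seed=100 + i)
    df["well"] = strain + "_" + df["well"]
    frames.append(df)
curves = pd.concat(frames, ignore_index=True)

fits = fit_many(curves)
fits["strain"] = fits["well"].str.rsplit("_", n=1).str[0]
fits.to_csv(OUT / "growth_fits.csv", index=False)

per_strain = fits.groupby("strain").agg(
    r2_min=("r_squared", "min"),
    t_max_rate_mean=("t_max_rate", "mean"),
    t_max_rate_sd=("t_max_rate", "std"),
    max_rate_mean=("max_rate", "mean"),
)
print(per_strain.to_string(float_format=lambda v: f"{v:.4f}"))
print(f"\nall {len(fits)} wells fit with R^2 > 0.99: {(fits['r_squared'] > 0.99).all()}")
delay = (
    per_strain.loc["blank_control", "t_max_rate_mean"]
    - per_strain.loc["overexpression", "t_max_rate_mean"]
)
print(f"maximum growth rate of the blank control arrives {delay:.2f} h after the "
      "overexpressing strain (ground-truth offset 2.5 h)")
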