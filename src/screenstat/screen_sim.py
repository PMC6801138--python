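"""Synthetic-data generators with known ground truth.

The centrepiece is a serial-passage simulator for the pooled activation
library: each of m guides starts at c copies; every subculture multiplies
expected counts by a guide-specific fitness factor, renormalizes, and
resamples a fixed-size bottleneck population (residual resampling by
default, plain multinomial optionally); after the final passage a handful
of clones is picked without replacement from the realized pool.  With neutral fitness the picks follow the exact equal-copy null of
:mod:`screenstat.enrichment_stats`; with one strongly advantaged guide the
picks collapse onto that guide — the two regimes a temperature screen
distinguishes (42 °C selection vs a 30 °C control).

The module also generates the downstream assay inputs — logistic growth
curves, qPCR Ct tables, GC peak-area tables and TBARS readings — from known
parameters so every quantification stage can be validated by round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .growth_model import LogisticFit, logistic
from .library_model import GuideEntry, GuideLibrary

__all__ = [
    "ScreenSimConfig",
    "ScreenTrajectory",
    "simulate_screen",
    "synthetic_guide_library",
    "gen_growth_curves",
    "gen_ct_table",
    "gen_gc_peaks",
    "gen_tbars",
]

# double-bond counts for the fatty acid species Ole1 biology cares about:
# the desaturase converts 16:0 -> 16:1 and 18:0 -> 18:1
DEFAULT_SATURATION = {"16:0": 0, "16:1": 1, "18:0": 0, "18:1": 1}


@dataclass(frozen=True)
class ScreenSimConfig:
    """Serial-passage screen parameters.

    Defaults mirror the screened library: 260 guides at 12 copies each
    (3120 clones), five subcultures, five picked clones.  ``fitness`` maps
    guide index -> per-subculture growth factor; unlisted guides get
    ``baseline_fitness``.
    """

    n_guides: int = 260
    copies: int = 12
    fitness: Mapping[int, float] = field(default_factory=dict)
    baseline_fitness: float = 1.0
    n_subcultures: int = 5
    bottleneck: int | None = None  # None -> n_guides * copies
    n_picked: int = 5
    doublings: float = 1.0  # generations per subculture; factor = fitness**doublings
    resample: str = "residual"  # "residual" (low-variance) or "multinomial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_guides < 1 or self.copies < 1 or self.n_picked < 1:
            raise ValueError("n_guides, copies and n_picked must be positive")
        if self.n_subcultures < 0:
            raise ValueError("n_subcultures must be >= 0")
        if self.baseline_fitness < 0 or any(w < 0 for w in self.fitness.values()):
            raise ValueError("fitness factors must be non-negative")
        if any(not np.isfinite(w) for w in self.fitness.values()):
            raise ValueError("fitness factors must be finite")
        if self.bottleneck is not None and self.bottleneck < 1:
            raise ValueError("bottleneck must be positive")
        if self.doublings <= 0:
            raise ValueError("doublings must be positive")
        if self.resample not in ("residual", "multinomial"):
            raise ValueError("resample must be 'residual' or 'multinomial'")

    @property
    def pool_size(self) -> int:
        return self.bottleneck if self.bottleneck is not None else self.n_guides * self.copies

    def fitness_vector(self) -> np.ndarray:
        w = np.full(self.n_guides, self.baseline_fitness, dtype=float)
        for g, f in self.fitness.items():
            if not 0 <= g < self.n_guides:
                raise ValueError(f"fitness refers to unknown guide index {g}")
            w[g] = f
        return w


@dataclass(frozen=True)
class ScreenTrajectory:
    """Per-passage guide frequencies and the final picked guides."""

    freq: np.ndarray  # (n_subcultures + 1, n_guides); rows sum to 1
    picks: tuple[int, ...]  # guide indices of the picked clones

    @property
    def pick_pattern(self) -> tuple[int, ...]:
        _, counts = np.unique(np.asarray(self.picks), return_counts=True)
        return tuple(sorted(counts.tolist(), reverse=True))


def _pick_without_replacement(
    rng: np.random.Generator, counts: np.ndarray, k: int
) -> tuple[int, ...]:
    """Sample k clones without replacement from a pool with per-guide counts."""
    total = int(counts.sum())
    if k > total:
        raise ValueError(f"cannot pick {k} clones from a pool of {total}")
    # multivariate hypergeometric via sequential conditional draws
    remaining = counts.astype(np.int64).copy()
    picks = []
    for _ in range(k):
        u = rng.integers(0, remaining.sum())
        g = int(np.searchsorted(np.cumsum(remaining), u, side="right"))
        picks.append(g)
        remaining[g] -= 1
    return tuple(picks)


def _resample(
    rng: np.random.Generator, pool: int, probs: np.ndarray, scheme: str
) -> np.ndarray:
    if scheme == "multinomial":
        return rng.multinomial(pool, probs)
    # residual (low-variance) resampling: the integer part of the expected
    # counts is kept deterministically, only the fractional remainder is
    # drawn multinomially.  A neutral passage of an equal-copy pool is then
    # exactly composition-preserving, matching the control-arm assumption
    # that an unselected library stays evenly distributed.
    expected = pool * probs
    base = np.floor(expected).astype(np.int64)
    r = pool - int(base.sum())
    if r == 0:
        return base
    resid = expected - base
    return base + rng.multinomial(r, resid / resid.sum())


def simulate_screen(config: ScreenSimConfig) -> ScreenTrajectory:
    """Run the serial-passage selection model; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    w = config.fitness_vector() ** config.doublings
    counts = np.full(config.n_guides, config.copies, dtype=np.int64)
    freqs = [counts / counts.sum()]
    pool = config.pool_size
    for _ in range(config.n_subcultures):
        expected = counts * w
        total = expected.sum()
        if total <= 0:
            raise ValueError("population extinct: all surviving guides have zero fitness")
        counts = _resample(rng, pool, expected / total, config.resample)
        freqs.append(counts / counts.sum())
    picks = _pick_without_replacement(rng, counts, config.n_picked)
    return ScreenTrajectory(freq=np.vstack(freqs), picks=picks)


def synthetic_guide_library(
    n_genes: int = 52, guides_per_gene: int = 5, seed: int = 0
) -> GuideLibrary:
    """Random guide catalogue shaped like the screened library.

    Gene ids GENE001..; five random 20-nt spacers per gene; TSS offsets
    drawn in the activating window [-200, 0] with an occasional outlier
    beyond it (as happens in real designs when the window is crowded).
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    entries = []
    for gi in range(n_genes):
        gene = f"GENE{gi + 1:03d}"
        for k in range(guides_per_gene):
            spacer = "".join(rng.choice(bases, size=20))
            if rng.random() < 0.02:
                offset = -int(rng.integers(201, 400))
            else:
                offset = -int(rng.integers(0, 201))
            entries.append(
                GuideEntry(
                    gene_id=gene,
                    guide_id=f"g{gene}_{k + 1}",
                    spacer=spacer,
                    tss_offset=offset,
                )
            )
    return GuideLibrary(entries)


def gen_growth_curves(
    params: LogisticFit,
    times: np.ndarray,
    noise_sd: float = 0.02,
    n_replicates: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Plate-reader-style OD600 table from a known logistic truth.

    Returns a long table (time, well, od); additive Gaussian noise, values
    floored at 0.  ``noise_sd`` default 0.02 OD emulates well-to-well
    reader scatter; quadruplicate wells match a typical plate layout.
    """
    times = np.asarray(times, dtype=float)
    if len(times) < 6 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing with >= 6 points")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    truth = logistic(times, params.A1, params.A2, params.x0, params.p)
    frames = []
    for r in range(n_replicates):
        od = truth + rng.normal(0.0, noise_sd, size=times.shape) if noise_sd > 0 else truth.copy()
        frames.append(
            pd.DataFrame(
                {"time": times, "well": f"W{r + 1}", "od": np.maximum(od, 0.0)}
            )
        )
    return pd.concat(frames, ignore_index=True)


def gen_ct_table(
    true_fold_changes: Mapping[str, float],
    ref_ct: float = 18.0,
    base_ct: Mapping[str, float] | None = None,
    replicate_sd: float = 0.0,
    n_replicates: int = 3,
    reference_gene: str = "TAF10",
    seed: int = 0,
) -> pd.DataFrame:
    """qPCR Ct table (sample, gene, replicate, ct) with known fold changes.

    Two samples are emitted: "treatment" and "control".  A gene with true
    fold f has its treatment Ct shifted by -log2(f) relative to its control
    baseline (one cycle earlier per doubling of transcript); the reference
    gene is unshifted.  Zero noise makes the downstream ddCt recovery exact.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    for gene, f in true_fold_changes.items():
        if not f > 0:
            raise ValueError(f"fold change for {gene!r} must be positive, got {f}")
    if base_ct is None:
        base_ct = {g: 24.0 for g in true_fold_changes}
    rng = np.random.default_rng(seed)
    rows = []

    def emit(sample: str, gene: str, centre: float) -> None:
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, replicate_sd) if replicate_sd > 0 else 0.0
            rows.append({"sample": sample, "gene": gene, "replicate": rep, "ct": centre + noise})

    for sample in ("treatment", "control"):
        emit(sample, reference_gene, ref_ct)
    for gene, fold in true_fold_changes.items():
        b = base_ct.get(gene, 24.0)
        emit("control", gene, b)
        emit("treatment", gene, b - np.log2(fold))
    return pd.DataFrame(rows)


def gen_gc_peaks(
    composition: Mapping[str, float],
    total_conc: float = 50.0,
    is_conc: float = 10.0,
    is_area: float = 1000.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """GC-FID peak-area table with an internal-standard (IS) row.

    With unit response factors, area_i = conc_i / is_conc * area_IS where
    conc_i = fraction_i * total_conc.  ``noise_cv`` applies multiplicative
    lognormal-ish scatter to sample peaks only.
    """
    fracs = np.array(list(composition.values()), dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"composition fractions must sum to 1, got {fracs.sum()!r}")
    if np.any(fracs < 0):
        raise ValueError("composition fractions must be non-negative")
    rng = np.random.default_rng(seed)
    rows = [{"species": "IS", "area": is_area}]
    for sp, frac in composition.items():
        area = frac * total_conc / is_conc * is_area
        if noise_cv > 0:
            area *= np.exp(rng.normal(0.0, noise_cv))
        rows.append({"species": sp, "area": area})
    return pd.DataFrame(rows)


def gen_tbars(
    true_mda: Mapping[str, float],
    slope: float = 0.02,
    intercept: float = 0.0,
    noise_sd: float = 0.0,
    n_standards: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TBARS OD535 readings plus calibration standards.

    Returns (samples, standards).  Samples carry od535 = slope*conc +
    intercept + noise for the known MDA concentrations; standards span
    [0, 1.25 * max truth] so interpolation never extrapolates.
    """
    if not slope > 0:
        raise ValueError("calibration slope must be positive")
    if n_standards < 3:
        raise ValueError("need >= 3 calibration standards")
    rng = np.random.default_rng(seed)
    top = 1.25 * max(max(true_mda.values()), 1e-9)
    std_conc = np.linspace(0.0, top, n_standards)
    standards = pd.DataFrame(
        {
            "concentration": std_conc,
            "od535": slope * std_conc
            + intercept
            + (rng.normal(0.0, noise_sd, size=n_standards) if noise_sd > 0 else 0.0),
        }
    )
    samples = pd.DataFrame(
        {
            "sample": list(true_mda),
            "od535": [
                slope * c + intercept + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                for c in true_mda.values()
            ],
        }
    )
    return samples, standards
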