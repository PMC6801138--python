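"""Phenotype assay quantification stages.

* ddCt relative expression: fold = E**(-ddCt) with amplification efficiency
  E = 2 (ideal doubling per cycle), a target gene normalised to a reference
  gene (TAF10 in yeast) and a control sample.  Down-regulation is reported
  by the reciprocal convention ("down by 7.39-fold" means fold = 1/7.39).
* TBARS lipid peroxidation: an OD535 reading is converted through a linear
  MDA calibration curve and expressed as moles MDA equivalent per 1e7 cells.
* FAME composition: GC peak areas relative to an internal standard give
  concentrations; fractions, the unsaturated (UFA) fraction and the
  monounsaturated (mono-UFA) fraction follow.
* Replicate statistics: two-sample Student's t test (pooled variance;
  Welch behind a flag), two-sided, significance at alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtTable",
    "FoldChangeResult",
    "TbarsCalibration",
    "FattyAcidProfile",
    "TTestResult",
    "ddct_fold_change",
    "fit_calibration",
    "tbars_mda",
    "fame_profile",
    "replicate_test",
]


class AssayError(ValueError):
    """Raised for inconsistent or incomplete assay inputs."""


@dataclass(frozen=True)
class CtTable:
    """Long-format qPCR Ct records with a declared reference gene and control.

    ``data`` columns: sample, gene, replicate, ct.
    """

    data: pd.DataFrame
    reference_gene: str = "TAF10"
    control_sample: str = "control"

    def __post_init__(self) -> None:
        required = {"sample", "gene", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise AssayError(f"Ct table missing columns {sorted(missing)}")
        if not np.isfinite(self.data["ct"]).all():
            raise AssayError("Ct values must be finite")
        for sample in self.data["sample"].unique():
            sub = self.data[self.data["sample"] == sample]
            if self.reference_gene not in set(sub["gene"]):
                raise AssayError(
                    f"reference gene {self.reference_gene!r} absent for sample {sample!r}"
                )

    def mean_ct(self, sample: str, gene: str) -> tuple[float, float, int]:
        """(mean, sd, n) of replicate Ct for one sample/gene pair."""
        sel = self.data[(self.data["sample"] == sample) & (self.data["gene"] == gene)]
        if sel.empty:
            raise AssayError(f"no Ct records for gene {gene!r} in sample {sample!r}")
        vals = sel["ct"].to_numpy(dtype=float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        return float(vals.mean()), sd, len(vals)


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    sample: str
    fold: float  # raw 2^(-ddCt)
    direction: str  # "up" | "down"
    reported_fold: float  # >= 1; reciprocal for down-regulation
    ddct: float
    ddct_sd: float

    def __post_init__(self) -> None:
        if self.reported_fold < 1.0 - 1e-12:
            raise AssayError("reported_fold must be >= 1")


def ddct_fold_change(
    table: CtTable, gene: str, sample: str, efficiency: float = 2.0
) -> FoldChangeResult:
    """Relative expression of ``gene`` in ``sample`` vs the control sample.

    dCt = mean Ct(gene) - mean Ct(reference) within each sample;
    ddCt = dCt(sample) - dCt(control); fold = efficiency**(-ddCt).
    Replicate SDs are propagated in quadrature onto ddCt.
    """
    if not efficiency > 1:
        raise AssayError("amplification efficiency must exceed 1")
    parts = []
    for s in (sample, table.control_sample):
        g_mean, g_sd, g_n = table.mean_ct(s, gene)
        r_mean, r_sd, r_n = table.mean_ct(s, table.reference_gene)
        parts.append((g_mean - r_mean, g_sd**2 / max(g_n, 1) + r_sd**2 / max(r_n, 1)))
    ddct = parts[0][0] - parts[1][0]
    ddct_sd = float(np.sqrt(parts[0][1] + parts[1][1]))
    fold = float(efficiency ** (-ddct))
    if fold >= 1.0:
        direction, reported = "up", fold
    else:
        direction, reported = "down", 1.0 / fold
    return FoldChangeResult(
        gene=gene,
        sample=sample,
        fold=fold,
        direction=direction,
        reported_fold=reported,
        ddct=float(ddct),
        ddct_sd=ddct_sd,
    )


@dataclass(frozen=True)
class TbarsCalibration:
    """Linear OD535-vs-MDA-concentration calibration."""

    slope: float  # OD per concentration unit
    intercept: float  # OD
    r_squared: float
    standards: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise AssayError("calibration slope must be positive")


def fit_calibration(standards: pd.DataFrame) -> TbarsCalibration:
    """Ordinary least-squares line through (concentration, od535) standards."""
    required = {"concentration", "od535"}
    if not required.issubset(standards.columns):
        raise AssayError(f"standards table needs columns {sorted(required)}")
    if len(standards) < 3:
        raise AssayError("need at least 3 calibration standards")
    x = standards["concentration"].to_numpy(dtype=float)
    y = standards["od535"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise AssayError("standards are degenerate: fewer than 2 distinct concentrations")
    res = stats.linregress(x, y)
    return TbarsCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        standards=standards.copy(),
    )


@dataclass(frozen=True)
class TbarsResult:
    concentration: float  # MDA concentration in the assay (calibration units)
    amount: float  # concentration * assay volume
    per_1e7_cells: float  # amount scaled to 1e7 cells
    clipped: bool  # True when a negative concentration was floored at 0


def tbars_mda(
    calibration: TbarsCalibration,
    od535: float,
    cells: float,
    assay_volume: float,
) -> TbarsResult:
    """MDA equivalents per 1e7 cells from one OD535 reading.

    ``assay_volume`` is in the volume unit matching the calibration's
    concentration unit (e.g. mL with µM gives nmol).  Negative inferred
    concentrations (reading below the blank) are floored at 0 and flagged.
    """
    if not cells > 0:
        raise AssayError("cell count must be positive")
    if not assay_volume > 0:
        raise AssayError("assay volume must be positive")
    conc = (od535 - calibration.intercept) / calibration.slope
    clipped = conc < 0
    conc = max(conc, 0.0)
    amount = conc * assay_volume
    return TbarsResult(
        concentration=conc,
        amount=amount,
        per_1e7_cells=amount * (1e7 / cells),
        clipped=clipped,
    )


@dataclass(frozen=True)
class FattyAcidProfile:
    concentrations: dict[str, float]
    fractions: dict[str, float]
    ufa_fraction: float
    mono_ufa_fraction: float

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise AssayError(f"fractions must sum to 1, got {total}")
        if self.mono_ufa_fraction > self.ufa_fraction + 1e-12:
            raise AssayError("mono-UFA fraction cannot exceed UFA fraction")


def fame_profile(
    peaks: pd.DataFrame,
    is_conc: float,
    saturation_map: Mapping[str, int] | None = None,
    response_factors: Mapping[str, float] | None = None,
    is_species: str = "IS",
) -> FattyAcidProfile:
    """Fatty-acid composition from a GC peak-area table.

    conc_i = (area_i / area_IS) * is_conc * response_factor_i; fractions are
    normalized concentrations.  ``saturation_map`` gives double-bond counts
    per species (defaults cover 16:0/16:1/18:0/18:1); species without an
    annotation raise.
    """
    if saturation_map is None:
        from .screen_sim import DEFAULT_SATURATION

        saturation_map = DEFAULT_SATURATION
    if not {"species", "area"}.issubset(peaks.columns):
        raise AssayError("peak table needs columns species, area")
    is_rows = peaks[peaks["species"] == is_species]
    if is_rows.empty:
        raise AssayError(f"internal standard {is_species!r} peak is missing")
    is_area = float(is_rows["area"].iloc[0])
    if not is_area > 0:
        raise AssayError("internal standard peak area must be positive")
    rf = response_factors or {}
    concs: dict[str, float] = {}
    for r in peaks.itertuples(index=False):
        if r.species == is_species:
            continue
        if r.species not in saturation_map:
            raise AssayError(
                f"species {r.species!r} lacks a double-bond annotation in saturation_map"
            )
        concs[r.species] = (float(r.area) / is_area) * is_conc * rf.get(r.species, 1.0)
    total = sum(concs.values())
    if not total > 0:
        raise AssayError("no quantifiable fatty-acid peaks")
    fractions = {sp: c / total for sp, c in concs.items()}
    ufa = sum(f for sp, f in fractions.items() if saturation_map[sp] >= 1)
    mono = sum(f for sp, f in fractions.items() if saturation_map[sp] == 1)
    return FattyAcidProfile(
        concentrations=concs,
        fractions=fractions,
        ufa_fraction=ufa,
        mono_ufa_fraction=mono,
    )


@dataclass(frozen=True)
class TTestResult:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    significant: bool
    alpha: float


def replicate_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alpha: float = 0.05,
    welch: bool = False,
) -> TTestResult:
    """Two-sided two-sample t test on replicate measurements.

    Pooled-variance Student's t by default; Welch's unequal-variance test
    with ``welch=True``.  Two identical zero-variance groups give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise AssayError("need >= 2 replicates per group")
    if not 0 < alpha < 1:
        raise AssayError("alpha must lie in (0, 1)")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = np.inf * np.sign(a.mean() - b.mean()), 0.0
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=not welch)
        t_stat, p = float(t_stat), float(p)
    return TTestResult(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        t_statistic=t_stat,
        p_value=p,
        significant=p < alpha,
        alpha=alpha,
    )
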