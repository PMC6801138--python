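"""End-to-end pipeline: coverage design, screen, enrichment test, assays.

A single YAML config drives the stages in the order a pooled-screen
campaign runs them: library coverage math, the serial-passage screen
(simulated with a seed, or picked-clone ids read from a file), the exact
enrichment test on the picked clones, logistic growth fits, and the qPCR /
TBARS / FAME quantifications.  Outputs are CSV tables, a JSON manifest
capturing inputs and seeds, and a plain-text report whose body is
byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assay_quant import (
    CtTable,
    ddct_fold_change,
    fame_profile,
    fit_calibration,
    tbars_mda,
)
from .enrichment_stats import (
    PickOutcome,
    UniformLibraryNull,
    enrichment_report,
    prob_all_distinct,
    prob_all_same,
)
from .growth_model import LogisticFit, fit_many
from .library_model import (
    coverage_probability,
    expected_copies_per_guide,
    load_guide_table,
    required_clones,
)
from .screen_sim import (
    ScreenSimConfig,
    gen_ct_table,
    gen_gc_peaks,
    gen_growth_curves,
    gen_tbars,
    simulate_screen,
    synthetic_guide_library,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "DEMO_CONFIG"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


# Demo configuration mirroring the screened library's constants:
# 52 genes x 5 guides = 260 constructs, ~3000 colonies for coverage,
# idealized 12 copies/guide (3120 clones), 5 subcultures, 5 picks.
DEMO_CONFIG: dict[str, Any] = {
    "seed": 0,
    "coverage": {"n_genes": 52, "guides_per_gene": 5, "colonies": 3000, "target_prob": 0.9999},
    "screen": {
        "copies": 12,
        "n_subcultures": 5,
        "n_picked": 5,
        "selected_guide": 0,
        "selected_fitness": 8.0,
    },
    "growth": {
        "A1": 0.2,
        "A2": 1.8,
        "x0": 8.0,
        "p": 4.0,
        "noise_sd": 0.02,
        "n_replicates": 4,
        "t_max": 24.0,
    },
    "qpcr": {"true_fold_changes": {"ANB1": 21.37, "GPH1": 1.96, "OLE1_knockdown": 1 / 7.39}},
    "tbars": {"true_mda": {"30C": 10.0, "42C": 25.0}, "slope": 0.02, "cells": 1e7, "volume": 1.0},
    "fame": {"composition": {"16:0": 0.3, "16:1": 0.2, "18:0": 0.1, "18:1": 0.4}, "is_conc": 10.0},
}


@dataclass
class PipelineConfig:
    """Validated pipeline settings (synthetic mode unless files are given)."""

    raw: dict[str, Any]
    out_dir: Path
    guide_table: Path | None = None
    picked_file: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, out_dir)

    @classmethod
    def from_dict(cls, raw: dict[str, Any], out_dir: str | Path) -> "PipelineConfig":
        guide_table = raw.get("guide_table")
        picked = raw.get("picked_file")
        synthetic = "seed" in raw
        if not synthetic and guide_table is None:
            raise PipelineError(
                "config", "either a guide_table path or a synthetic-mode seed is required"
            )
        return cls(
            raw=raw,
            out_dir=Path(out_dir),
            guide_table=Path(guide_table) if guide_table else None,
            picked_file=Path(picked) if picked else None,
        )

    def get(self, key: str, default: Any = None) -> Any:
        return self.raw.get(key, default)


def _fmt_prob(p: float) -> str:
    return f"{p:.3g}"


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict[str, Any] = {"version": __version__, "seed": seed, "stages": {}}
    report: list[str] = ["pooled-screen analysis report", "=" * 30, ""]
    warnings: list[str] = []

    # ---- stage: library + coverage -------------------------------------
    try:
        cov_cfg = config.get("coverage", {})
        if config.guide_table is not None:
            library = load_guide_table(config.guide_table)
        else:
            library = synthetic_guide_library(
                n_genes=int(cov_cfg.get("n_genes", 52)),
                guides_per_gene=int(cov_cfg.get("guides_per_gene", 5)),
                seed=seed,
            )
        colonies = int(cov_cfg.get("colonies", 3000))
        target = float(cov_cfg.get("target_prob", 0.9999))
        cov = coverage_probability(library.n_guides, colonies)
        need = required_clones(library.n_guides, target)
        library.to_frame().to_csv(out / "guide_library.csv", index=False)
        manifest["stages"]["coverage"] = {
            "n_guides": library.n_guides,
            "n_genes": len(library.genes),
            "colonies": colonies,
            "coverage_probability": cov,
            "required_clones": need,
        }
        report += [
            "[coverage]",
            f"guides: {library.n_guides} ({len(library.genes)} genes)",
            f"colonies pooled: {colonies}",
            f"per-guide coverage probability: {cov:.6f}"
            + (" (> 99.99%)" if cov > 0.9999 else ""),
            f"clones required for P >= {target}: {need}",
            "",
        ]
    except PipelineError:
        raise
    except Exception as err:
        _fail(out, report, "coverage", err)

    # ---- stage: screen (simulate or ingest picks) ----------------------
    try:
        scr_cfg = config.get("screen", {})
        copies = int(scr_cfg.get("copies", 12))
        cc = expected_copies_per_guide(copies * library.n_guides, library.n_guides)
        if not cc.integral:
            warnings.append(f"non-integer copies per guide: {cc.copies}")
        null = UniformLibraryNull(m=library.n_guides, c=copies)
        if config.picked_file is not None:
            picked_ids = [
                ln.strip()
                for ln in config.picked_file.read_text().splitlines()
                if ln.strip()
            ]
            outcome = PickOutcome.from_guide_ids(picked_ids)
            picks_repr = picked_ids
        else:
            fitness = {}
            if scr_cfg.get("selected_guide") is not None:
                fitness[int(scr_cfg["selected_guide"])] = float(
                    scr_cfg.get("selected_fitness", 8.0)
                )
            sim = ScreenSimConfig(
                n_guides=library.n_guides,
                copies=copies,
                fitness=fitness,
                n_subcultures=int(scr_cfg.get("n_subcultures", 5)),
                n_picked=int(scr_cfg.get("n_picked", 5)),
                seed=seed,
            )
            traj = simulate_screen(sim)
            outcome = PickOutcome(traj.pick_pattern)
            picks_repr = [library.entries[g].guide_id for g in traj.picks]
            pd.DataFrame(
                traj.freq,
                columns=[e.guide_id for e in library.entries],
            ).to_csv(out / "guide_frequencies.tsv", sep="\t", index=False)
            (out / "picks.txt").write_text("\n".join(picks_repr) + "\n")
        manifest["stages"]["screen"] = {"picks": picks_repr, "pattern": list(outcome.pattern)}
        report += ["[screen]", f"picked clones: {', '.join(picks_repr)}", ""]
    except PipelineError:
        raise
    except Exception as err:
        _fail(out, report, "screen", err)

    # ---- stage: enrichment test ----------------------------------------
    try:
        k = outcome.k
        p_diff = prob_all_distinct(null, k)
        p_same = prob_all_same(null, k)
        verdict = enrichment_report(outcome, null, alpha=float(config.get("alpha", 0.05)))
        manifest["stages"]["enrichment"] = {
            "m": null.m,
            "c": null.c,
            "k": k,
            "p_all_distinct": p_diff,
            "p_all_same": p_same,
            "observed_pattern": list(outcome.pattern),
            "point_probability": verdict.point_probability,
            "tail_probability": verdict.tail_probability,
            "reject_uniform_null": verdict.reject,
        }
        report += [
            "[enrichment]",
            f"null: {null.m} guides x {null.c} copies = {null.N} clones; k = {k} picks",
            f"P(all distinct) = {_fmt_prob(p_diff)}",
            f"P(all same)     = {_fmt_prob(p_same)}",
            f"observed pattern: {list(outcome.pattern)}",
            f"pattern probability = {_fmt_prob(verdict.point_probability)}; "
            f"tail = {_fmt_prob(verdict.tail_probability)}",
            "verdict: " + ("REJECT uniform null (enrichment)" if verdict.reject else "retain uniform null"),
            "",
        ]
    except Exception as err:
        _fail(out, report, "enrichment", err)

    # ---- stage: growth fits ---------------------------------------------
    try:
        g = config.get("growth", {})
        truth = LogisticFit(
            A1=float(g.get("A1", 0.2)),
            A2=float(g.get("A2", 1.8)),
            x0=float(g.get("x0", 8.0)),
            p=float(g.get("p", 4.0)),
        )
        times = np.arange(0.0, float(g.get("t_max", 24.0)) + 1e-9, 1.0)
        curves = gen_growth_curves(
            truth,
            times,
            noise_sd=float(g.get("noise_sd", 0.02)),
            n_replicates=int(g.get("n_replicates", 4)),
            seed=seed + 1,
        )
        fits = fit_many(curves, seed=seed + 1)
        fits.to_csv(out / "growth_fits.csv", index=False)
        manifest["stages"]["growth"] = {
            "truth": {"A1": truth.A1, "A2": truth.A2, "x0": truth.x0, "p": truth.p},
            "min_r_squared": float(fits["r_squared"].min()),
            "mean_t_max_rate": float(fits["t_max_rate"].mean()),
        }
        report += [
            "[growth]",
            f"{len(fits)} wells fitted; min R^2 = {fits['r_squared'].min():.4f}",
            f"mean time of max growth rate = {fits['t_max_rate'].mean():.2f} h",
            "",
        ]
    except Exception as err:
        _fail(out, report, "growth", err)

    # ---- stage: qPCR ----------------------------------------------------
    try:
        q = config.get("qpcr", {})
        folds = {k_: float(v) for k_, v in q.get("true_fold_changes", {"ANB1": 21.37}).items()}
        ct = gen_ct_table(
            folds,
            replicate_sd=float(q.get("replicate_sd", 0.0)),
            n_replicates=int(q.get("n_replicates", 3)),
            seed=seed + 2,
        )
        table = CtTable(ct)
        results = [ddct_fold_change(table, gene, "treatment") for gene in folds]
        qdf = pd.DataFrame(
            {
                "gene": [r.gene for r in results],
                "fold": [r.fold for r in results],
                "direction": [r.direction for r in results],
                "reported_fold": [r.reported_fold for r in results],
            }
        )
        qdf.to_csv(out / "qpcr_fold_changes.csv", index=False)
        manifest["stages"]["qpcr"] = qdf.to_dict(orient="records")
        report += ["[qpcr]"] + [
            f"{r.gene}: {r.reported_fold:.2f}-fold {r.direction}" for r in results
        ] + [""]
    except Exception as err:
        _fail(out, report, "qpcr", err)

    # ---- stage: TBARS ---------------------------------------------------
    try:
        tb = config.get("tbars", {})
        samples, standards = gen_tbars(
            {k_: float(v) for k_, v in tb.get("true_mda", {"42C": 25.0}).items()},
            slope=float(tb.get("slope", 0.02)),
            intercept=float(tb.get("intercept", 0.0)),
            noise_sd=float(tb.get("noise_sd", 0.0)),
            seed=seed + 3,
        )
        calib = fit_calibration(standards)
        rows = []
        for r in samples.itertuples(index=False):
            res = tbars_mda(
                calib,
                r.od535,
                cells=float(tb.get("cells", 1e7)),
                assay_volume=float(tb.get("volume", 1.0)),
            )
            if res.clipped:
                warnings.append(f"TBARS sample {r.sample}: negative concentration floored at 0")
            rows.append({"sample": r.sample, "od535": r.od535, "mda_per_1e7_cells": res.per_1e7_cells})
        tdf = pd.DataFrame(rows)
        tdf.to_csv(out / "tbars.csv", index=False)
        manifest["stages"]["tbars"] = {
            "slope": calib.slope,
            "intercept": calib.intercept,
            "r_squared": calib.r_squared,
            "samples": tdf.to_dict(orient="records"),
        }
        report += ["[tbars]", f"calibration slope {calib.slope:.4g}, R^2 {calib.r_squared:.4f}"] + [
            f"{row['sample']}: {row['mda_per_1e7_cells']:.3g} MDA eq. per 1e7 cells" for row in rows
        ] + [""]
    except Exception as err:
        _fail(out, report, "tbars", err)

    # ---- stage: FAME ----------------------------------------------------
    try:
        fm = config.get("fame", {})
        comp = {k_: float(v) for k_, v in fm.get(
            "composition", {"16:0": 0.3, "16:1": 0.2, "18:0": 0.1, "18:1": 0.4}
        ).items()}
        peaks = gen_gc_peaks(comp, is_conc=float(fm.get("is_conc", 10.0)), seed=seed + 4)
        profile = fame_profile(peaks, is_conc=float(fm.get("is_conc", 10.0)))
        fdf = pd.DataFrame(
            {"species": list(profile.fractions), "fraction": list(profile.fractions.values())}
        )
        fdf.to_csv(out / "fame_fractions.csv", index=False)
        manifest["stages"]["fame"] = {
            "fractions": profile.fractions,
            "ufa_fraction": profile.ufa_fraction,
            "mono_ufa_fraction": profile.mono_ufa_fraction,
        }
        report += [
            "[fame]",
            f"UFA fraction = {profile.ufa_fraction:.3f}; mono-UFA = {profile.mono_ufa_fraction:.3f}",
            "",
        ]
    except Exception as err:
        _fail(out, report, "fame", err)

    if warnings:
        report += ["[warnings]"] + warnings + [""]
    manifest["warnings"] = warnings
    (out / "report.txt").write_text("\n".join(report))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _fail(out: Path, report: list[str], stage: str, err: Exception) -> None:
    """Persist partial outputs with a FAILED marker, then raise."""
    report += [f"[{stage}] FAILED: {err}", ""]
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.txt").write_text("\n".join(report))
    (out / "FAILED").write_text(f"{stage}: {err}\n")
    raise PipelineError(stage, str(err)) from err
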