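"""End-to-end demonstration pipeline on simulated data.

Simulates two mash conditions (a 23 L-style vessel mash and a faster-
extracting 1 mL micro-mash), runs trypsin normalization, builds the
scale-comparison difference map, classifies time- vs temperature-dependent
changes at protein and peptide level against the simulator's ground truth,
and quantifies simulated sugar/amino-acid standards. Everything is written
as CSV plus a JSON summary carrying the seed and config hash; internal
invariants (profile and fraction conservation, map antisymmetry) are checked
and reflected in the exit status.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, config_hash
from .metabolites import AnalytePanel, quantify_table
from .normalize import family_fractions, normalized_profiles, point_means
from .quantio import write_quant_table
from .scale_compare import difference_map, map_report
from .simulate import default_dataset, labels_to_str
from .stage_extension import classify_all

__all__ = ["run_full_demo", "simulate_standards", "label_agreement"]

log = logging.getLogger("micromash")


def simulate_standards(panel: AnalytePanel, seed: int, area_cv: float = 0.02):
    """Simulated MRM standards and wort unknowns for the analyte panel.

    Each analyte gets a 6-point standard series with analyte-specific
    response slope and 2% multiplicative area noise, plus triplicate unknown
    areas drawn from a mid-curve "wort" concentration. Returns
    ``(standards, unknowns, true_concentrations)``.
    """
    rng = np.random.default_rng(seed)
    levels = np.array([0.5, 1.0, 2.0, 5.0, 10.0, 20.0])
    std_rows, unk_rows, truth = [], [], {}
    for analyte in panel.analytes:
        slope = rng.uniform(50.0, 500.0)
        true_diluted = rng.uniform(2.0, 8.0)  # mid-curve, in standard units
        truth[analyte] = true_diluted * panel.dilution
        for conc in levels:
            area = slope * conc * rng.lognormal(0.0, area_cv)
            std_rows.append({"analyte": analyte, "concentration": conc, "area": area})
        for rep in range(1, 4):
            area = slope * true_diluted * rng.lognormal(0.0, area_cv)
            unk_rows.append({"analyte": analyte, "sample": f"wort_rep{rep}", "area": area})
    return pd.DataFrame(std_rows), pd.DataFrame(unk_rows), truth


def label_agreement(calls: pd.DataFrame, truth: pd.DataFrame, transition: str | None = None) -> float:
    """Fraction of (feature, transition) cells where the classifier's label
    set equals the simulator's ground truth."""
    t = truth[truth["basis"] == "abundance"][["feature_id", "transition", "label"]]
    merged = calls.merge(t, on=["feature_id", "transition"], suffixes=("_call", "_truth"))
    if transition is not None:
        merged = merged[merged["transition"] == transition]
    if merged.empty:
        raise ValueError("no overlapping calls and truth rows")
    return float((merged["label_call"] == merged["label_truth"]).mean())


def run_full_demo(config: RunConfig, out_dir) -> Path:
    """Run the whole pipeline on simulated data; returns the output directory.

    Raises RuntimeError naming the failing stage if any internal invariant
    breaks.
    """
    if config.noise.n_replicates < 2:
        raise ValueError("full demo needs n_replicates >= 2 for statistics")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config_hash(config)}
    config.to_yaml(out / "config.yaml")

    # --- simulate two conditions ------------------------------------------
    stage = "simulate"
    braumeister, truth_b = default_dataset(
        seed=config.seed,
        condition="braumeister-23L",
        n_replicates=config.noise.n_replicates,
        cv=config.noise.cv,
        run_scale_sd=config.noise.run_scale_sd,
        extraction_multiplier=1.0,
        program=config.program,
        delta=config.delta,
    )
    micro, truth_m = default_dataset(
        seed=config.seed + 1,
        condition="micro-1mL",
        n_replicates=config.noise.n_replicates,
        cv=config.noise.cv,
        run_scale_sd=config.noise.run_scale_sd,
        extraction_multiplier=1.6,   # faster extraction at micro scale
        program=config.program,
        delta=config.delta,
    )
    write_quant_table(braumeister, out / "quant_braumeister-23L.csv")
    write_quant_table(micro, out / "quant_micro-1mL.csv")
    truth_m.to_csv(out / "ground_truth_micro-1mL.csv", index=False)

    # --- normalization -----------------------------------------------------
    stage = "normalise"
    norm_b = normalized_profiles(braumeister[braumeister["feature_type"] != "peptide"])
    norm_m = normalized_profiles(micro[micro["feature_type"] != "peptide"])
    point_means(norm_b).to_csv(out / "normalized_braumeister-23L.csv", index=False)
    point_means(norm_m).to_csv(out / "normalized_micro-1mL.csv", index=False)
    sums = point_means(norm_m).groupby("feature_id")["mean"].sum()
    if not np.allclose(sums, 1.0, atol=1e-9):
        raise RuntimeError(f"stage {stage}: normalized profiles do not sum to 1")
    frac = family_fractions(micro)
    fsums = frac.groupby(["family_id", "stage", "point", "replicate"])["fraction"].sum()
    if not np.allclose(fsums.dropna(), 1.0, atol=1e-9):
        raise RuntimeError(f"stage {stage}: family fractions do not sum to 1")
    frac.to_csv(out / "family_fractions_micro-1mL.csv", index=False)

    # --- scale comparison --------------------------------------------------
    stage = "compare-scales"
    dmap = difference_map(norm_b, norm_m, alpha=config.alpha_protein,
                          family=config.family_mode)
    swapped = difference_map(norm_m, norm_b, alpha=config.alpha_protein,
                             family=config.family_mode)
    if not np.allclose(dmap.cells["D"], -swapped.cells["D"], atol=1e-12):
        raise RuntimeError(f"stage {stage}: difference map not antisymmetric")
    if (dmap.cells["D"].abs() > 1.0 + 1e-12).any():
        raise RuntimeError(f"stage {stage}: |D| exceeds 1")
    map_report(dmap, out / "difference_map")

    # --- dependence classification ----------------------------------------
    stage = "classify-dependence"
    calls_protein = classify_all(micro, config.program, level="protein",
                                 alpha=config.alpha_protein)
    calls_peptide = classify_all(micro, config.program, level="peptide",
                                 alpha=config.alpha_peptide)
    calls_protein.to_csv(out / "dependence_calls_protein.csv", index=False)
    calls_peptide.to_csv(out / "dependence_calls_peptide.csv", index=False)
    agreement = label_agreement(calls_protein, truth_m)

    # --- metabolite quantification ----------------------------------------
    stage = "quantify-metabolites"
    panel = AnalytePanel()
    standards, unknowns, truth_conc = simulate_standards(panel, seed=config.seed + 2)
    results = quantify_table(standards, unknowns, dilution=panel.dilution)
    results["true_concentration"] = results["analyte"].map(truth_conc)
    results.to_csv(out / "metabolite_concentrations.csv", index=False)
    rec = results.groupby("analyte").apply(
        lambda g: g["concentration"].mean() / g["true_concentration"].iloc[0],
        include_groups=False,
    )
    if not ((rec - 1.0).abs() < 0.10).all():
        raise RuntimeError(f"stage {stage}: calibration recovery off by >10%")

    summary = {
        **meta,
        "n_protein_features": int(braumeister[
            braumeister["feature_type"] == "protein"]["feature_id"].nunique()),
        "difference_map_cells": int(len(dmap.cells)),
        "difference_map_significant": int(dmap.cells["significant"].sum()),
        "protein_label_agreement": agreement,
        "protein_label_counts": calls_protein["label"].value_counts().to_dict(),
        "peptide_label_counts": calls_peptide["label"].value_counts().to_dict(),
        "metabolite_mean_recovery": float(rec.mean()),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("full demo complete: %s", out)
    return out
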