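"""The three normalization layers of the mash-proteomics workflow.

1. **Relative abundance** R: each feature's intensity divided by the trypsin
   self-digest reference intensity of the same run. Trypsin is spiked at
   nominally constant amount per sample, so this cancels per-run loading and
   instrument-response factors.
2. **Normalised abundance** N: per feature and condition, the per-point
   replicate mean of R divided by the sum of those means across all sampled
   points. Profiles then sum to 1 over the time course and are comparable
   between features and conditions.
3. **Family fractions** f: within a peptide family (a full-tryptic peptide
   plus its clipped forms), each form's intensity divided by the summed
   intensity of all detected forms at that run. Reports proteolysis-driven
   redistribution independently of total family abundance.

Zeros are never imputed: an all-zero feature or a zero family total is
flagged and excluded/NaN rather than pseudo-counted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationError",
    "relative_to_trypsin",
    "normalise_timecourse",
    "normalized_profiles",
    "family_fractions",
    "log2_fold_change",
    "point_means",
]

log = logging.getLogger("micromash")

RUN_KEY = ["condition", "stage", "point", "replicate"]


class NormalizationError(ValueError):
    pass


def relative_to_trypsin(table: pd.DataFrame, method: str = "sum") -> pd.DataFrame:
    """Relative abundance R = intensity / trypsin-reference intensity per run.

    The run's trypsin intensity is the sum (default; ``method="mean"`` for the
    mean) of all ``trypsin_ref`` feature intensities in that run. Every run
    must contain at least one trypsin reference with positive total; a run
    without one, or with a zero total, raises NormalizationError naming it.

    Returns the non-trypsin rows with an added ``rel_abundance`` column.
    """
    if method not in ("sum", "mean"):
        raise ValueError("method must be 'sum' or 'mean'")
    tryp = table[table["feature_type"] == "trypsin_ref"]
    feats = table[table["feature_type"] != "trypsin_ref"].copy()
    if tryp.empty:
        raise NormalizationError("table contains no trypsin_ref records")

    agg = tryp.groupby(RUN_KEY, sort=False)["intensity"].agg(method)
    runs = feats[RUN_KEY].drop_duplicates()
    missing = runs.merge(agg.reset_index(), how="left", on=RUN_KEY)
    bad = missing[missing["intensity"].isna() | (missing["intensity"] <= 0)]
    if len(bad):
        r = bad.iloc[0]
        raise NormalizationError(
            "run without positive trypsin reference: "
            f"condition={r['condition']}, stage={r['stage']}, "
            f"point={r['point']}, replicate={r['replicate']}"
        )

    denom = feats.set_index(RUN_KEY).index.map(agg)
    feats["rel_abundance"] = feats["intensity"].to_numpy() / denom.to_numpy()
    return feats


def normalise_timecourse(rel: pd.DataFrame) -> pd.DataFrame:
    """Normalised abundance N across the sampled time course.

    Per (feature, condition): the replicate mean of R at each (stage, point)
    is divided by the sum of those means over all sampled points, so the
    per-point mean N values of a feature sum to 1. The replicate-level column
    ``norm_abundance`` (= R / same denominator) is retained so downstream
    statistics can use within-point replicate variation.

    Features whose R is zero at every point have no defined profile; they are
    flagged with a warning and excluded from the output.
    """
    need = {"feature_id", "condition", "stage", "point", "replicate", "rel_abundance"}
    if not need.issubset(rel.columns):
        raise NormalizationError(f"missing columns: {need - set(rel.columns)}")
    if rel.groupby(["feature_id", "condition"])[["stage", "point"]].apply(
        lambda g: len(g.drop_duplicates())
    ).min() < 2:
        raise NormalizationError("need >= 2 sampled points per (feature, condition)")

    means = (
        rel.groupby(["feature_id", "condition", "stage", "point"], sort=False)[
            "rel_abundance"
        ]
        .mean()
        .rename("point_mean")
        .reset_index()
    )
    totals = (
        means.groupby(["feature_id", "condition"], sort=False)["point_mean"]
        .sum()
        .rename("total")
        .reset_index()
    )
    zero = totals[totals["total"] <= 0]
    for _, r in zero.iterrows():
        log.warning(
            "feature %s (%s) has zero total relative abundance; excluded",
            r["feature_id"], r["condition"],
        )
    out = rel.merge(totals[totals["total"] > 0], on=["feature_id", "condition"])
    out["norm_abundance"] = out["rel_abundance"] / out["total"]
    return out.drop(columns="total")


def normalized_profiles(table: pd.DataFrame, method: str = "sum") -> pd.DataFrame:
    """Convenience pipeline: trypsin-relative then time-course normalization."""
    return normalise_timecourse(relative_to_trypsin(table, method=method))


def point_means(
    norm: pd.DataFrame, value: str = "norm_abundance"
) -> pd.DataFrame:
    """Per-point replicate means of a normalized table (heatmap-ready, tidy)."""
    return (
        norm.groupby(["feature_id", "condition", "stage", "point"], sort=False)[value]
        .mean()
        .rename("mean")
        .reset_index()
    )


def family_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Within-family form fractions per run.

    Each peptide form's intensity is divided by the summed intensity of all
    detected forms of the same family in the same run. Where a family's total
    is zero the fractions are undefined: those rows get NaN and a warning.

    Returns the peptide rows with an added ``fraction`` column.
    """
    pep = table[(table["feature_type"] == "peptide") & (table["family_id"] != "")].copy()
    if pep.empty:
        raise NormalizationError("no peptide records with a family_id")
    key = ["condition", "family_id", "stage", "point", "replicate"]
    totals = pep.groupby(key, sort=False)["intensity"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, pep["intensity"] / totals, np.nan)
    n_undef = int(np.isnan(frac).sum())
    if n_undef:
        log.warning(
            "family fractions undefined at %d records (zero family total)", n_undef
        )
    pep["fraction"] = frac
    return pep


def log2_fold_change(values_a, values_b) -> float:
    """log2 of the ratio of means, point A -> point B.

    Antisymmetric under swapping A and B. Raises on a non-positive mean (no
    pseudo-count is applied; zeros should be handled upstream).
    """
    ma = float(np.mean(values_a))
    mb = float(np.mean(values_b))
    if ma <= 0 or mb <= 0:
        raise NormalizationError(
            f"log2 fold change needs positive means (got {ma}, {mb})"
        )
    return float(np.log2(mb / ma))
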