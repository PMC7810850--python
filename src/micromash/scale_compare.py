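"""Stage-aligned comparison of two mash scales.

Builds the per-feature, per-timepoint difference map between two conditions
(e.g. a 23 L vessel mash and a 1 mL micro-mash): the difference of the
normalized-abundance means at each (stage, point), with a Student's t-test on
the replicate-level values and Bonferroni correction over the map. Positive
differences mean higher in condition 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bonferroni, students_t_matrix

__all__ = ["DifferenceMap", "difference_map", "map_report"]

log = logging.getLogger("micromash")

CELL = ["feature_id", "stage", "point"]


@dataclass
class DifferenceMap:
    """Result of a two-condition comparison.

    ``cells`` is tidy: feature_id, stage, point, D (mean N condition 1 minus
    mean N condition 2), t, df, p, p_adj, significant. ``alpha`` and
    ``family`` record the significance convention; ``grid`` the (stage,
    point) order used for matrix exports.
    """

    cells: pd.DataFrame
    condition_1: str
    condition_2: str
    alpha: float
    family: str
    grid: list[tuple[str, str]]

    def matrix(self, value: str = "D") -> pd.DataFrame:
        """Features × timepoints matrix of ``value`` (heatmap-ready)."""
        wide = self.cells.pivot(index="feature_id", columns=["stage", "point"], values=value)
        cols = [g for g in self.grid if g in wide.columns]
        return wide[cols]

    def mask(self) -> pd.DataFrame:
        """Boolean significance mask aligned with :meth:`matrix`."""
        wide = self.cells.pivot(
            index="feature_id", columns=["stage", "point"], values="significant"
        )
        cols = [g for g in self.grid if g in wide.columns]
        return wide[cols].astype(bool)


def difference_map(
    norm_1: pd.DataFrame,
    norm_2: pd.DataFrame,
    alpha: float = 0.05,
    family: str = "global",
) -> DifferenceMap:
    """Difference of normalized-abundance means per feature and timepoint.

    Inputs are replicate-level normalized tables (from
    :func:`micromash.normalize.normalise_timecourse`) of the two conditions.
    Timepoints are matched by (stage, point) label; the feature set and grid
    are intersected, with mismatches logged and dropped rather than
    zero-filled. The Bonferroni family is either every cell of the map
    (``"global"``) or each feature's own row (``"per-feature"``).
    """
    if family not in ("global", "per-feature"):
        raise ValueError("family must be 'global' or 'per-feature'")
    c1 = norm_1["condition"].unique()
    c2 = norm_2["condition"].unique()
    if len(c1) != 1 or len(c2) != 1:
        raise ValueError("each input must hold exactly one condition")

    f1, f2 = set(norm_1["feature_id"]), set(norm_2["feature_id"])
    shared = f1 & f2
    if not shared:
        raise ValueError("conditions share no features")
    for lost, cond in (((f1 | f2) - shared, "either"),):
        if lost:
            log.warning("dropping %d features absent from one condition", len(lost))

    g1 = set(map(tuple, norm_1[["stage", "point"]].drop_duplicates().to_numpy()))
    g2 = set(map(tuple, norm_2[["stage", "point"]].drop_duplicates().to_numpy()))
    shared_grid = g1 & g2
    if not shared_grid:
        raise ValueError("conditions share no (stage, point) grid cells")
    if g1 != g2:
        log.warning(
            "dropping %d grid cells absent from one condition", len((g1 | g2) - shared_grid)
        )

    def _wide(norm):
        d = norm[
            norm["feature_id"].isin(shared)
            & norm[["stage", "point"]].apply(tuple, axis=1).isin(shared_grid)
        ]
        return d.pivot_table(
            index=CELL, columns="replicate", values="norm_abundance", sort=True
        )

    w1, w2 = _wide(norm_1), _wide(norm_2)
    idx = w1.index.intersection(w2.index)
    w1, w2 = w1.loc[idx], w2.loc[idx]
    res = students_t_matrix(w1.to_numpy(), w2.to_numpy())
    cells = pd.DataFrame(index=idx).reset_index()
    cells["D"] = (w1.mean(axis=1) - w2.mean(axis=1)).to_numpy()
    cells[["t", "df", "p"]] = res[["t", "df", "p"]].to_numpy()

    if family == "global":
        cells["p_adj"] = bonferroni(cells["p"].to_numpy())
    else:
        cells["p_adj"] = cells.groupby("feature_id")["p"].transform(
            lambda p: bonferroni(p.to_numpy())
        )
    cells["significant"] = cells["p_adj"] < alpha

    # program order for exports: follow condition 1's appearance order
    order = [
        g for g in map(tuple, norm_1[["stage", "point"]].drop_duplicates().to_numpy())
        if g in shared_grid
    ]
    return DifferenceMap(
        cells=cells,
        condition_1=str(c1[0]),
        condition_2=str(c2[0]),
        alpha=alpha,
        family=family,
        grid=order,
    )


def map_report(dmap: DifferenceMap, out_prefix) -> dict:
    """Write the map as tidy CSV plus heatmap matrix and significance mask.

    Returns the paths written, keyed by role.
    """
    out_prefix = str(out_prefix)
    paths = {
        "cells": out_prefix + "_cells.csv",
        "matrix": out_prefix + "_matrix.csv",
        "mask": out_prefix + "_mask.csv",
    }
    dmap.cells.to_csv(paths["cells"], index=False)
    dmap.matrix().to_csv(paths["matrix"])
    dmap.mask().to_csv(paths["mask"])
    log.info(
        "difference map %s vs %s: %d cells, %d significant at alpha=%g",
        dmap.condition_1, dmap.condition_2, len(dmap.cells),
        int(dmap.cells["significant"].sum()), dmap.alpha,
    )
    return paths
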