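"""Time- vs temperature-dependence classification via stage extensions.

The experimental trick: at the end of a rest the mash can either be held
longer at the same temperature (the stage *extension*, X) or moved to the
next rest's temperature (whose end is NE). Comparing abundance at the stage
end (E), the extension (X) and the end of the next stage (NE) separates the
two drivers of change:

* E vs X significant  -> the feature changes with **time** at this temperature;
* X vs NE significant -> the feature changes with **temperature**;
* only E vs NE significant -> the change needs both, labelled
  ``time+temperature`` (neither driver alone moved it detectably).
* nothing significant -> ``none``.

When both E–X and X–NE are significant the feature receives both labels
(``{time, temperature}``); the E–NE comparison is then informational only.
Proteins are classified on normalized abundance, peptide forms on
within-family fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normalize import family_fractions, normalized_profiles
from .program import MashProgram
from .simulate import labels_to_str
from .stats import TestResult, students_t

__all__ = [
    "StageTriple",
    "DependenceCall",
    "decision_labels",
    "build_triples",
    "classify",
    "classify_all",
]

log = logging.getLogger("micromash")


@dataclass(frozen=True)
class StageTriple:
    """Replicate-level abundances of one feature at E, X and NE.

    X is sampled at the same temperature as E; NE at the next stage's
    temperature. Each arm needs >= 2 replicates for testing.
    """

    feature_id: str
    stage: str
    next_stage: str
    E: np.ndarray
    X: np.ndarray
    NE: np.ndarray

    @property
    def transition(self) -> str:
        return f"{self.stage}->{self.next_stage}"


@dataclass
class DependenceCall:
    """Classification of one feature at one stage transition."""

    feature_id: str
    transition: str
    p_EX: float
    p_XNE: float
    p_ENE: float
    lfc_EX: float
    lfc_XNE: float
    lfc_ENE: float
    labels: frozenset = field(default_factory=frozenset)

    @property
    def label_str(self) -> str:
        return labels_to_str(self.labels)


def decision_labels(sig_EX: bool, sig_XNE: bool, sig_ENE: bool) -> frozenset:
    """Map a significance triple to a dependence label set.

    Every one of the 8 combinations has a defined outcome: the E–X and X–NE
    comparisons contribute ``time`` and ``temperature`` independently; only
    when neither fires does a significant E–NE yield the joint
    ``time+temperature`` label; otherwise ``none``.
    """
    labels = set()
    if sig_EX:
        labels.add("time")
    if sig_XNE:
        labels.add("temperature")
    if not labels:
        labels = {"time+temperature"} if sig_ENE else {"none"}
    return frozenset(labels)


def build_triples(
    values: pd.DataFrame, program: MashProgram, value_col: str
) -> list[StageTriple]:
    """Assemble E/X/NE replicate vectors per feature per extended stage.

    ``values`` is tidy with columns feature_id, stage, point, replicate and
    ``value_col``. Every stage with an extension and a successor yields one
    triple per feature; stages whose extension point is missing from the
    table are skipped with a warning. The boil (final stage) never yields a
    triple of its own.
    """
    triples: list[StageTriple] = []
    have = set(map(tuple, values[["stage", "point"]].drop_duplicates().to_numpy()))
    piv = values.pivot_table(
        index="feature_id", columns=["stage", "point"], values=value_col,
        aggfunc=list, sort=True,
    )
    for i, stage in enumerate(program.stages[:-1]):
        if stage.extension <= 0:
            continue
        nxt = program.stages[i + 1]
        needed = [(stage.name, "end"), (stage.name, "extension"), (nxt.name, "end")]
        if any(k not in have for k in needed):
            log.warning(
                "stage %s skipped: missing %s",
                stage.name, [k for k in needed if k not in have],
            )
            continue
        for fid in piv.index:
            arms = [np.asarray(piv.loc[fid, k], dtype=float) for k in needed]
            arms = [a[~np.isnan(a)] for a in arms]
            if min(a.size for a in arms) < 2:
                log.warning("feature %s at %s: <2 replicates, skipped", fid, stage.name)
                continue
            triples.append(StageTriple(fid, stage.name, nxt.name, *arms))
    return triples


def _safe_lfc(a: np.ndarray, b: np.ndarray) -> float:
    ma, mb = float(np.mean(a)), float(np.mean(b))
    if ma <= 0 or mb <= 0:
        return float("nan")
    return float(np.log2(mb / ma))


def classify(triple: StageTriple, alpha: float = 0.05, test=students_t) -> DependenceCall:
    """Classify one triple with three two-group tests at threshold ``alpha``.

    ``test`` is any callable with the :func:`micromash.stats.students_t`
    signature (e.g. a linear-contrast wrapper). The raw p-values are
    thresholded directly; multiple-testing control across features, if
    wanted, is applied by the caller.
    """
    r_EX: TestResult = test(triple.E, triple.X)
    r_XNE: TestResult = test(triple.X, triple.NE)
    r_ENE: TestResult = test(triple.E, triple.NE)
    labels = decision_labels(r_EX.p < alpha, r_XNE.p < alpha, r_ENE.p < alpha)
    return DependenceCall(
        feature_id=triple.feature_id,
        transition=triple.transition,
        p_EX=r_EX.p,
        p_XNE=r_XNE.p,
        p_ENE=r_ENE.p,
        lfc_EX=_safe_lfc(triple.E, triple.X),
        lfc_XNE=_safe_lfc(triple.X, triple.NE),
        lfc_ENE=_safe_lfc(triple.E, triple.NE),
        labels=labels,
    )


def classify_all(
    table: pd.DataFrame,
    program: MashProgram,
    level: str = "protein",
    alpha: float | None = None,
    test=students_t,
) -> pd.DataFrame:
    """Classify every feature at every extended stage transition.

    ``level="protein"`` classifies proteins on replicate-level normalized
    abundance (default alpha 0.05); ``level="peptide"`` classifies peptide
    forms on within-family fractions (default alpha 1e-5, the stringent
    peptide-level convention). Returns a tidy frame of calls.
    """
    if level == "protein":
        alpha = 0.05 if alpha is None else alpha
        norm = normalized_profiles(table[table["feature_type"] != "peptide"])
        values = norm.rename(columns={"norm_abundance": "value"})
    elif level == "peptide":
        alpha = 1e-5 if alpha is None else alpha
        frac = family_fractions(table)
        values = frac.rename(columns={"fraction": "value"}).dropna(subset=["value"])
    else:
        raise ValueError("level must be 'protein' or 'peptide'")

    triples = build_triples(
        values[["feature_id", "stage", "point", "replicate", "value"]],
        program,
        "value",
    )
    calls = [classify(t, alpha=alpha, test=test) for t in triples]
    return pd.DataFrame(
        {
            "feature_id": [c.feature_id for c in calls],
            "transition": [c.transition for c in calls],
            "p_EX": [c.p_EX for c in calls],
            "p_XNE": [c.p_XNE for c in calls],
            "p_ENE": [c.p_ENE for c in calls],
            "lfc_EX": [c.lfc_EX for c in calls],
            "lfc_XNE": [c.lfc_XNE for c in calls],
            "lfc_ENE": [c.lfc_ENE for c in calls],
            "label": [c.label_str for c in calls],
        }
    )
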