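"""Forward simulator for mash proteomics quant tables.

Emulates the structure of DIA/SWATH label-free datasets from replicated mash
time courses: triplicate (or n-replicate) runs at every sample point of a
multi-rest mash program, proteins with rise-then-fall soluble profiles,
peptide families whose proteolytically clipped forms differ in thermal
stability, trypsin self-digest reference peptides in every run, per-run scale
factors, and multiplicative log-normal measurement noise.  Alongside the
noisy table it emits the exact noiseless ground truth of every feature's
behaviour across each stage transition, labelled time- and/or
temperature-dependent by a relative-change rule, so that downstream
classifiers can be benchmarked against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import ProteinKinetics, simulate_timecourse
from .program import MashProgram, default_program

__all__ = [
    "NoiseModel",
    "PeptideFormSpec",
    "generate_dataset",
    "ground_truth_label",
    "default_protein_set",
    "default_families",
    "default_dataset",
    "benchmark_dataset",
]

#: columns of the long-format quant table dialect
QUANT_COLUMNS = [
    "feature_id",
    "feature_type",
    "protein_id",
    "family_id",
    "form_id",
    "condition",
    "stage",
    "point",
    "replicate",
    "intensity",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise model for simulated runs.

    ``cv`` is the multiplicative log-normal coefficient of variation of a
    single intensity; ``run_scale_sd`` the standard deviation of the per-run
    log scale factor (shared by every feature in a run, trypsin references
    included, so spike-in normalization can cancel it); ``trypsin_mean`` the
    expected *summed* trypsin-reference intensity of a run, split across
    ``n_trypsin`` reference features. Identical seeds give bit-identical
    output.
    """

    cv: float = 0.10
    run_scale_sd: float = 0.2
    trypsin_mean: float = 1000.0
    n_replicates: int = 3
    n_trypsin: int = 3
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.run_scale_sd < 0:
            raise ValueError("cv and run_scale_sd must be >= 0")
        if self.n_replicates < 1 or self.n_trypsin < 1:
            raise ValueError("n_replicates and n_trypsin must be >= 1")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")

    @property
    def sigma_log(self) -> float:
        """Log-space SD giving exactly the requested CV."""
        return math.sqrt(math.log1p(self.cv**2))


@dataclass(frozen=True)
class PeptideFormSpec:
    """One form (full-tryptic or clipped) of a peptide family.

    ``kinetics`` carries the form's own parameters — clipped forms typically
    get a lower T_m than the full-tryptic parent. The form's share of the
    family produced during low-temperature proteolysis, ``generation_fraction``,
    scales its initial amounts; fractions within a family must sum to 1
    (checked by :func:`generate_dataset`).
    """

    protein_id: str
    family_id: str
    form_id: str
    kinetics: ProteinKinetics
    generation_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 < self.generation_fraction <= 1.0):
            raise ValueError("generation_fraction must be in (0, 1]")


def ground_truth_label(E: float, X: float, NE: float, delta: float) -> frozenset:
    """Label a stage transition from its noiseless E/X/NE values.

    E is the abundance at the stage end, X after the stage extension (same
    temperature, more time), NE at the end of the next stage (new
    temperature). A change larger than ``delta`` relative to E over the
    extension is time-dependent; from extension to next-stage end,
    temperature-dependent; if neither moves but end-to-next-end does, the
    change needs both ("time+temperature"); otherwise "none". A zero (or
    negative) reference abundance E yields "none" by convention.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if E <= 0:
        return frozenset({"none"})
    labels = set()
    if abs(X - E) > delta * E:
        labels.add("time")
    if abs(NE - X) > delta * E:
        labels.add("temperature")
    if not labels:
        labels = {"time+temperature"} if abs(NE - E) > delta * E else {"none"}
    return frozenset(labels)


def labels_to_str(labels: frozenset) -> str:
    return ",".join(sorted(labels))


def _transitions(program: MashProgram):
    """(stage, next_stage) pairs for every stage with an extension and a successor."""
    out = []
    for i, s in enumerate(program.stages[:-1]):
        if s.extension > 0:
            out.append((s, program.stages[i + 1]))
    return out


def _truth_rows(program, feature_id, basis, values, delta, extra=None):
    """Ground-truth rows from a {(stage, point): value} mapping."""
    rows = []
    for stage, nxt in _transitions(program):
        E = values.get((stage.name, "end"))
        X = values.get((stage.name, "extension"))
        NE = values.get((nxt.name, "end"))
        if E is None or X is None or NE is None:
            continue
        label = ground_truth_label(E, X, NE, delta)
        row = {
            "feature_id": feature_id,
            "transition": f"{stage.name}->{nxt.name}",
            "basis": basis,
            "E": E,
            "X": X,
            "NE": NE,
            "delta_EX": X - E,
            "delta_XNE": NE - X,
            "delta_ENE": NE - E,
            "label": labels_to_str(label),
        }
        if extra:
            row.update(extra)
        rows.append(row)
    return rows


def generate_dataset(
    program: MashProgram,
    kinetics_list: list[ProteinKinetics],
    families: list[PeptideFormSpec] | None = None,
    noise: NoiseModel = NoiseModel(),
    condition: str = "micro-1mL",
    delta: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a noisy replicate quant table plus its exact ground truth.

    Per replicate r and sample point, every feature's observed intensity is
    ``noiseless_S * run_scale(r, point) * lognormal(cv)``; trypsin reference
    features get ``trypsin_mean/n_trypsin * run_scale(r, point) *
    lognormal(cv)``. Ground truth carries, per feature and stage transition,
    the noiseless E/X/NE values (soluble abundance for proteins, within-family
    fraction for peptide forms) and the dependence label at threshold
    ``delta``.

    Returns ``(quant_table, ground_truth)`` as tidy DataFrames.
    """
    families = families or []
    rng = np.random.default_rng(noise.seed)
    grid = program.grid()
    n_pts = len(grid)
    n_rep = noise.n_replicates

    # per-run scale factors, one MS run per (point, replicate)
    log_scales = rng.normal(0.0, noise.run_scale_sd, size=(n_pts, n_rep))
    run_scale = np.exp(log_scales) if noise.run_scale_sd > 0 else np.ones((n_pts, n_rep))

    sigma = noise.sigma_log

    def _noise(shape):
        if sigma == 0:
            return np.ones(shape)
        return np.exp(rng.normal(0.0, sigma, size=shape))

    records = []

    def _emit(feature_id, ftype, protein_id, family_id, form_id, noiseless):
        obs = noiseless[:, None] * run_scale * _noise((n_pts, n_rep))
        if noise.dropout > 0:
            obs = np.where(rng.random(obs.shape) < noise.dropout, 0.0, obs)
        for i, (stage, point) in enumerate(grid):
            for r in range(n_rep):
                records.append(
                    (
                        feature_id,
                        ftype,
                        protein_id,
                        family_id,
                        form_id,
                        condition,
                        stage,
                        point,
                        r + 1,
                        obs[i, r],
                    )
                )

    truth_rows = []

    # proteins
    for kin in kinetics_list:
        traj = simulate_timecourse(program, kin)
        values = {
            (s, p): v for s, p, v in zip(traj["stage"], traj["point"], traj["value"])
        }
        noiseless = np.array([values[g] for g in grid])
        _emit(kin.feature_id, "protein", kin.feature_id, "", "", noiseless)
        truth_rows += _truth_rows(program, kin.feature_id, "abundance", values, delta)

    # peptide families: forms share the family pool via generation fractions
    by_family: dict[str, list[PeptideFormSpec]] = {}
    for spec in families:
        by_family.setdefault(spec.family_id, []).append(spec)
    for family_id, specs in by_family.items():
        total = sum(s.generation_fraction for s in specs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"family {family_id}: generation fractions sum to {total}, not 1"
            )
        form_values = {}
        for spec in specs:
            kin = spec.kinetics.with_(
                G0=spec.kinetics.G0 * spec.generation_fraction,
                S0=spec.kinetics.S0 * spec.generation_fraction,
            )
            traj = simulate_timecourse(program, kin)
            form_values[spec.form_id] = {
                (s, p): v
                for s, p, v in zip(traj["stage"], traj["point"], traj["value"])
            }
        for spec in specs:
            vals = form_values[spec.form_id]
            noiseless = np.array([vals[g] for g in grid])
            fid = f"{spec.family_id}|{spec.form_id}"
            _emit(fid, "peptide", spec.protein_id, spec.family_id, spec.form_id, noiseless)
            fractions = {
                g: (
                    vals[g] / tot
                    if (tot := sum(fv[g] for fv in form_values.values())) > 0
                    else 0.0
                )
                for g in grid
            }
            truth_rows += _truth_rows(
                program, fid, "fraction", fractions, delta,
                extra={"family_id": spec.family_id, "form_id": spec.form_id},
            )

    # trypsin self-digest references
    per_feature = noise.trypsin_mean / noise.n_trypsin
    for j in range(noise.n_trypsin):
        _emit(
            f"TRYP_REF_{j + 1}",
            "trypsin_ref",
            "TRYPSIN",
            "",
            "",
            np.full(n_pts, per_feature),
        )

    table = pd.DataFrame.from_records(records, columns=QUANT_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return table, truth


# ---------------------------------------------------------------------------
# stock parameter sets
# ---------------------------------------------------------------------------

def default_protein_set() -> list[ProteinKinetics]:
    """A panel of malt-like proteins spanning the thermal-stability range.

    Extraction parameters give rising profiles through the low-temperature
    rests; melting midpoints from 58 to 105 °C spread the fall over the
    program, with the most stable protein surviving the boil.
    """
    panel = []
    tms = [58, 62, 66, 70, 74, 78, 82, 86, 90, 95, 100, 105]
    for i, tm in enumerate(tms):
        panel.append(
            ProteinKinetics(
                feature_id=f"PROT_{i + 1:02d}_Tm{tm}",
                G0=1.0,
                S0=0.05,
                k_ext_ref=0.03 + 0.005 * (i % 4),
                b_ext=0.05,
                T_ref=63.0,
                k_den_max=0.25 + 0.01 * (i % 5),
                T_m=float(tm),
                s_m=3.0,
            )
        )
    return panel


def default_families() -> list[PeptideFormSpec]:
    """Two peptide families of clipped forms with site-specific stability.

    Modelled on barley alpha-amylase/trypsin inhibitor (IAAA) residues
    122–145 and non-specific lipid transfer protein (NLTP1) residues 99–115:
    a full-tryptic parent plus semi-tryptic clipped forms whose melting
    midpoints differ, so family fractions redistribute as temperature climbs.
    """

    def kin(fid, tm, kd=0.3):
        return ProteinKinetics(
            feature_id=fid, G0=1.0, S0=0.05, k_ext_ref=0.035, b_ext=0.04,
            T_ref=63.0, k_den_max=kd, T_m=tm, s_m=2.5,
        )

    fams = []
    iaaa = "IAAA_122_145"
    fams += [
        PeptideFormSpec("IAAA", iaaa, "VLVTPGQCNVLTVHNAPYCLGLDI[122-145]",
                        kin("IAAA_full", 92.0), 0.40),
        PeptideFormSpec("IAAA", iaaa, "VLVTPGQCNVLTVH[122-135]",
                        kin("IAAA_135", 84.0), 0.25),
        PeptideFormSpec("IAAA", iaaa, "VLVTPGQCN[122-130]",
                        kin("IAAA_130", 66.0), 0.25),
        PeptideFormSpec("IAAA", iaaa, "VLVTPGQCNVLTVHNAPYCLGLD[122-144]",
                        kin("IAAA_144", 88.0), 0.10),
    ]
    nltp = "NLTP1_99_115"
    fams += [
        PeptideFormSpec("NLTP1", nltp, "CNVNVPYTISPDIDCSR[99-115]",
                        kin("NLTP1_full", 96.0), 0.45),
        PeptideFormSpec("NLTP1", nltp, "ISPDIDCSR[107-115]",
                        kin("NLTP1_107", 72.0), 0.55),
    ]
    return fams


def default_dataset(
    seed: int = 0,
    condition: str = "micro-1mL",
    n_replicates: int = 3,
    cv: float = 0.10,
    run_scale_sd: float = 0.2,
    extraction_multiplier: float = 1.0,
    program: MashProgram | None = None,
    delta: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The stock synthetic dataset: default program, protein panel, two
    peptide families and trypsin references, in triplicate.

    ``extraction_multiplier`` scales every extraction rate and emulates the
    faster wetting/extraction of a 1 mL micro-mash relative to a 23 L vessel.
    """
    program = program or default_program()
    proteins = [
        k.with_(k_ext_ref=k.k_ext_ref * extraction_multiplier)
        for k in default_protein_set()
    ]
    families = [
        PeptideFormSpec(
            s.protein_id, s.family_id, s.form_id,
            s.kinetics.with_(k_ext_ref=s.kinetics.k_ext_ref * extraction_multiplier),
            s.generation_fraction,
        )
        for s in default_families()
    ]
    noise = NoiseModel(
        cv=cv, run_scale_sd=run_scale_sd, n_replicates=n_replicates, seed=seed
    )
    return generate_dataset(
        program, proteins, families, noise, condition=condition, delta=delta
    )


def benchmark_dataset(
    seed: int = 0,
    n_time: int = 100,
    n_temperature: int = 100,
    cv: float = 0.10,
    n_replicates: int = 6,
    delta: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """The standard label-recovery benchmark.

    Half the proteins are time-dependent at the 63 °C transition: their T_m
    sits far below 63 °C so the loss rate is saturated and identical at 63 and
    73 °C; with the 20 min extension equal to the 20 min 73 °C rest, the
    extension branch and the next-stage end coincide and the ground truth is
    a pure time label. The other half are temperature-dependent: T_m = 68 °C
    between the rests, with negligible loss during the 63 °C extension and a
    >= 2-fold drop across the 73 °C rest. Effect sizes are >= 2-fold over the
    relevant interval. Proteins start fully extracted (no extraction term) so
    the transition of interest isolates the planted effect.

    Returns ``(quant_table, ground_truth, designated_transition)``.
    """
    k_time = math.log(2.2) / 20.0  # ~2.2-fold loss over the 20 min extension
    k_temp = 0.055                 # ~3-fold loss over the 20 min 73 °C rest
    kinetics = []
    for i in range(n_time):
        kinetics.append(
            ProteinKinetics(
                feature_id=f"TIME_{i + 1:03d}", G0=0.0, S0=1.0,
                k_ext_ref=0.0, b_ext=0.0, k_den_max=k_time, T_m=40.0, s_m=1.0,
            )
        )
    for i in range(n_temperature):
        kinetics.append(
            ProteinKinetics(
                feature_id=f"TEMP_{i + 1:03d}", G0=0.0, S0=1.0,
                k_ext_ref=0.0, b_ext=0.0, k_den_max=k_temp, T_m=68.0, s_m=1.0,
            )
        )
    program = default_program()
    noise = NoiseModel(cv=cv, run_scale_sd=0.15, n_replicates=n_replicates, seed=seed)
    table, truth = generate_dataset(program, kinetics, None, noise, delta=delta)
    return table, truth, "63C->73C"
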