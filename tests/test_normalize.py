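"""Trypsin-relative, time-course and family-fraction normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micromash import (
    ProteinKinetics,
    default_program,
    family_fractions,
    log2_fold_change,
    normalise_timecourse,
    normalized_profiles,
    point_means,
    relative_to_trypsin,
    simulate_timecourse,
)
from micromash.normalize import NormalizationError
from micromash.simulate import NoiseModel, generate_dataset


def make_table(rows):
    cols = ["feature_id", "feature_type", "protein_id", "family_id", "form_id",
            "condition", "stage", "point", "replicate", "intensity"]
    return pd.DataFrame(rows, columns=cols)


def run_row(fid, ftype, stage, point, rep, intensity, family="", form=""):
    return (fid, ftype, fid, family, form, "c", stage, point, rep, intensity)


class TestRelativeToTrypsin:
    def test_definitional_ratio(self):
        t = make_table([
            run_row("P1", "protein", "s", "end", 1, 1000.0),
            run_row("T1", "trypsin_ref", "s", "end", 1, 300.0),
            run_row("T2", "trypsin_ref", "s", "end", 1, 200.0),
        ])
        rel = relative_to_trypsin(t)
        assert rel["rel_abundance"].iloc[0] == pytest.approx(2.0)

    def test_per_run_scaling_cancels(self):
        t = make_table([
            run_row("P1", "protein", "s", "end", 1, 1000.0),
            run_row("T1", "trypsin_ref", "s", "end", 1, 500.0),
        ])
        scaled = t.copy()
        scaled["intensity"] *= 7.3
        assert relative_to_trypsin(t)["rel_abundance"].iloc[0] == pytest.approx(
            relative_to_trypsin(scaled)["rel_abundance"].iloc[0]
        )

    def test_run_without_trypsin_reference_fails(self):
        t = make_table([
            run_row("P1", "protein", "s", "end", 1, 1000.0),
            run_row("T1", "trypsin_ref", "s", "end", 2, 500.0),
        ])
        with pytest.raises(NormalizationError, match="replicate=1"):
            relative_to_trypsin(t)

    def test_mean_option(self):
        t = make_table([
            run_row("P1", "protein", "s", "end", 1, 1000.0),
            run_row("T1", "trypsin_ref", "s", "end", 1, 300.0),
            run_row("T2", "trypsin_ref", "s", "end", 1, 200.0),
        ])
        rel = relative_to_trypsin(t, method="mean")
        assert rel["rel_abundance"].iloc[0] == pytest.approx(4.0)


class TestNormaliseTimecourse:
    def test_profile_from_point_means(self):
        rows = []
        for point, val in [("start", 2.0), ("end", 2.0), ("extension", 4.0)]:
            rows.append(run_row("P1", "protein", "s", point, 1, val))
        t = make_table(rows)
        t["rel_abundance"] = t["intensity"]
        norm = normalise_timecourse(t)
        means = point_means(norm).set_index("point")["mean"]
        assert means["start"] == pytest.approx(0.25)
        assert means["extension"] == pytest.approx(0.5)

    def test_constant_profile_is_uniform(self):
        rows = [run_row("P1", "protein", s, "end", 1, 3.0) for s in "abcd"]
        t = make_table(rows)
        t["rel_abundance"] = t["intensity"]
        norm = normalise_timecourse(t)
        assert np.allclose(norm["norm_abundance"], 0.25)

    def test_profiles_sum_to_one_on_simulated_data(self, stock_dataset):
        table, _ = stock_dataset
        norm = normalized_profiles(table[table["feature_type"] != "peptide"])
        sums = point_means(norm).groupby(["feature_id", "condition"])["mean"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_all_zero_feature_excluded(self):
        rows = [run_row("P1", "protein", s, "end", 1, 0.0) for s in "ab"]
        rows += [run_row("P2", "protein", s, "end", 1, 1.0) for s in "ab"]
        t = make_table(rows)
        t["rel_abundance"] = t["intensity"]
        norm = normalise_timecourse(t)
        assert set(norm["feature_id"]) == {"P2"}


class TestFamilyFractions:
    def test_definitional_fractions(self):
        t = make_table([
            run_row("F|a", "peptide", "s", "end", 1, 30.0, family="F", form="a"),
            run_row("F|b", "peptide", "s", "end", 1, 70.0, family="F", form="b"),
        ])
        frac = family_fractions(t).set_index("form_id")["fraction"]
        assert frac["a"] == pytest.approx(0.3)
        assert frac["b"] == pytest.approx(0.7)

    def test_single_detected_form_is_one(self):
        t = make_table([
            run_row("F|a", "peptide", "s", "end", 1, 5.0, family="F", form="a"),
        ])
        assert family_fractions(t)["fraction"].iloc[0] == pytest.approx(1.0)

    def test_zero_family_total_flagged_nan(self):
        t = make_table([
            run_row("F|a", "peptide", "s", "end", 1, 0.0, family="F", form="a"),
            run_row("F|b", "peptide", "s", "end", 1, 0.0, family="F", form="b"),
        ])
        assert family_fractions(t)["fraction"].isna().all()

    def test_fractions_sum_to_one_on_simulated_data(self, stock_dataset):
        table, _ = stock_dataset
        frac = family_fractions(table)
        sums = frac.groupby(["family_id", "stage", "point", "replicate"])["fraction"].sum()
        assert np.allclose(sums.dropna(), 1.0, atol=1e-12)


class TestLog2FoldChange:
    def test_known_ratio_and_antisymmetry(self):
        a, b = [2.0, 2.0], [8.0, 8.0]
        assert log2_fold_change(a, b) == pytest.approx(2.0)
        assert log2_fold_change(b, a) == pytest.approx(-2.0)
        assert log2_fold_change(a, a) == 0.0

    def test_zero_mean_rejected(self):
        with pytest.raises(NormalizationError):
            log2_fold_change([0.0, 0.0], [1.0, 1.0])


class TestPipelineProperties:
    @settings(max_examples=20, deadline=None)
    @given(c=st.floats(0.01, 100.0), run_index=st.integers(0, 13))
    def test_run_scale_invariance(self, c, run_index, noiseless_dataset):
        """Scaling every intensity of one run (trypsin included) by c > 0
        leaves R, N and family fractions unchanged."""
        table, _ = noiseless_dataset
        runs = table[["condition", "stage", "point", "replicate"]].drop_duplicates()
        run = runs.iloc[run_index % len(runs)]
        mask = (
            (table["stage"] == run["stage"])
            & (table["point"] == run["point"])
            & (table["replicate"] == run["replicate"])
        )
        scaled = table.copy()
        scaled.loc[mask, "intensity"] *= c

        prot = table["feature_type"] != "peptide"
        n0 = normalized_profiles(table[prot]).sort_values(
            ["feature_id", "stage", "point", "replicate"])
        n1 = normalized_profiles(scaled[prot]).sort_values(
            ["feature_id", "stage", "point", "replicate"])
        assert np.allclose(n0["norm_abundance"], n1["norm_abundance"], rtol=1e-12)

        f0 = family_fractions(table).sort_values(
            ["feature_id", "stage", "point", "replicate"])
        f1 = family_fractions(scaled).sort_values(
            ["feature_id", "stage", "point", "replicate"])
        assert np.allclose(
            f0["fraction"].fillna(-1), f1["fraction"].fillna(-1), rtol=1e-12
        )

    def test_noiseless_pipeline_matches_analytic_profile(self):
        """With noise off, the normalized profile equals the one computed
        directly from the closed-form trajectory."""
        program = default_program()
        kin = ProteinKinetics("P_check", G0=1, S0=0.1, k_ext_ref=0.04,
                              k_den_max=0.3, T_m=75.0)
        table, _ = generate_dataset(
            program, [kin], None,
            NoiseModel(cv=0.0, run_scale_sd=0.0, n_replicates=3, seed=0),
        )
        norm = normalized_profiles(table)
        got = point_means(norm).set_index(["stage", "point"])["mean"]

        traj = simulate_timecourse(program, kin).set_index(["stage", "point"])["value"]
        expected = traj / traj.sum()
        for key, val in expected.items():
            assert got[key] == pytest.approx(val, abs=1e-9)
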