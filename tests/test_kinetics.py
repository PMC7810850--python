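"""Closed-form two-compartment kinetics vs independent numerical integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micromash import ProteinKinetics, default_program, simulate_timecourse, stage_solution
from micromash.program import MashProgram, MashStage

from conftest import rk4_final


class TestStageSolution:
    @pytest.mark.parametrize(
        "G0,S0,k_ext,k_den,t,expected_S",
        [
            (0.0, 1.0, 0.0, 2.0, 1.0, np.exp(-2.0)),       # pure decay
            (1.0, 0.0, 1.0, 2.0, 1.0, 0.23254415793482963),  # frozen: RK4-confirmed
            (1.0, 0.5, 0.3, 0.3, 2.0, (0.5 + 0.3 * 1.0 * 2.0) * np.exp(-0.6)),  # degenerate line
        ],
    )
    def test_known_values(self, G0, S0, k_ext, k_den, t, expected_S):
        _, S = stage_solution(G0, S0, k_ext, k_den, t)
        assert S == pytest.approx(expected_S, rel=1e-12)

    def test_extraction_approaches_full_transfer(self):
        # with no loss, everything ends up soluble as t grows
        _, S = stage_solution(1.0, 0.0, 1.0, 0.0, 60.0)
        assert S == pytest.approx(1.0, abs=1e-12)

    def test_mass_conservation_without_denaturation(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            G0, S0 = rng.uniform(0, 2, 2)
            a, t = rng.uniform(0, 1), rng.uniform(0, 90)
            G, S = stage_solution(G0, S0, a, 0.0, t)
            assert G + S == pytest.approx(G0 + S0, rel=1e-9)

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            stage_solution(1, 0, -0.1, 0.2, 1.0)
        with pytest.raises(ValueError):
            stage_solution(1, 0, 0.1, 0.2, -1.0)

    def test_matches_rk4_oracle_including_degenerate_line(self):
        """1,000 random draws (rates in [0,1], t in [0,90]), of which 100 sit
        within 1e-9 of the k_ext = k_den line, agree with fixed-step RK4 to
        better than 1e-6 relative."""
        rng = np.random.default_rng(1)
        n = 1000
        a = rng.uniform(0, 1, n)
        d = rng.uniform(0, 1, n)
        t = rng.uniform(0, 90, n)
        G0 = rng.uniform(0, 2, n)
        S0 = rng.uniform(0, 2, n)
        a[:100] = d[:100] + rng.uniform(-1, 1, 100) * 1e-9
        a[:10] = d[:10]
        S_closed = np.array(
            [stage_solution(G0[i], S0[i], a[i], d[i], t[i])[1] for i in range(n)]
        )
        _, S_num = rk4_final(G0, S0, a, d, t)
        rel = np.abs(S_closed - S_num) / np.maximum(
            np.maximum(np.abs(S_closed), np.abs(S_num)), 1e-12
        )
        assert rel.max() < 1e-6

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.floats(0, 1),
        eps=st.floats(-1e-13, 1e-13),
        t=st.floats(0, 90),
        G0=st.floats(0.1, 2),
        S0=st.floats(0, 2),
    )
    def test_continuity_across_degenerate_line(self, a, eps, t, G0, S0):
        """Solution is continuous in k_den through k_den = k_ext."""
        _, S_eq = stage_solution(G0, S0, a, a, t)
        _, S_near = stage_solution(G0, S0, a, max(a + eps, 0.0), t)
        assert S_near == pytest.approx(S_eq, rel=1e-6, abs=1e-12)


class TestTimecourse:
    def test_no_denaturation_gives_nondecreasing_profile(self, program):
        kin = ProteinKinetics("p", G0=1, S0=0.0, k_ext_ref=0.02, b_ext=0.0,
                              k_den_max=0.0, T_m=80, s_m=3)
        traj = simulate_timecourse(program, kin)
        main = traj[traj["point"] != "extension"].sort_values("time")
        assert (np.diff(main["value"]) >= -1e-12).all()

    def test_boil_loss_below_pre_boil_level(self, program):
        kin = ProteinKinetics("p", G0=1, S0=0.5, k_ext_ref=0.3, b_ext=0.0,
                              k_den_max=0.5, T_m=70, s_m=2)
        traj = simulate_timecourse(program, kin).set_index(["stage", "point"])
        assert traj.loc[("boil", "end"), "value"] < traj.loc[("63C", "end"), "value"]

    def test_trajectory_matches_piecewise_numeric_integration(self, program):
        """Chained closed form vs brute-force RK4 of the same piecewise ODE."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            kin = ProteinKinetics(
                "p", G0=rng.uniform(0.5, 2), S0=rng.uniform(0, 0.5),
                k_ext_ref=rng.uniform(0, 0.1), b_ext=rng.uniform(0, 0.08),
                k_den_max=rng.uniform(0, 0.5), T_m=rng.uniform(55, 100),
                s_m=rng.uniform(1, 5),
            )
            traj = simulate_timecourse(program, kin)
            # numeric: integrate stage by stage, branching for extensions
            G, S = kin.G0, kin.S0
            numeric = {}
            for stage in program.stages:
                a, d = kin.k_ext(stage.temperature), kin.k_den(stage.temperature)
                numeric[(stage.name, "start")] = S
                Ge, Se = rk4_final(G, S, a, d, stage.duration, n_steps=4000)
                numeric[(stage.name, "end")] = float(Se[0])
                if stage.extension > 0:
                    _, Sx = rk4_final(G, S, a, d, stage.duration + stage.extension,
                                      n_steps=4000)
                    numeric[(stage.name, "extension")] = float(Sx[0])
                G, S = float(Ge[0]), float(Se[0])
            for _, row in traj.iterrows():
                expect = numeric[(row["stage"], row["point"])]
                assert abs(row["value"] - expect) <= 1e-6 * max(abs(expect), 1e-12)

    def test_extension_is_counterfactual(self, program):
        """The extension branch must not alter the main trajectory."""
        kin = ProteinKinetics("p")
        no_ext = MashProgram(
            stages=tuple(
                MashStage(s.name, s.temperature, s.duration, 0.0, s.is_boil)
                for s in program.stages
            )
        )
        a = simulate_timecourse(program, kin)
        b = simulate_timecourse(no_ext, kin)
        a_main = a[a["point"] != "extension"].reset_index(drop=True)
        assert np.allclose(a_main["value"], b["value"])

    def test_empty_sampling_grid_rejected(self):
        prog = default_program()
        object.__setattr__(prog, "sample_points", ())
        kin = ProteinKinetics("p")
        with pytest.raises(ValueError):
            simulate_timecourse(prog, kin)


class TestProgramValidation:
    def test_temperature_and_duration_bounds(self):
        with pytest.raises(ValueError):
            MashStage("x", 120.0, 10.0)
        with pytest.raises(ValueError):
            MashStage("x", 60.0, 0.0)
        with pytest.raises(ValueError):
            MashStage("x", 60.0, 10.0, extension=-1.0)

    def test_needs_two_stages(self):
        with pytest.raises(ValueError):
            MashProgram(stages=(MashStage("only", 63.0, 30.0),))

    def test_default_program_grid(self, program):
        grid = program.grid()
        assert ("63C", "extension") in grid
        assert ("boil", "end") in grid
        assert program.stage("63C").duration == 35.0
        assert program.stage("boil").duration == 30.0
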