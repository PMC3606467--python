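import numpy as np
import pytest

from kneeload.distributor import SolverOptions, solve_cycle, solve_frame
from kneeload.knee_model import ConstraintSystem, Formulation
from kneeload.objectives import OBJECTIVES
from kneeload.synthetic_data import gen_trial, inconsistent_load_params
from oracles import (
    active_set_newton,
    grid_minimax,
    minimax_bisection,
    vertex_enumeration_lp,
)


def make_system(A, b, ub=5000.0, pcsa=None, n_force_rows=0):
    A = np.atleast_2d(np.asarray(A, float))
    n = A.shape[1]
    return ConstraintSystem(
        matrix_A=A, rhs_b=np.asarray(b, float),
        lower_bounds=np.zeros(n), upper_bounds=np.full(n, float(ub)),
        column_labels=tuple(f"m{i}" for i in range(n)),
        n_force_rows=n_force_rows, muscle_slice=slice(0, n),
        muscle_pcsa=np.asarray(pcsa, float) if pcsa is not None else np.ones(n),
    )


class TestWorkedToys:
    def test_single_muscle_moment_balance(self):
        # one muscle, 0.05 m moment arm about z, must supply 5 N·m
        sys_ = make_system([[0.05]], [5.0])
        sol = solve_frame(sys_, OBJECTIVES["J1"])
        assert sol.status == "optimal"
        assert sol.forces[0] == pytest.approx(100.0, abs=1e-6)

    def test_two_muscle_quadratic_kkt(self):
        # KKT of min ΣF² s.t. 0.04 F1 + 0.02 F2 = 2: forces ∝ moment arms
        sys_ = make_system([[0.04, 0.02]], [2.0])
        sol = solve_frame(sys_, OBJECTIVES["J2"])
        np.testing.assert_allclose(sol.forces, [40.0, 20.0], atol=1e-4)
        assert sol.objective_value == pytest.approx(2000.0, rel=1e-6)

    def test_two_muscle_linear_uses_larger_arm(self):
        sys_ = make_system([[0.04, 0.02]], [2.0])
        sol = solve_frame(sys_, OBJECTIVES["J1"])
        assert sol.objective_value == pytest.approx(50.0, abs=1e-6)

    def test_two_muscle_minimax_equalizes(self):
        sys_ = make_system([[0.04, 0.02]], [2.0])
        sol = solve_frame(sys_, OBJECTIVES["J4"])
        assert sol.objective_value == pytest.approx(2.0 / 0.06, abs=1e-4)
        np.testing.assert_allclose(sol.forces[0], sol.forces[1], atol=1e-4)


class TestScaleEquivariance:
    """With inactive bounds, scaling the load scales J1/J4/J5/J8 linearly
    and J2/J6 quadratically."""

    @pytest.mark.parametrize("jid, power", [
        ("J1", 1), ("J4", 1), ("J5", 1), ("J8", 1), ("J2", 2), ("J6", 2),
    ])
    def test_homogeneity(self, jid, power):
        A = np.array([[0.04, 0.02, 0.03]])
        pcsa = np.array([5.0, 10.0, 20.0])
        base = solve_frame(make_system(A, [2.0], pcsa=pcsa), OBJECTIVES[jid])
        half = solve_frame(make_system(A, [1.0], pcsa=pcsa), OBJECTIVES[jid])
        assert half.objective_value == pytest.approx(
            base.objective_value * 0.5 ** power, rel=1e-5)


class TestOracleEquivalence:
    """Solver optima match independent brute-force oracles on random
    moment-only instances with ≤ 5 structures."""

    @pytest.mark.parametrize("jid", list(OBJECTIVES))
    def test_small_random_instances(self, jid, rng):
        spec = OBJECTIVES[jid]
        for _ in range(12):
            n = int(rng.integers(3, 6))
            dirs = rng.normal(size=(3, n))
            dirs /= np.linalg.norm(dirs, axis=0)
            levs = rng.uniform(-0.05, 0.05, size=(3, n))
            A = np.column_stack(
                [np.cross(levs[:, j], dirs[:, j]) for j in range(n)])
            b = A @ rng.uniform(0, 300, size=n)        # feasible by witness
            ub = np.full(n, 5000.0)
            pcsa = rng.uniform(2, 30, size=n)
            sol = solve_frame(make_system(A, b, pcsa=pcsa), spec)
            assert sol.status == "optimal"
            w = np.ones(n) if spec.basis == "force" else 1.0 / pcsa
            if spec.form == "max":
                ref = minimax_bisection(w, A, b, ub, np.arange(n))
            elif spec.p == 1:
                ref = vertex_enumeration_lp(w.copy(), A, b, ub)
            else:
                ref, _ = active_set_newton(w, spec.p, A, b, ub, np.arange(n))
            denom = max(1e-9, abs(ref), abs(sol.objective_value))
            assert abs(sol.objective_value - ref) / denom < 1e-4


class TestInfeasible:
    def test_incompatible_rows_reported_not_raised(self):
        # same column must equal two different values -> infeasible
        sys_ = make_system([[1.0], [1.0]], [1.0, 2.0])
        sol = solve_frame(sys_, OBJECTIVES["J2"])
        assert sol.status == "infeasible"
        # least-squares closest point splits the difference
        assert sol.forces[0] == pytest.approx(1.5, abs=1e-6)
        assert np.max(np.abs(sol.residual_moment)) == pytest.approx(0.5, abs=1e-6)

    def test_inconsistent_trial_yields_infeasible_frames(self, props):
        trial = gen_trial(seed=0, n_frames=11,
                          load_params=inconsistent_load_params())
        cyc = solve_cycle(trial, Formulation("RFML"), OBJECTIVES["J2"], props)
        assert len(cyc.frames) == 11          # failures recorded, not dropped
        assert any(s == "infeasible" for s in cyc.statuses)


class TestSolveCycle:
    def test_zero_loads_give_zero_forces(self, props):
        from kneeload.synthetic_data import LoadParams, WaveformParams, gen_trial
        zero = WaveformParams()
        trial = gen_trial(seed=0, n_frames=21,
                          load_params=LoadParams(*([zero] * 6)))
        for tag in ("RM", "RML", "RFML"):
            cyc = solve_cycle(trial, Formulation(tag), OBJECTIVES["J3"], props)
            assert all(s == "optimal" for s in cyc.statuses)
            np.testing.assert_allclose(cyc.forces, 0.0, atol=1e-6)

    def test_deterministic_bit_for_bit(self, props):
        trial = gen_trial(seed=4, n_frames=16)
        a = solve_cycle(trial, Formulation("RFML"), OBJECTIVES["J6"], props)
        b = solve_cycle(trial, Formulation("RFML"), OBJECTIVES["J6"], props)
        assert np.array_equal(a.forces, b.forces)
        assert np.array_equal(a.objective_values, b.objective_values)

    def test_frame_count_preserved(self, all_cycles, default_trial):
        for cyc in all_cycles.values():
            assert len(cyc.frames) == default_trial.n_frames


class TestTieBreak:
    def test_reported_solution_is_no_larger_in_norm(self):
        """The tie-break never inflates the solution norm and keeps J optimal."""
        rng = np.random.default_rng(5)
        A = rng.normal(size=(2, 6)) * 0.05
        b = A @ rng.uniform(0, 100, size=6)
        raw = solve_frame(make_system(A, b), OBJECTIVES["J1"],
                          SolverOptions(tie_break=False))
        tb = solve_frame(make_system(A, b), OBJECTIVES["J1"],
                         SolverOptions(tie_break=True))
        assert np.linalg.norm(tb.forces) <= np.linalg.norm(raw.forces) + 1e-6
        assert tb.objective_value == pytest.approx(raw.objective_value,
                                                   rel=1e-6, abs=1e-6)
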