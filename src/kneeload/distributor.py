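"""Per-frame and per-cycle solution of the force-distribution problem.

Each gait frame poses a small constrained program: minimize one of the
criteria in :mod:`kneeload.objectives` over nonnegative, bounded structure
force magnitudes subject to the frame's equality system ``A·x = b``.  The
smooth power-sum criteria (p = 2, 3) are solved with sequential quadratic
programming (SLSQP) using analytic gradients; the linear criteria (J1, J5)
and the epigraph form of the minimax criteria (J4, J8) are linear programs
and are dispatched to a simplex/interior LP solver, which returns exact
optimal values where an SQP iteration would stall on the degenerate vertex
geometry of linear objectives.

Moment rows are divided by a characteristic lever arm (0.05 m) before
solving so force (N) and moment (N·m) rows are comparably conditioned;
reported residuals are always unscaled.  Frames are solved independently,
warm-started from the previous frame's solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .knee_model import ConstraintSystem, Formulation, MuscleProperties, DEFAULT_PCSA_CM2
from .objectives import ObjectiveSpec, evaluate_objective, epigraph_reformulate

__all__ = ["SolverOptions", "FrameSolution", "CycleSolution",
           "solve_frame", "solve_cycle"]


@dataclass(frozen=True)
class SolverOptions:
    """Numerical controls for the per-frame solves.

    Attributes
    ----------
    residual_tol : float
        A frame is "optimal" only if its unscaled equality residual satisfies
        ``‖A·x − b‖∞ ≤ residual_tol · max(1, ‖b‖∞)``.
    char_lever_arm_m : float
        Moment rows are divided by this length before solving.
    ftol, maxiter : SLSQP termination controls (ftol applies to the
        objective rescaled to order 1 by the start-point value).
    tie_break : bool
        The criteria cost only muscle variables, so ligament/contact forces
        are degenerate along internal "preload" loops (ligament tension
        balanced by joint compression) that leave both the constraints and
        the objective unchanged.  With ``tie_break=True`` a second stage
        minimizes ``‖x‖²`` subject to the constraints and
        ``J(x) ≤ J*·(1 + tie_break_rel_slack)``, reporting the optimal
        solution with the least internal co-contraction.
    """

    residual_tol: float = 1e-6
    char_lever_arm_m: float = 0.05
    ftol: float = 1e-12
    maxiter: int = 500
    tie_break: bool = True
    tie_break_rel_slack: float = 1e-9


@dataclass
class FrameSolution:
    """Solution of one frame: magnitudes, objective, status, residuals."""

    forces: np.ndarray
    objective_value: float
    status: str                      # optimal | infeasible | max_iter
    residual_moment: np.ndarray      # (3,) N·m
    residual_force: np.ndarray | None  # (3,) N, RFML only
    column_labels: tuple[str, ...] = ()

    @property
    def is_optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class CycleSolution:
    """Per-frame solutions over one time-normalized gait cycle."""

    frame_pct: np.ndarray
    frames: list[FrameSolution]
    formulation: Formulation
    objective_id: str
    column_labels: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.frames) != len(self.frame_pct):
            raise ValueError("one FrameSolution required per frame")

    @property
    def forces(self) -> np.ndarray:
        """(n_frames, n_vars) force magnitudes in N."""
        return np.vstack([f.forces for f in self.frames])

    @property
    def objective_values(self) -> np.ndarray:
        return np.array([f.objective_value for f in self.frames])

    @property
    def statuses(self) -> list[str]:
        return [f.status for f in self.frames]

    @property
    def fraction_optimal(self) -> float:
        return float(np.mean([f.is_optimal for f in self.frames]))

    def forces_of(self, label: str) -> np.ndarray:
        j = self.column_labels.index(label)
        return self.forces[:, j]


def _scale_system(system: ConstraintSystem, options: SolverOptions):
    """Return (A_scaled, b_scaled): moment rows divided by the lever-arm scale."""
    A = system.matrix_A.copy()
    b = system.rhs_b.copy()
    k = system.n_force_rows
    A[k:] /= options.char_lever_arm_m
    b[k:] /= options.char_lever_arm_m
    return A, b


def _split_residual(system: ConstraintSystem, x: np.ndarray):
    r = system.residual(x)
    if system.n_force_rows:
        return r[3:], r[:3]
    return r, None


def _status_from_residual(system: ConstraintSystem, x: np.ndarray,
                          options: SolverOptions, converged: bool) -> str:
    r = system.residual(x)
    tol = options.residual_tol * max(1.0, np.max(np.abs(system.rhs_b)))
    if np.max(np.abs(r)) <= tol:
        return "optimal" if converged else "max_iter"
    return "max_iter" if converged else "infeasible"


def _finish(system: ConstraintSystem, spec: ObjectiveSpec, x: np.ndarray,
            status: str) -> FrameSolution:
    x = np.asarray(x, dtype=float).copy()
    x[(x < 0.0) & (x > -1e-7)] = 0.0     # scrub solver round-off
    rm, rf = _split_residual(system, x)
    obj = evaluate_objective(x[system.muscle_slice], system.muscle_pcsa, spec)
    return FrameSolution(
        forces=x, objective_value=obj, status=status,
        residual_moment=rm, residual_force=rf,
        column_labels=system.column_labels,
    )


def _solve_linear(system, spec, A_s, b_s, options) -> FrameSolution | None:
    """Linear (p=1) criteria via LP; returns None if the LP reports failure."""
    n = system.n_variables
    c = np.zeros(n)
    idx = np.arange(n)[system.muscle_slice]
    if spec.basis == "stress":
        c[idx] = 1.0 / system.muscle_pcsa
    else:
        c[idx] = 1.0
    res = optimize.linprog(
        c, A_eq=A_s, b_eq=b_s,
        bounds=list(zip(system.lower_bounds, system.upper_bounds)),
        method="highs",
    )
    if not res.success:
        return None
    status = _status_from_residual(system, res.x, options, converged=True)
    return _finish(system, spec, res.x, status)


def _solve_minimax(system, spec, A_s, b_s, options) -> FrameSolution | None:
    """Minimax criteria via their epigraph linear program."""
    n = system.n_variables
    epi = epigraph_reformulate(spec, n, system.muscle_slice, system.muscle_pcsa)
    A_eq = np.hstack([A_s, np.zeros((A_s.shape[0], 1))])
    bounds = list(zip(system.lower_bounds, system.upper_bounds)) + [(0.0, None)]
    res = optimize.linprog(
        epi.c, A_ub=epi.G, b_ub=epi.h, A_eq=A_eq, b_eq=b_s,
        bounds=bounds, method="highs",
    )
    if not res.success:
        return None
    x = res.x[:n]                      # strip the auxiliary bound variable
    status = _status_from_residual(system, x, options, converged=True)
    return _finish(system, spec, x, status)


def _solve_power_sum(system, spec, A_s, b_s, options, x0, x_feas) -> FrameSolution:
    """p = 2 or 3 power-sum criteria via SLSQP with analytic gradients."""
    n = system.n_variables
    idx = np.arange(n)[system.muscle_slice]
    w = np.ones(idx.size)
    if spec.basis == "stress":
        w = 1.0 / system.muscle_pcsa
    p = spec.p

    # Rescale the objective to order 1: x_feas is equality-feasible, so the
    # optimum value is bounded by its objective and ftol acts relatively.
    def raw(x):
        return float(np.sum((w * x[idx]) ** p))

    scale = max(1.0, raw(x_feas), raw(x0))

    def fun(x):
        return raw(x) / scale

    def jac(x):
        g = np.zeros(n)
        g[idx] = p * w * (w * x[idx]) ** (p - 1) / scale
        return g

    kwargs = dict(
        jac=jac, method="SLSQP",
        bounds=list(zip(system.lower_bounds, system.upper_bounds)),
        constraints=[{"type": "eq",
                      "fun": lambda x: A_s @ x - b_s,
                      "jac": lambda x: A_s}],
        options={"ftol": options.ftol, "maxiter": options.maxiter},
    )

    # Power-sum objectives have vanishing gradients near zero muscle force,
    # so an SQP run can stagnate without discovering that cost-free
    # structures could replace muscles entirely.  The linear analog of the
    # criterion (same force/stress weights, p=1) is solved exactly as an LP
    # and finds those substitutions; its solution seeds a second SQP run.
    starts = [x0]
    n = system.n_variables
    c = np.zeros(n)
    c[idx] = w
    lp = optimize.linprog(
        c, A_eq=A_s, b_eq=b_s,
        bounds=list(zip(system.lower_bounds, system.upper_bounds)),
        method="highs",
    )
    if lp.success:
        starts.append(lp.x)

    tol = options.residual_tol * max(1.0, np.max(np.abs(system.rhs_b)))

    def rank(r):
        feasible = np.max(np.abs(system.residual(r.x))) <= tol
        return (feasible, bool(r.success), -r.fun)

    res = None
    for start in starts:
        r = optimize.minimize(fun, start, **kwargs)
        r2 = optimize.minimize(fun, r.x, **kwargs)   # polish restart
        if r2.fun <= r.fun:
            r = r2
        if res is None or rank(r) > rank(res):
            res = r
    converged = bool(res.success)
    status = _status_from_residual(system, res.x, options, converged)
    return _finish(system, spec, res.x, status)


def _tie_break_min_norm(system: ConstraintSystem, spec: ObjectiveSpec,
                        A_s, b_s, options: SolverOptions,
                        x_opt: np.ndarray) -> np.ndarray:
    """Among J-optimal points, pick the minimum-norm one.

    Minimizes ``½‖x‖²`` subject to the equality system, the bounds, and
    ``J(x) ≤ J* (1 + slack) + slack`` with ``J*`` the stage-1 optimum.
    Returns the stage-1 point unchanged if the polish step fails or worsens
    the equality residual.
    """
    n = system.n_variables
    idx = np.arange(n)[system.muscle_slice]
    w = np.ones(idx.size)
    if spec.basis == "stress":
        w = 1.0 / system.muscle_pcsa

    j_star = evaluate_objective(x_opt[idx], system.muscle_pcsa, spec)
    slack = options.tie_break_rel_slack
    j_cap = j_star * (1.0 + slack) + slack
    j_ref = max(1.0, j_star)          # normalize the cap row to order 1

    if spec.form == "max":
        # max-form cap decomposes into one linear row per muscle
        G = np.zeros((idx.size, n))
        G[np.arange(idx.size), idx] = w
        ineq = {"type": "ineq", "fun": lambda x: (j_cap - G @ x) / j_ref,
                "jac": lambda x: -G / j_ref}
    else:
        p = spec.p
        c = np.zeros(n)
        c[idx] = w

        def j_fun(x):
            return float(np.sum((w * x[idx]) ** p))

        def j_jac(x):
            g = np.zeros(n)
            g[idx] = p * w * (w * x[idx]) ** (p - 1)
            return g

        if p == 1:
            ineq = {"type": "ineq", "fun": lambda x: (j_cap - c @ x) / j_ref,
                    "jac": lambda x: -c[None, :] / j_ref}
        else:
            ineq = {"type": "ineq",
                    "fun": lambda x: np.array([(j_cap - j_fun(x)) / j_ref]),
                    "jac": lambda x: -j_jac(x)[None, :] / j_ref}

    # normalize equality rows and the norm objective to order 1
    b_ref = max(1.0, float(np.max(np.abs(b_s))))
    A_t, b_t = A_s / b_ref, b_s / b_ref
    scale = max(1.0, float(x_opt @ x_opt))
    kwargs = dict(
        jac=lambda x: x / scale,
        method="SLSQP",
        bounds=list(zip(system.lower_bounds, system.upper_bounds)),
        constraints=[{"type": "eq", "fun": lambda x: A_t @ x - b_t,
                      "jac": lambda x: A_t}, ineq],
        options={"ftol": 1e-10, "maxiter": options.maxiter},
    )
    fun = lambda x: 0.5 * (x @ x) / scale
    res = optimize.minimize(fun, x_opt, **kwargs)
    res2 = optimize.minimize(fun, res.x, **kwargs)
    if res2.fun <= res.fun:
        res = res2
    # accept the polished point only if it is verifiably at least as good:
    # feasible, within the criterion cap, and of no larger norm
    tol = options.residual_tol * max(1.0, np.max(np.abs(system.rhs_b)))
    j_new = evaluate_objective(np.clip(res.x, 0.0, None)[idx],
                               system.muscle_pcsa, spec)
    if (np.max(np.abs(system.residual(res.x))) <= tol
            and j_new <= j_star * (1.0 + 1e-6) + 1e-6
            and res.x @ res.x <= x_opt @ x_opt + 1e-9 * scale):
        return res.x
    return x_opt


def solve_frame(
    system: ConstraintSystem,
    spec: ObjectiveSpec,
    options: SolverOptions | None = None,
    x0: np.ndarray | None = None,
) -> FrameSolution:
    """Solve one frame's force-distribution problem.

    Parameters
    ----------
    system : ConstraintSystem
        Assembled equality system with bounds (see ``assemble_equipollence``).
    spec : ObjectiveSpec
        Criterion to minimize; minimax criteria are solved in epigraph form
        and the auxiliary variable is stripped from the reported forces.
    options : SolverOptions, optional
    x0 : array, optional
        Warm start (previous frame's solution); defaults to all zeros.

    Returns
    -------
    FrameSolution
        ``status="infeasible"`` frames carry the bounded least-squares
        closest point and its residual rather than being dropped.
    """
    options = options or SolverOptions()
    A_s, b_s = _scale_system(system, options)
    lb, ub = system.lower_bounds, system.upper_bounds

    # Feasibility probe: bounded least squares on the scaled system.  Its
    # solution doubles as the reported closest point for infeasible frames
    # and as the objective-rescaling reference for the SQP branch.
    probe = optimize.lsq_linear(A_s, b_s, bounds=(lb, ub),
                                tol=1e-14, method="bvls")
    x_feas = probe.x
    tol = options.residual_tol * max(1.0, np.max(np.abs(system.rhs_b)))
    if np.max(np.abs(system.residual(x_feas))) > tol:
        return _finish(system, spec, x_feas, "infeasible")

    if x0 is None:
        x0 = np.zeros(system.n_variables)
    else:
        x0 = np.clip(np.asarray(x0, dtype=float), lb, ub)

    if spec.form == "max":
        sol = _solve_minimax(system, spec, A_s, b_s, options)
    elif spec.p == 1:
        sol = _solve_linear(system, spec, A_s, b_s, options)
    else:
        sol = _solve_power_sum(system, spec, A_s, b_s, options, x0, x_feas)

    if sol is None:   # LP failed although the probe found a feasible point
        return _finish(system, spec, x_feas, "max_iter")
    if sol.is_optimal and options.tie_break:
        x_tb = _tie_break_min_norm(system, spec, A_s, b_s, options, sol.forces)
        sol = _finish(system, spec, x_tb, sol.status)
    return sol


def solve_cycle(
    trial,
    formulation: Formulation,
    spec: ObjectiveSpec,
    props: MuscleProperties | None = None,
    options: SolverOptions | None = None,
    contact_upper_bound: float = 10_000.0,
) -> CycleSolution:
    """Solve every frame of a gait trial for one formulation × criterion.

    Frames are independent problems; each is warm-started from the previous
    optimal solution.  Failed frames keep their non-optimal status in place —
    they are never dropped, so the cycle always has one solution per frame.
    """
    from .knee_model import assemble_equipollence  # local import, no cycle

    options = options or SolverOptions()
    props = props or MuscleProperties(dict(DEFAULT_PCSA_CM2))

    frames: list[FrameSolution] = []
    labels: tuple[str, ...] = ()
    x_prev = None
    for load, geometry in zip(trial.loads, trial.geometry):
        system = assemble_equipollence(
            geometry, load, formulation, props,
            contact_upper_bound=contact_upper_bound,
        )
        labels = system.column_labels
        sol = solve_frame(system, spec, options, x0=x_prev)
        frames.append(sol)
        x_prev = sol.forces if sol.is_optimal else None

    n_bad = sum(not f.is_optimal for f in frames)
    return CycleSolution(
        frame_pct=np.asarray(trial.frame_pct, dtype=float),
        frames=frames,
        formulation=formulation,
        objective_id=spec.id,
        column_labels=labels,
        metadata={
            "residual_tol": options.residual_tol,
            "n_non_optimal": n_bad,
            "seed": getattr(trial, "seed", None),
        },
    )
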