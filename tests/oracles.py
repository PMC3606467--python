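"""Independent brute-force oracles used to validate the solver.

These deliberately avoid the code paths of ``kneeload.distributor``:
linear criteria are checked by basic-solution (vertex) enumeration,
smooth power criteria by an active-set Newton iteration on the reduced KKT
system, and minimax criteria by bisection on the bound with feasibility
established by bounded least squares — plus, for tiny problems, a dense
grid over the feasible polytope's null-space parameterization.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize


def vertex_enumeration_lp(c, A, b, ub, tol=1e-9):
    """Minimize ``c·x`` s.t. ``A x = b``, ``0 ≤ x ≤ ub`` by enumerating
    basic solutions (non-basic variables at either bound)."""
    m, n = A.shape
    best = None
    for basis in itertools.combinations(range(n), m):
        B = A[:, basis]
        if abs(np.linalg.det(B)) < 1e-12:
            continue
        nonbasis = [j for j in range(n) if j not in basis]
        for corner in itertools.product((0.0, 1.0), repeat=len(nonbasis)):
            x = np.zeros(n)
            for j, t in zip(nonbasis, corner):
                x[j] = t * ub[j]
            rhs = b - A[:, nonbasis] @ x[nonbasis]
            xb = np.linalg.solve(B, rhs)
            x[list(basis)] = xb
            if np.all(x >= -tol) and np.all(x <= ub + tol):
                val = float(c @ x)
                if best is None or val < best:
                    best = val
    return best


def active_set_newton(w, p, A, b, ub, muscle_idx, tol=1e-10, max_outer=200):
    """Minimize ``Σ (w_i x_i)^p`` over muscles s.t. ``A x = b``, ``0 ≤ x ≤ ub``.

    Active-set loop on the bound constraints with a Newton solve of the
    reduced KKT system at each step (for p = 2 the KKT system is linear and
    Newton converges in one iteration).  Non-muscle variables carry zero
    cost; a vanishing-curvature floor keeps the KKT matrix invertible where
    the objective is flat.
    """
    n = A.shape[1]
    weights = np.zeros(n)
    weights[muscle_idx] = w

    def grad(x):
        g = np.zeros(n)
        g[muscle_idx] = p * w * np.maximum(w * x[muscle_idx], 0.0) ** (p - 1)
        return g

    def hess_diag(x):
        h = np.full(n, 1e-9)          # curvature floor for cost-free columns
        h[muscle_idx] = np.maximum(
            p * (p - 1) * w ** 2 * np.maximum(w * x[muscle_idx], 0.0) ** (p - 2),
            1e-9,
        )
        return h

    # start from a bounded least-squares feasible point
    x = optimize.lsq_linear(A, b, bounds=(np.zeros(n), ub), method="bvls").x

    for _ in range(max_outer):
        lower_active = {j for j in range(n) if x[j] <= 1e-11}
        upper_active = {j for j in range(n) if x[j] >= ub[j] - 1e-11}
        for _ in range(100):          # Newton iterations on the working set
            free = [j for j in range(n)
                    if j not in lower_active and j not in upper_active]
            if not free:
                break
            H = np.diag(hess_diag(x)[free])
            Af = A[:, free]
            m = A.shape[0]
            K = np.block([[H, Af.T], [Af, np.zeros((m, m))]])
            rhs = np.concatenate([-grad(x)[free], b - A @ x])
            sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
            dx = sol[:len(free)]
            alpha, hit = 1.0, None
            for k, j in enumerate(free):
                if dx[k] < -1e-15 and (0.0 - x[j]) / dx[k] < alpha:
                    alpha, hit = (0.0 - x[j]) / dx[k], (j, "lo")
                elif dx[k] > 1e-15 and (ub[j] - x[j]) / dx[k] < alpha:
                    alpha, hit = (ub[j] - x[j]) / dx[k], (j, "hi")
            for k, j in enumerate(free):
                x[j] += max(alpha, 0.0) * dx[k]
            x = np.clip(x, 0.0, ub)
            if hit is not None:
                (lower_active if hit[1] == "lo" else upper_active).add(hit[0])
            elif np.max(np.abs(dx), initial=0.0) < tol:
                break

        # multiplier check: release bound constraints with wrong-sign duals
        g = grad(x)
        free = [j for j in range(n)
                if j not in lower_active and j not in upper_active]
        if free:
            lam, *_ = np.linalg.lstsq(A[:, free].T, g[free], rcond=None)
        else:
            lam = np.zeros(A.shape[0])
        released = False
        for j in sorted(lower_active):
            if g[j] - A[:, j] @ lam < -1e-8:   # leaving 0 decreases J
                x[j] = min(1e-9, ub[j])
                released = True
        for j in sorted(upper_active):
            if g[j] - A[:, j] @ lam > 1e-8:
                x[j] = ub[j] - min(1e-9, ub[j])
                released = True
        if not released:
            break
    val = float(np.sum((w * np.maximum(x[muscle_idx], 0.0)) ** p))
    return val, x


def minimax_bisection(w, A, b, ub, muscle_idx, tol=1e-7):
    """Minimize ``max_i w_i x_i`` over muscles s.t. ``A x = b``, bounds.

    Bisection on the bound ``t``; feasibility of each trial ``t`` is decided
    by bounded least squares with muscle upper bounds clipped to ``t/w``.
    """
    n = A.shape[1]

    def feasible(t):
        hi = ub.copy().astype(float)
        hi[muscle_idx] = np.minimum(hi[muscle_idx], t / w)
        hi = np.maximum(hi, 1e-12)      # lsq_linear needs lo < hi strictly
        res = optimize.lsq_linear(A, b, bounds=(np.zeros(n), hi),
                                  method="bvls")
        return np.max(np.abs(A @ res.x - b)) <= 1e-6 * max(1.0, np.max(np.abs(b)))

    lo, hi = 0.0, float(np.max(ub[muscle_idx] * w))
    if feasible(lo):
        return 0.0
    if not feasible(hi):
        return np.inf
    while hi - lo > tol * max(1.0, hi):
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return hi


def grid_minimax(w, A, b, ub, muscle_idx, resolution=400):
    """Dense-grid minimax oracle for problems with ≤ 2 degrees of freedom.

    Parameterizes the affine solution set ``x = x_p + N z`` and scans a grid
    of ``z``, keeping points inside the bounds.
    """
    n = A.shape[1]
    x_p, *_ = np.linalg.lstsq(A, b, rcond=None)
    _, s, vt = np.linalg.svd(A)
    rank = int(np.sum(s > 1e-10 * s[0]))
    N = vt[rank:].T
    dof = N.shape[1]
    if dof == 0:
        x = x_p
        if np.any(x < -1e-9) or np.any(x > ub + 1e-9):
            return np.inf
        return float(np.max(w * x[muscle_idx]))
    # iterative grid refinement over the null-space coordinates, starting
    # from a bracket wide enough to cover the whole box
    center = np.zeros(dof)
    span = float(np.max(ub)) * np.sqrt(n)
    best = np.inf
    for _ in range(6):
        grids = [np.linspace(c - span, c + span, resolution) for c in center]
        mesh = np.meshgrid(*grids, indexing="ij")
        Z = np.stack([m.ravel() for m in mesh], axis=1)
        X = x_p[None, :] + Z @ N.T
        ok = (np.all(X >= -1e-9, axis=1)
              & np.all(X <= ub[None, :] + 1e-9, axis=1))
        if not np.any(ok):
            return np.inf
        vals = np.max(w[None, :] * X[np.ix_(ok, muscle_idx)], axis=1)
        k = int(np.argmin(vals))
        best = min(best, float(vals[k]))
        center = Z[ok][k]
        # zoom around the best point, keeping a ±10-cell window
        span = 10.0 * (2.0 * span / (resolution - 1))
    return best


def summed_force_and_moment(geometry_items, forces):
    """Loop-based equipollence oracle: Σ F·l and Σ F·(d × l), no matrices."""
    F = np.zeros(3)
    M = np.zeros(3)
    for (l, d), f in zip(geometry_items, forces):
        F = F + f * np.asarray(l, float)
        M = M + f * np.cross(np.asarray(d, float), np.asarray(l, float))
    return F, M


def cross_product_reference(a, b):
    """Component-wise cross product written out explicitly."""
    a1, a2, a3 = a
    b1, b2, b3 = b
    return np.array([a2 * b3 - a3 * b2,
                     a3 * b1 - a1 * b3,
                     a1 * b2 - a2 * b1])
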