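"""Derived quantities: unbalanced forces, ligament resultants, RMS summaries,
body-weight normalization and contact-force peak extraction.

When only moment equipollence is enforced (RM, RML) the optimized structure
forces generally violate the force balance; the *unbalanced force vector*

    e = Σ F·l  −  R

measures that violation and is the standard diagnostic for moment-only
formulations.  The *total ligament force* ``L = Σ_j F_j·l_j`` summarizes the
ligamentous contribution as a single vector in the tibia frame.  Waveform
summaries (per-axis RMS over the cycle, peak contact forces in units of body
weight) mirror how gait studies report these quantities.
"""

from __future__ import annotations

import numpy as np

from .distributor import CycleSolution, FrameSolution
from .knee_model import LineOfAction, ResultantLoad

__all__ = [
    "unbalanced_force", "total_ligament_force", "rms_over_cycle", "to_bw",
    "extract_contact_peaks", "unbalanced_force_cycle",
    "ligament_force_cycle", "contact_force_cycle",
    "DEFAULT_PEAK_WINDOWS",
]

#: (first peak, second peak, swing) windows in % gait cycle.  Walking places
#: the loading-response peak near 10% GC and the push-off peak near 40% GC;
#: stance-to-swing transition is taken at 62% GC.
DEFAULT_PEAK_WINDOWS: dict[str, tuple[float, float]] = {
    "first": (0.0, 30.0),
    "second": (30.0, 62.0),
    "swing": (62.0, 100.0),
}


def _directions_for(solution: FrameSolution,
                    geometry_set: dict[str, LineOfAction]) -> np.ndarray:
    missing = [n for n in solution.column_labels if n not in geometry_set]
    if missing:
        raise ValueError(f"geometry missing for solved structures: {missing}")
    return np.column_stack(
        [geometry_set[n].direction for n in solution.column_labels]
    )


def unbalanced_force(
    solution: FrameSolution,
    geometry_set: dict[str, LineOfAction],
    load: ResultantLoad,
) -> np.ndarray:
    """Residual of the force-equipollence equation for one frame (N).

    ``e = Σ_i F_i l_i − R`` over every variable of the solved formulation.
    For RM/RML this is the diagnostic error of moment-only optimization; for
    an optimal RFML frame it coincides with the solver's force-row residual
    and is numerically zero.
    """
    D = _directions_for(solution, geometry_set)
    return D @ solution.forces - load.force_R


def total_ligament_force(
    solution: FrameSolution,
    geometry_set: dict[str, LineOfAction],
    ligament_names: tuple[str, ...] = ("ACL", "PCL", "MCL", "LCL"),
) -> np.ndarray:
    """Vector sum of ligament force contributions, tibia frame (N).

    Raises
    ------
    ValueError
        If the solution's formulation carries no ligament variables (RM).
    """
    present = [n for n in ligament_names if n in solution.column_labels]
    if not present:
        raise ValueError(
            "solution has no ligament variables (RM formulation?); "
            "total ligament force requires RML or RFML"
        )
    L = np.zeros(3)
    for name in present:
        j = solution.column_labels.index(name)
        L += solution.forces[j] * geometry_set[name].direction
    return L


def rms_over_cycle(series: np.ndarray) -> np.ndarray:
    """Per-axis root-mean-square of a per-frame vector series.

    ``series`` is (n_frames, k); returns (k,) values
    ``sqrt(mean_t series[t, a]²)`` per axis ``a``.
    """
    s = np.atleast_2d(np.asarray(series, dtype=float))
    if s.shape[0] == 0:
        raise ValueError("RMS of an empty series is undefined")
    return np.sqrt(np.mean(s ** 2, axis=0))


def to_bw(values: np.ndarray | float, body_weight: float):
    """Convert forces in newtons to multiples of body weight (mass × g)."""
    if not body_weight > 0:
        raise ValueError(f"body weight must be positive, got {body_weight}")
    return np.asarray(values, dtype=float) / body_weight


def extract_contact_peaks(
    contact_total: np.ndarray,
    frame_pct: np.ndarray,
    windows: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Peak contact-force metrics over configurable gait-cycle windows.

    Parameters
    ----------
    contact_total : (n_frames,) array
        Sum of medial + lateral contact magnitudes (any consistent unit,
        typically BW).
    frame_pct : (n_frames,) array
        Sample locations in % gait cycle.
    windows : mapping with keys "first", "second", "swing"
        Inclusive (lo, hi) bounds in % GC; defaults to
        :data:`DEFAULT_PEAK_WINDOWS`.

    Returns
    -------
    dict with ``first_peak``, ``first_peak_pct``, ``second_peak``,
    ``second_peak_pct`` and ``swing_max``.
    """
    windows = windows or DEFAULT_PEAK_WINDOWS
    y = np.asarray(contact_total, dtype=float)
    pct = np.asarray(frame_pct, dtype=float)
    out: dict[str, float] = {}
    for key in ("first", "second", "swing"):
        lo, hi = windows[key]
        if not (0.0 <= lo < hi <= 100.0):
            raise ValueError(f"window {key}=({lo}, {hi}) outside 0–100% GC")
        mask = (pct >= lo) & (pct <= hi)
        if not np.any(mask):
            raise ValueError(f"no samples inside window {key}=({lo}, {hi})")
        i = np.argmax(y[mask])
        peak = float(y[mask][i])
        where = float(pct[mask][i])
        if key == "swing":
            out["swing_max"] = peak
        else:
            out[f"{key}_peak"] = peak
            out[f"{key}_peak_pct"] = where
    return out


# -- cycle-level conveniences -------------------------------------------------

def unbalanced_force_cycle(cycle: CycleSolution, trial) -> np.ndarray:
    """(n_frames, 3) unbalanced force vectors over a solved cycle (N)."""
    return np.vstack([
        unbalanced_force(sol, geom, load)
        for sol, geom, load in zip(cycle.frames, trial.geometry, trial.loads)
    ])


def ligament_force_cycle(cycle: CycleSolution, trial) -> np.ndarray:
    """(n_frames, 3) total ligament force vectors over a solved cycle (N)."""
    return np.vstack([
        total_ligament_force(sol, geom)
        for sol, geom in zip(cycle.frames, trial.geometry)
    ])


def contact_force_cycle(cycle: CycleSolution) -> np.ndarray:
    """(n_frames,) summed medial + lateral contact magnitude (N)."""
    return (cycle.forces_of("contact_medial")
            + cycle.forces_of("contact_lateral"))
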