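"""The eight optimization criteria used to resolve muscular redundancy.

Only muscle magnitudes enter the objective; ligament and contact variables
are cost-free.  Four criteria act on forces, four on stresses (force divided
by physiological cross-sectional area, N/cm²):

=====  ==========================  =====  ============================
J1     sum of muscle forces        J5     sum of muscle stresses
J2     sum of squared forces       J6     sum of squared stresses
J3     sum of cubed forces         J7     sum of cubed stresses
J4     maximum muscle force        J8     maximum muscle stress
=====  ==========================  =====  ============================

The minimax criteria (J4, J8) are non-smooth; :func:`epigraph_reformulate`
converts them into an equivalent smooth problem by introducing an auxiliary
bound variable ``t`` minimized subject to ``F_i ≤ t`` (or ``F_i/A_i ≤ t``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .knee_model import MuscleProperties

__all__ = ["ObjectiveSpec", "OBJECTIVES", "get_objective",
           "evaluate_objective", "objective_terms", "epigraph_reformulate",
           "EpigraphForm"]


@dataclass(frozen=True)
class ObjectiveSpec:
    """One optimization criterion.

    Attributes
    ----------
    id : str
        "J1" .. "J8".
    basis : str
        "force" or "stress".
    form : str
        "sum" (power-sum with exponent ``p``) or "max" (minimax).
    p : int
        Exponent for sum-form criteria (1, 2 or 3); 1 for minimax.
    """

    id: str
    basis: str
    form: str
    p: int = 1

    def __post_init__(self):
        if self.basis not in ("force", "stress"):
            raise ValueError(f"basis must be force|stress, got {self.basis!r}")
        if self.form not in ("sum", "max"):
            raise ValueError(f"form must be sum|max, got {self.form!r}")
        if self.form == "sum" and self.p not in (1, 2, 3):
            raise ValueError(f"sum-form exponent must be 1, 2 or 3, got {self.p}")


OBJECTIVES: dict[str, ObjectiveSpec] = {
    "J1": ObjectiveSpec("J1", "force", "sum", 1),
    "J2": ObjectiveSpec("J2", "force", "sum", 2),
    "J3": ObjectiveSpec("J3", "force", "sum", 3),
    "J4": ObjectiveSpec("J4", "force", "max"),
    "J5": ObjectiveSpec("J5", "stress", "sum", 1),
    "J6": ObjectiveSpec("J6", "stress", "sum", 2),
    "J7": ObjectiveSpec("J7", "stress", "sum", 3),
    "J8": ObjectiveSpec("J8", "stress", "max"),
}


def get_objective(objective_id: str) -> ObjectiveSpec:
    try:
        return OBJECTIVES[objective_id]
    except KeyError:
        raise KeyError(
            f"unknown objective {objective_id!r}; expected one of "
            f"{sorted(OBJECTIVES)}"
        ) from None


def _stress_weights(spec: ObjectiveSpec, pcsa: np.ndarray | None,
                    n_muscles: int) -> np.ndarray:
    """Per-muscle divisors: PCSA for stress criteria, ones for force criteria."""
    if spec.basis == "force":
        return np.ones(n_muscles)
    if pcsa is None:
        raise ValueError(f"{spec.id} is stress-based and needs muscle PCSAs")
    pcsa = np.asarray(pcsa, dtype=float)
    if pcsa.shape != (n_muscles,) or np.any(pcsa <= 0):
        raise ValueError("PCSA must be positive, one value per muscle")
    return pcsa


def objective_terms(muscle_forces: np.ndarray, spec: ObjectiveSpec,
                    pcsa: np.ndarray | None = None) -> np.ndarray:
    """Per-muscle force or stress values the criterion aggregates."""
    f = np.asarray(muscle_forces, dtype=float)
    return f / _stress_weights(spec, pcsa, f.shape[0])


def evaluate_objective(
    muscle_forces: np.ndarray,
    props: MuscleProperties | np.ndarray | None,
    spec: ObjectiveSpec,
) -> float:
    """Evaluate a criterion on a vector of muscle force magnitudes (N).

    ``props`` may be a :class:`MuscleProperties`, a bare PCSA array (cm²), or
    ``None`` for force-based criteria.
    """
    f = np.asarray(muscle_forces, dtype=float)
    if isinstance(props, MuscleProperties):
        pcsa = props.pcsa_array()[: f.shape[0]]
    else:
        pcsa = props
    terms = objective_terms(f, spec, pcsa)
    if spec.form == "max":
        return float(np.max(terms))
    return float(np.sum(terms ** spec.p))


@dataclass(frozen=True)
class EpigraphForm:
    """Smooth reformulation of a minimax criterion.

    The augmented variable vector is ``(x, t)`` with linear objective
    ``c·(x, t) = t`` and inequality rows ``G·(x, t) ≤ h`` expressing
    ``F_i / w_i ≤ t`` for every muscle.  The optimum of the augmented problem
    equals the minimax optimum, and ``t`` is stripped from reported forces.
    """

    c: np.ndarray           # (n_vars + 1,) linear objective, selects t
    G: np.ndarray           # (n_muscles, n_vars + 1) inequality matrix
    h: np.ndarray           # (n_muscles,) zeros
    n_original: int


def epigraph_reformulate(
    spec: ObjectiveSpec,
    n_vars: int,
    muscle_slice: slice = slice(0, 12),
    pcsa: np.ndarray | None = None,
) -> EpigraphForm:
    """Build the epigraph form of a minimax criterion over ``n_vars`` unknowns.

    Raises
    ------
    ValueError
        If called on a sum-form criterion.
    """
    if spec.form != "max":
        raise ValueError(f"{spec.id} is not a minimax criterion")
    muscle_idx = np.arange(n_vars)[muscle_slice]
    w = _stress_weights(spec, pcsa, muscle_idx.size)
    G = np.zeros((muscle_idx.size, n_vars + 1))
    G[np.arange(muscle_idx.size), muscle_idx] = 1.0 / w
    G[:, -1] = -1.0
    c = np.zeros(n_vars + 1)
    c[-1] = 1.0
    return EpigraphForm(c=c, G=G, h=np.zeros(muscle_idx.size), n_original=n_vars)
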