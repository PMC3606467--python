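"""Domain types for the force-bearing structures of the knee and assembly of
the per-frame equipollence constraint system.

The tibiofemoral joint is treated as a free body: the intersegmental
resultant force ``R`` (N) and moment ``M`` (N·m) at the joint center,
expressed in the tibia-embedded frame (x anterior, y superior, z right),
must be reproduced by the forces the crossing structures apply to the shank.
Each structure is a pure force generator described by a unit line of action
``l`` and a lever-arm vector ``d`` from the joint center to its point of
application, so a magnitude ``F`` contributes ``F·l`` to the force balance
and ``F·(d × l)`` to the moment balance.

Twelve muscles, four ligaments (ACL, PCL, MCL, LCL) and two tibiofemoral
contacts (medial, lateral) are modeled.  Three problem formulations are
supported:

* ``RM``   — muscles + contacts as unknowns, moment equipollence only (3 rows, 14 columns);
* ``RML``  — muscles + ligaments + contacts, moment equipollence only (3 rows, 18 columns);
* ``RFML`` — muscles + ligaments + contacts, force *and* moment equipollence
  (6 rows, 18 columns; force rows stacked above moment rows).

All direction vectors express the force applied TO the shank: muscle and
ligament directions point from the tibial attachment toward the femoral
side (tension-only), and contact "normals" point in the direction the femur
pushes the tibia (compression-only).  This convention makes every unknown
magnitude nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LineOfAction",
    "StructureSet",
    "ResultantLoad",
    "MuscleProperties",
    "Formulation",
    "ConstraintSystem",
    "GeometryError",
    "AssemblyError",
    "moment_contribution",
    "assemble_equipollence",
    "validate_frame_geometry",
    "MUSCLE_NAMES",
    "LIGAMENT_NAMES",
    "CONTACT_NAMES",
    "DEFAULT_STRUCTURES",
]

#: Canonical column order of every assembled constraint system.
MUSCLE_NAMES: tuple[str, ...] = (
    "rectus_femoris",
    "semitendinosus",
    "semimembranosus",
    "biceps_femoris_long",
    "biceps_femoris_short",
    "gastrocnemius_medial",
    "gastrocnemius_lateral",
    "vastus_intermedius",
    "vastus_medialis",
    "vastus_lateralis",
    "gluteus_maximus_itb",
    "tensor_fasciae_latae_itb",
)
LIGAMENT_NAMES: tuple[str, ...] = ("ACL", "PCL", "MCL", "LCL")
CONTACT_NAMES: tuple[str, ...] = ("contact_medial", "contact_lateral")

UNIT_NORM_TOL = 1e-9
LEVER_ARM_MAX_M = 0.5


class GeometryError(ValueError):
    """A line of action or lever arm violates its invariants."""


class AssemblyError(ValueError):
    """Formulation and available geometry/variables are inconsistent."""


def _as_vec3(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise GeometryError(f"{name} must be a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise GeometryError(f"{name} has non-finite components: {a}")
    return a


@dataclass(frozen=True)
class LineOfAction:
    """Unit force direction and lever arm of one structure, tibia frame.

    Parameters
    ----------
    direction : (3,) array-like, dimensionless
        Unit vector of the force applied to the shank.
    lever_arm : (3,) array-like, meters
        Vector from the joint center (midpoint of the inter-condylar line)
        to the structure's point of application on the shank.
    """

    direction: np.ndarray
    lever_arm: np.ndarray

    def __post_init__(self):
        d = _as_vec3(self.direction, "direction")
        r = _as_vec3(self.lever_arm, "lever_arm")
        if abs(np.linalg.norm(d) - 1.0) > UNIT_NORM_TOL:
            raise GeometryError(
                f"direction must be unit norm within {UNIT_NORM_TOL}: |{d}| = "
                f"{np.linalg.norm(d)!r}"
            )
        if np.linalg.norm(r) >= LEVER_ARM_MAX_M:
            raise GeometryError(
                f"lever arm |{r}| = {np.linalg.norm(r):.3f} m exceeds the "
                f"{LEVER_ARM_MAX_M} m sanity bound"
            )
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "lever_arm", r)


@dataclass(frozen=True)
class StructureSet:
    """Ordered naming of the modeled structures (fixed column order)."""

    muscles: tuple[str, ...] = MUSCLE_NAMES
    ligaments: tuple[str, ...] = LIGAMENT_NAMES
    contacts: tuple[str, ...] = CONTACT_NAMES

    def __post_init__(self):
        if len(self.muscles) != 12:
            raise ValueError(f"expected 12 muscles, got {len(self.muscles)}")
        if len(self.ligaments) != 4:
            raise ValueError(f"expected 4 ligaments, got {len(self.ligaments)}")
        if len(self.contacts) != 2:
            raise ValueError(f"expected 2 contacts, got {len(self.contacts)}")
        names = self.all_names
        if len(set(names)) != len(names):
            raise ValueError("structure names must be unique")

    @property
    def all_names(self) -> tuple[str, ...]:
        return tuple(self.muscles) + tuple(self.ligaments) + tuple(self.contacts)

    def kind_of(self, name: str) -> str:
        if name in self.muscles:
            return "muscle"
        if name in self.ligaments:
            return "ligament"
        if name in self.contacts:
            return "contact"
        raise KeyError(f"unknown structure {name!r}")


DEFAULT_STRUCTURES = StructureSet()


@dataclass(frozen=True)
class ResultantLoad:
    """Resultant intersegmental force (N) and moment (N·m) at the joint center.

    Components follow the tibia-embedded convention: x anterior, y superior,
    z right (lateral for a right knee).
    """

    force_R: np.ndarray
    moment_M: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "force_R", _as_vec3(self.force_R, "force_R"))
        object.__setattr__(self, "moment_M", _as_vec3(self.moment_M, "moment_M"))


@dataclass(frozen=True)
class MuscleProperties:
    """Physiological cross-sectional areas (cm²) and the force upper bound (N).

    The same upper bound is applied to muscle and ligament magnitudes; it is
    deliberately unphysiologically large (default 5000 N) so that the
    optimization itself reveals which formulations predict reasonable forces.
    """

    pcsa_cm2: dict[str, float]
    force_upper_bound: float = 5000.0

    def __post_init__(self):
        if self.force_upper_bound <= 0:
            raise ValueError("force_upper_bound must be positive")
        for name, a in self.pcsa_cm2.items():
            if not a > 0:
                raise ValueError(f"PCSA of {name!r} must be positive, got {a}")

    def pcsa_array(self, muscles: tuple[str, ...] = MUSCLE_NAMES) -> np.ndarray:
        missing = [m for m in muscles if m not in self.pcsa_cm2]
        if missing:
            raise KeyError(f"PCSA missing for muscles: {missing}")
        return np.array([self.pcsa_cm2[m] for m in muscles], dtype=float)


# Default PCSAs (cm²): a configurable table of anatomically plausible values
# for the modeled muscles; stress-based criteria only need relative areas.
DEFAULT_PCSA_CM2: dict[str, float] = {
    "rectus_femoris": 12.7,
    "semitendinosus": 5.4,
    "semimembranosus": 16.9,
    "biceps_femoris_long": 12.8,
    "biceps_femoris_short": 5.1,
    "gastrocnemius_medial": 21.1,
    "gastrocnemius_lateral": 9.7,
    "vastus_intermedius": 22.3,
    "vastus_medialis": 21.1,
    "vastus_lateralis": 30.6,
    "gluteus_maximus_itb": 10.2,
    "tensor_fasciae_latae_itb": 2.5,
}


@dataclass(frozen=True)
class Formulation:
    """One of the three problem formulations.

    ``RM``: moment rows only, muscle + contact unknowns (3×14).
    ``RML``: moment rows only, muscle + ligament + contact unknowns (3×18).
    ``RFML``: force rows stacked above moment rows, all 18 unknowns (6×18).
    """

    tag: str

    _VALID = ("RM", "RML", "RFML")

    def __post_init__(self):
        if self.tag not in self._VALID:
            raise ValueError(f"formulation tag must be one of {self._VALID}")

    @property
    def includes_ligaments(self) -> bool:
        return self.tag in ("RML", "RFML")

    @property
    def includes_force_rows(self) -> bool:
        return self.tag == "RFML"

    def variable_names(self, structures: StructureSet = DEFAULT_STRUCTURES) -> tuple[str, ...]:
        names = tuple(structures.muscles)
        if self.includes_ligaments:
            names += tuple(structures.ligaments)
        names += tuple(structures.contacts)
        return names

    @property
    def n_variables(self) -> int:
        return 18 if self.includes_ligaments else 14

    @property
    def n_constraints(self) -> int:
        return 6 if self.includes_force_rows else 3


@dataclass
class ConstraintSystem:
    """Assembled linear equality system ``A·x = b`` with bounds, one frame.

    Force rows (RFML only) hold the direction components of each structure;
    moment rows hold the components of ``d × l``.  Columns follow the fixed
    muscles → ligaments → contacts order.  ``muscle_slice`` locates the
    muscle variables for the objective functions; ``muscle_pcsa`` carries the
    PCSAs (cm²) so stress-based criteria can be evaluated without re-passing
    muscle properties.
    """

    matrix_A: np.ndarray
    rhs_b: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    column_labels: tuple[str, ...]
    n_force_rows: int
    muscle_slice: slice
    muscle_pcsa: np.ndarray | None = None
    formulation: Formulation | None = None

    @property
    def n_variables(self) -> int:
        return self.matrix_A.shape[1]

    @property
    def n_constraints(self) -> int:
        return self.matrix_A.shape[0]

    @property
    def force_rows(self) -> np.ndarray:
        return self.matrix_A[: self.n_force_rows]

    @property
    def moment_rows(self) -> np.ndarray:
        return self.matrix_A[self.n_force_rows :]

    def residual(self, x: np.ndarray) -> np.ndarray:
        """Unscaled equality residual ``A·x − b``."""
        return self.matrix_A @ np.asarray(x, dtype=float) - self.rhs_b


def moment_contribution(geometry: LineOfAction) -> np.ndarray:
    """Moment about the joint center per unit force magnitude: ``d × l`` (m).

    Parameters
    ----------
    geometry : LineOfAction
        Validated unit direction and lever arm.

    Returns
    -------
    (3,) ndarray
        Cross product of lever arm with direction, in meters (N·m per N).
    """
    return np.cross(geometry.lever_arm, geometry.direction)


def assemble_equipollence(
    geometry_set: dict[str, LineOfAction],
    load: ResultantLoad,
    formulation: Formulation,
    props: MuscleProperties,
    structures: StructureSet = DEFAULT_STRUCTURES,
    contact_upper_bound: float = 10_000.0,
) -> ConstraintSystem:
    """Build the equality system and bounds for one frame and formulation.

    Parameters
    ----------
    geometry_set : dict name -> LineOfAction
        Geometry for at least every structure the formulation requires.
    load : ResultantLoad
        Right-hand side: ``b = M`` (RM/RML) or ``b = (R, M)`` (RFML).
    formulation : Formulation
    props : MuscleProperties
        Supplies PCSAs (attached to the system for stress objectives) and the
        muscle/ligament force upper bound.
    contact_upper_bound : float, N
        Upper bound on contact magnitudes.  Contacts must absorb the summed
        compressive action of all muscles, so their bound is larger than the
        muscle/ligament bound by default.

    Raises
    ------
    AssemblyError
        If geometry for a required structure is missing.
    """
    names = formulation.variable_names(structures)
    missing = [n for n in names if n not in geometry_set]
    if missing:
        raise AssemblyError(f"geometry missing for structures: {missing}")

    n = len(names)
    directions = np.column_stack([geometry_set[n_].direction for n_ in names])
    moments = np.column_stack(
        [moment_contribution(geometry_set[n_]) for n_ in names]
    )

    if formulation.includes_force_rows:
        A = np.vstack([directions, moments])
        b = np.concatenate([load.force_R, load.moment_M])
        n_force_rows = 3
    else:
        A = moments
        b = load.moment_M.copy()
        n_force_rows = 0

    lb = np.zeros(n)
    ub = np.full(n, props.force_upper_bound)
    for j, name in enumerate(names):
        if structures.kind_of(name) == "contact":
            ub[j] = contact_upper_bound

    n_muscles = len(structures.muscles)
    return ConstraintSystem(
        matrix_A=A,
        rhs_b=b,
        lower_bounds=lb,
        upper_bounds=ub,
        column_labels=tuple(names),
        n_force_rows=n_force_rows,
        muscle_slice=slice(0, n_muscles),
        muscle_pcsa=props.pcsa_array(structures.muscles),
        formulation=formulation,
    )


def validate_frame_geometry(geometry_set: dict[str, object]) -> list[str]:
    """Report every invariant violation in a raw geometry mapping.

    Accepts either ``LineOfAction`` instances (already valid by construction)
    or ``(direction, lever_arm)`` pairs of raw arrays.  Returns a list of
    human-readable violation strings; an empty list means the frame is valid.
    """
    violations: list[str] = []
    for name, geom in geometry_set.items():
        if isinstance(geom, LineOfAction):
            continue
        direction, lever_arm = geom
        try:
            LineOfAction(direction=direction, lever_arm=lever_arm)
        except GeometryError as exc:
            violations.append(f"{name}: {exc}")
    return violations
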