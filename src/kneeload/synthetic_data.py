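"""Synthetic gait trials: resultant load waveforms, flexion angle, and
flexion-dependent structure geometry.

Real inputs to the force-distribution problem come from motion capture plus
inverse dynamics (joint resultants) and from a subject-scaled musculoskeletal
model (lines of action and lever arms).  This module generates both with the
statistical and mechanical structure the analysis assumes:

* Load waveforms are mixtures of Gaussian bumps on a 0–100% gait-cycle grid,
  giving direct, testable control of peak counts and locations.  The default
  template mimics level walking: a two-peak compressive axial force of order
  one body weight during stance with small swing values, an order-of-magnitude
  smaller anterior/posterior and medial/lateral force, a biphasic
  extensor/flexor moment and a two-peak frontal-plane moment.
* Geometry is a smooth closed-form template parameterized by the knee flexion
  angle (not a mechanism solution).  The extensors act through a common
  patellar-tendon line whose inclination decreases with flexion (extensor
  moment arm ≈ 4 cm), the iliotibial-tract pair pulls vertically at Gerdy's
  tubercle, hamstrings and gastrocnemius pull posterior-superiorly with
  ≈ 3 cm flexor arms, cruciates run posterior-superior (ACL) and
  anterior-superior (PCL) with millimeter-scale sagittal moment arms tied to
  their anterior-shear components, collaterals are near-vertical distraction
  restraints on either side of the midline, and the two contact normals
  point inferiorly (femur pushing tibia) at the medial/lateral plateau
  points.  The template is constructed so that the passive structures and
  contacts cannot generate sagittal or axial moment at zero muscle cost:
  the extensor/flexor moment always has to be bought from muscle, which is
  what makes moment-only formulations objective-sensitive while the full
  force+moment formulation stays pinned.

Sign conventions (tibia frame, right knee): x anterior, y superior,
z right/lateral.  The axial force is negative (compressive) in stance.  The
moment components are the *internal* resultant reproduced by the structures,
so the frontal-plane component is abductor (negative) in stance — the mirror
of the commonly reported external adduction moment — which loads the medial
compartment.

Trials are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .knee_model import LineOfAction, ResultantLoad

__all__ = [
    "Bump", "WaveformParams", "LoadParams", "GeometryParams", "GaitTrial",
    "DEFAULT_BODY_MASS_KG", "GRAVITY_M_S2", "REFERENCE_BW_N",
    "eval_waveform", "gen_flexion_angle", "gen_resultant_loads",
    "gen_geometry", "gen_trial", "default_load_params",
    "default_flexion_params", "inconsistent_load_params",
    "structure_template",
]

#: Cohort-mean body mass of the emulated study population.
DEFAULT_BODY_MASS_KG = 56.4
GRAVITY_M_S2 = 9.81
REFERENCE_BW_N = DEFAULT_BODY_MASS_KG * GRAVITY_M_S2


@dataclass(frozen=True)
class Bump:
    """One Gaussian bump: ``amplitude · exp(−(t − center)² / (2·width²))``."""

    amplitude: float
    center_pct: float
    width_pct: float

    def __post_init__(self):
        if not self.width_pct > 0:
            raise ValueError("bump width must be positive")
        if not 0.0 <= self.center_pct <= 100.0:
            raise ValueError("bump center must lie within 0–100% GC")


@dataclass(frozen=True)
class WaveformParams:
    """Gaussian-bump mixture for one waveform component."""

    bumps: tuple[Bump, ...] = ()
    baseline: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def eval_waveform(params: WaveformParams, grid: np.ndarray,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Evaluate a bump mixture on a % gait-cycle grid, optionally noisy."""
    t = np.asarray(grid, dtype=float)
    y = np.full_like(t, params.baseline)
    for b in params.bumps:
        y += b.amplitude * np.exp(-0.5 * ((t - b.center_pct) / b.width_pct) ** 2)
    if params.noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires a random generator")
        y = y + rng.normal(0.0, params.noise_sd, size=t.shape)
    return y


@dataclass(frozen=True)
class LoadParams:
    """Waveforms for the six resultant load components.

    Forces are in units of body weight (converted to N at generation time);
    moments are in N·m for the reference 56.4-kg subject and scale
    proportionally with body weight.
    """

    fx: WaveformParams
    fy: WaveformParams
    fz: WaveformParams
    mx: WaveformParams
    my: WaveformParams
    mz: WaveformParams

    def components(self):
        return {"fx": self.fx, "fy": self.fy, "fz": self.fz,
                "mx": self.mx, "my": self.my, "mz": self.mz}


def default_load_params(noise_sd: float = 0.0) -> LoadParams:
    """Level-walking default template (noise off for reproducibility).

    Axial force: two compressive stance peaks (≈1.1 BW near 10% GC and
    ≈1.0 BW near 40% GC) over a small compressive baseline; swing magnitudes
    stay below a quarter of the stance peak.  Shear components are an order
    of magnitude smaller.  The sagittal moment is biphasic
    (extensor ≈ +32 N·m at 15% GC, flexor ≈ −26 N·m at 48% GC); the
    frontal-plane (abductor) moment is two-peaked.
    """
    def wf(bumps, baseline=0.0):
        return WaveformParams(tuple(Bump(*b) for b in bumps), baseline, noise_sd)

    return LoadParams(
        fx=wf([(-0.12, 8.0, 5.0), (0.14, 45.0, 8.0)]),
        fy=wf([(-1.05, 10.0, 6.0), (-0.95, 40.0, 7.0)], baseline=-0.08),
        fz=wf([(-0.02, 12.0, 7.0), (-0.018, 42.0, 7.0)]),
        mx=wf([(-17.0, 12.0, 7.0), (-15.0, 42.0, 7.0)]),
        my=wf([]),
        mz=wf([(32.0, 15.0, 5.0), (-26.0, 48.0, 6.0), (-6.0, 85.0, 6.0)]),
    )


def default_flexion_params() -> WaveformParams:
    """Stance flexion wave (≈20° near 15% GC) + swing peak (≈60° near 72%)."""
    return WaveformParams(
        (Bump(17.0, 15.0, 7.0), Bump(57.0, 72.0, 9.0)), baseline=3.0
    )


def inconsistent_load_params() -> LoadParams:
    """Loads mechanically incompatible with the default geometry.

    A sustained lateral force of several body weights cannot be produced by
    the template's near-sagittal lines of action within the force bounds;
    solving such a trial exercises the infeasible-frame error path.
    """
    base = default_load_params()
    return replace(base, fz=WaveformParams((Bump(5.0, 50.0, 30.0),), baseline=2.0))


def gen_flexion_angle(params: WaveformParams | None, grid: np.ndarray,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Knee flexion angle (degrees) over the gait-cycle grid."""
    params = params or default_flexion_params()
    return eval_waveform(params, grid, rng)


def gen_resultant_loads(
    params: LoadParams | None,
    body_weight: float,
    grid: np.ndarray,
    seed: int = 0,
) -> list[ResultantLoad]:
    """Per-frame resultant loads from the waveform template.

    Force waveforms (BW) are multiplied by ``body_weight``; moment waveforms
    are scaled by ``body_weight / reference BW`` so heavier subjects carry
    proportionally larger moments.
    """
    params = params or default_load_params()
    rng = np.random.default_rng(seed)
    comps = {k: eval_waveform(p, grid, rng if p.noise_sd > 0 else None)
             for k, p in params.components().items()}
    m_scale = body_weight / REFERENCE_BW_N
    loads = []
    for i in range(len(np.asarray(grid))):
        R = body_weight * np.array([comps["fx"][i], comps["fy"][i], comps["fz"][i]])
        M = m_scale * np.array([comps["mx"][i], comps["my"][i], comps["mz"][i]])
        loads.append(ResultantLoad(force_R=R, moment_M=M))
    return loads


@dataclass(frozen=True)
class GeometryParams:
    """Knobs of the closed-form geometry template (meters, degrees)."""

    patellar_tendon_angle_ext_deg: float = 20.0   # anterior tilt at 0° flexion
    patellar_tendon_angle_drop_deg: float = 10.0  # reduction by 60° flexion
    hamstring_wrap_deg: float = 12.0              # posterior tilt at 0° flexion
    hamstring_wrap_gain_deg: float = 15.0         # extra tilt by 60° flexion
    contact_tilt_deg: float = 0.0                 # contact normal tilt from −y
    cruciate_moment_per_shear_m: float = 0.0025    # κ: sagittal arm per unit shear
    contact_z_m: float = 0.0225                   # plateau half-separation
    contact_rollback_m: float = 0.0               # posterior drift by 90° flexion
    collateral_z_m: float = 0.006                 # collateral offset from midline
    direction_jitter_sd: float = 0.0              # optional per-frame jitter


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def structure_template(flexion_deg: float,
                       params: GeometryParams | None = None
                       ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Closed-form (direction, lever arm) template at one flexion angle.

    Returns raw ``(l, d)`` arrays keyed by structure name; directions are
    normalized, lever arms are in meters from the joint center.  Valid for
    flexion in [0°, 90°].
    """
    p = params or GeometryParams()
    if not 0.0 <= flexion_deg <= 90.0:
        raise ValueError(f"flexion {flexion_deg:.1f}° outside template "
                         "validity range [0°, 90°]")
    fn = flexion_deg / 60.0          # normalized flexion, 1.0 at 60°
    f90 = flexion_deg / 90.0

    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # Extensor mechanism: the four quadriceps and the two iliotibial-tract
    # actuators deliver force to the tibia through the common patellar-tendon
    # line (distally the ITB blends into the lateral retinaculum), so every
    # extensor shares one sagittal line of action and one extensor moment
    # arm; they differ in the mediolateral offset of their effective
    # insertion, which gives each a distinct frontal-plane (varus/valgus)
    # side-effect.
    alpha = math.radians(p.patellar_tendon_angle_ext_deg
                         - p.patellar_tendon_angle_drop_deg * fn)
    l_ext = np.array([math.sin(alpha), math.cos(alpha), 0.0])
    quad_dz = {"rectus_femoris": 0.0, "vastus_intermedius": 0.0,
               "vastus_medialis": -0.016, "vastus_lateralis": 0.016}
    for name, dz in quad_dz.items():
        out[name] = (l_ext.copy(), np.array([0.035, -0.030, dz]))

    # Iliotibial-tract pair: vertical pull at Gerdy's tubercle, anterior and
    # lateral to the joint center — a weaker extensor than the patellar
    # tendon, with a frontal-plane (abductor) side-effect and no axial-twist
    # component.
    out["gluteus_maximus_itb"] = (np.array([0.0, 1.0, 0.0]),
                                  np.array([0.035, -0.030, 0.028]))
    out["tensor_fasciae_latae_itb"] = (np.array([0.0, 1.0, 0.0]),
                                       np.array([0.035, -0.030, 0.018]))

    # Hamstrings: common posterior-superior pull with per-muscle
    # mediolateral insertion offsets (ST/SM medial, biceps lateral).
    beta = math.radians(p.hamstring_wrap_deg + p.hamstring_wrap_gain_deg * fn)
    l_ham = np.array([-math.sin(beta), math.cos(beta), 0.0])
    ham_dz = {"semitendinosus": -0.006,
              "biceps_femoris_long": 0.008, "biceps_femoris_short": 0.006}
    for name, dz in ham_dz.items():
        out[name] = (l_ham.copy(), np.array([-0.022, -0.040, dz]))

    # Semimembranosus: the deep medial hamstring descends almost vertically
    # to its broad tibial insertion — a flexor through its posterior
    # insertion offset, with a medial (varus) side-effect and no axial-twist
    # component.
    out["semimembranosus"] = (_unit(np.array([-0.05, 1.0, 0.0])),
                              np.array([-0.028, -0.040, -0.022]))

    # Gastrocnemius heads: steeper posterior wrap than the hamstrings, small
    # compartment offsets.
    gamma = math.radians(p.hamstring_wrap_deg + 2.0
                         + p.hamstring_wrap_gain_deg * fn)
    l_gas = np.array([-math.sin(gamma), math.cos(gamma), 0.0])
    out["gastrocnemius_medial"] = (l_gas.copy(),
                                   np.array([-0.024, -0.026, -0.004]))
    out["gastrocnemius_lateral"] = (l_gas.copy(),
                                    np.array([-0.024, -0.026, 0.004]))

    # Cruciates: ACL posterior-superior, PCL anterior-superior; both flatten
    # somewhat with flexion.  Their sagittal moment arms are under a
    # centimeter — an order below the muscles' — ACL flexor, PCL extensor,
    # and both are tied to the anterior shear component of the ligament's
    # pull through a common ratio κ (moment per unit shear).  A lone
    # cruciate is then a usable but very expensive sagittal moment channel
    # (as moment-only formulations discover), while under force equipollence
    # any cruciate combination's net moment is pinned to the net shear it
    # carries, leaving no cost-free moment generation.
    kappa = p.cruciate_moment_per_shear_m
    th_a = math.radians(55.0 - 10.0 * fn)
    l_acl = _unit(np.array([-math.cos(th_a), math.sin(th_a), 0.0]))
    dy_a = -0.003
    out["ACL"] = (l_acl,
                  np.array([l_acl[0] * (kappa + dy_a) / l_acl[1], dy_a, 0.0]))
    th_p = math.radians(50.0 + 8.0 * fn)
    l_pcl = _unit(np.array([math.cos(th_p), math.sin(th_p), 0.0]))
    dy_p = -0.004
    out["PCL"] = (l_pcl,
                  np.array([l_pcl[0] * (kappa + dy_p) / l_pcl[1], dy_p, 0.0]))

    # Tibiofemoral contacts: femur pushes the tibia inferiorly at the plateau
    # points.  The application points sit on the plateau plane through the
    # joint center, so — like the ligaments — the contacts have near-zero
    # sagittal moment arms and the extensor/flexor moment must come from
    # muscles; an optional posterior drift emulates femoral rollback.
    tilt = math.sin(math.radians(p.contact_tilt_deg))
    xc = -p.contact_rollback_m * f90
    l_con = _unit(np.array([-tilt, -1.0, 0.0]))
    out["contact_medial"] = (l_con.copy(), np.array([xc, 0.0, -p.contact_z_m]))
    out["contact_lateral"] = (l_con.copy(), np.array([xc, 0.0, p.contact_z_m]))

    # Collaterals: near-vertical distraction restraints on either side of
    # the midline, each with a small frontal tilt (MCL toward the lateral
    # femoral attachment line, LCL toward the medial).  Sitting closer to
    # the midline than the plateau points, they are less efficient
    # frontal-moment generators than the contact split, so they engage only
    # when a frontal moment would require a negative contact force
    # (compartment lift-off); their frontal tilts make them the joint's
    # passive mediolateral shear restraints.
    out["MCL"] = (_unit(np.array([0.0, 1.0, 0.05])),
                  np.array([0.0, 0.0, -p.collateral_z_m]))
    out["LCL"] = (_unit(np.array([0.0, 1.0, -0.05])),
                  np.array([0.0, 0.0, p.collateral_z_m]))
    return out


def gen_geometry(
    flexion_deg: np.ndarray,
    geom_params: GeometryParams | None = None,
    seed: int = 0,
) -> list[dict[str, LineOfAction]]:
    """Per-frame, per-structure lines of action from the flexion template.

    With ``direction_jitter_sd > 0`` a small random rotation is applied to
    every direction (re-normalized), seeded for reproducibility.
    """
    p = geom_params or GeometryParams()
    rng = np.random.default_rng(seed)
    frames: list[dict[str, LineOfAction]] = []
    for flex in np.asarray(flexion_deg, dtype=float):
        raw = structure_template(float(flex), p)
        frame: dict[str, LineOfAction] = {}
        for name, (l, d) in raw.items():
            if p.direction_jitter_sd > 0:
                l = _unit(l + rng.normal(0.0, p.direction_jitter_sd, 3))
            frame[name] = LineOfAction(direction=l, lever_arm=d)
        frames.append(frame)
    return frames


@dataclass
class GaitTrial:
    """One time-normalized gait trial: loads, flexion, geometry, anthropometry."""

    frame_pct: np.ndarray
    loads: list[ResultantLoad]
    flexion_deg: np.ndarray
    geometry: list[dict[str, LineOfAction]]
    body_mass_kg: float
    seed: int = 0

    def __post_init__(self):
        pct = np.asarray(self.frame_pct, dtype=float)
        if pct.size < 2 or np.any(np.diff(pct) <= 0):
            raise ValueError("frame_pct must be strictly increasing")
        if pct[0] != 0.0 or pct[-1] != 100.0:
            raise ValueError("frame grid must cover 0 and 100% GC")
        if not (len(self.loads) == len(self.geometry) == pct.size
                == np.asarray(self.flexion_deg).size):
            raise ValueError("loads, flexion and geometry must share the grid")
        self.frame_pct = pct

    @property
    def body_weight(self) -> float:
        """Body weight in newtons (mass × g)."""
        return self.body_mass_kg * GRAVITY_M_S2

    @property
    def n_frames(self) -> int:
        return self.frame_pct.size


def gen_trial(
    seed: int = 0,
    n_frames: int = 101,
    body_mass_kg: float = DEFAULT_BODY_MASS_KG,
    load_params: LoadParams | None = None,
    flexion_params: WaveformParams | None = None,
    geom_params: GeometryParams | None = None,
) -> GaitTrial:
    """Bundle flexion, loads and geometry into a deterministic gait trial.

    The default trial (seed 0, 101 frames, 56.4 kg, noise off) is the study
    condition used throughout the test suite.
    """
    grid = np.linspace(0.0, 100.0, n_frames)
    rng = np.random.default_rng(seed)
    flexion_params = flexion_params or default_flexion_params()
    flexion = gen_flexion_angle(
        flexion_params, grid, rng if flexion_params.noise_sd > 0 else None
    )
    body_weight = body_mass_kg * GRAVITY_M_S2
    loads = gen_resultant_loads(load_params, body_weight, grid, seed=seed)
    geometry = gen_geometry(flexion, geom_params, seed=seed)
    return GaitTrial(
        frame_pct=grid, loads=loads, flexion_deg=flexion,
        geometry=geometry, body_mass_kg=body_mass_kg, seed=seed,
    )
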