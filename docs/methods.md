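# Methods

## The force-distribution problem

At each instant of the gait cycle, inverse dynamics yields a resultant
intersegmental force **R** (N) and moment **M** (N·m) at the knee joint
center, expressed in a tibia-embedded frame (x anterior, y superior, z
right).  The structures crossing the joint — 12 muscles, 4 ligaments (ACL,
PCL, MCL, LCL) and 2 tibiofemoral contacts — must be *equipollent* with
this load: their force vectors must sum to **R** and their moments about
the joint center to **M**.  Each structure is a pure force generator along
a unit line of action `l` applied at a lever arm `d` from the joint center,
so a magnitude `F ≥ 0` contributes `F·l` to the force balance and
`F·(d × l)` to the moment balance.  With 18 unknown magnitudes and at most
6 equations the problem is redundant, and a criterion must select a
solution.

Three formulations are posed per frame:

| tag  | unknowns                          | equality constraints |
|------|-----------------------------------|----------------------|
| RM   | muscles + contacts (14)           | moment rows (3)      |
| RML  | muscles + ligaments + contacts (18) | moment rows (3)    |
| RFML | muscles + ligaments + contacts (18) | force + moment rows (6) |

under eight criteria: sums of muscle forces to the power p ∈ {1,2,3}
(J1–J3), the maximum muscle force (J4), and the same four on muscle
*stresses* F/A with A the physiological cross-sectional area in cm²
(J5–J8).  Only muscle variables are costed; ligament and contact
magnitudes are free.  Muscles and ligaments are bounded by a deliberately
unphysiological 5000 N so that the formulations themselves, not the
bounds, decide whether predictions are physiological; contacts get a
configurable 10 000 N bound since they must absorb the summed compressive
action of every other structure.

Sign conventions make all magnitudes nonnegative: muscle and ligament
directions point from the tibial attachment toward the femoral side
(tension), contact "normals" point the way the femur pushes the tibia
(compression).  The moment reported in the loads is the *internal*
resultant reproduced by the structures; its frontal-plane component is
therefore abductor (negative) during stance — the mirror image of the
commonly plotted external knee adduction moment.

Derived diagnostics:

* **Unbalanced force** `e = Σ F·l − R`, the violation of force
  equipollence left by a moment-only solution (identically the force-row
  residual for RFML);
* **Total ligament force** `L = Σ_ligaments F·l`;
* per-axis RMS of either over the cycle, in body weight (BW = mass ×
  9.81 m/s²);
* contact-force peaks: the maxima of the summed medial + lateral contact
  magnitude inside three windows of the gait cycle, 0–30 % (loading
  response), 30–62 % (push-off) and 62–100 % (swing).  The windows are a
  reporting convention chosen around the conventional ≈10 % and ≈40 %
  peak timings and a 62 % stance–swing transition.

## Solver

Each frame is an independent convex program: minimize J(x) subject to
`A·x = b` and bounds.  Moment rows are divided by a characteristic lever
arm (0.05 m) before solving so force and moment rows are comparably
conditioned; residuals are reported unscaled, and a frame counts as
*optimal* only if its unscaled residual satisfies
`‖A·x − b‖∞ ≤ 1e-6 · max(1, ‖b‖∞)`.

Routing by criterion class:

* **J1, J5** (linear) and **J4, J8** (minimax, via the epigraph
  reformulation `min t` s.t. `F_i/w_i ≤ t`) are linear programs and are
  solved exactly with HiGHS.  A sequential-quadratic-programming iteration
  is the method of record for this problem class, but it stalls on the
  degenerate vertex geometry of linear objectives; an LP solver returns
  the exact optimal value, which the oracle-equivalence and nesting tests
  require.
* **J2, J3, J6, J7** are solved with SLSQP using analytic gradients.  The
  objective is rescaled to order 1 by its value at a feasible reference
  point (the bounded-least-squares projection of `b`), and each solve is
  polished by one restart (resetting the BFGS memory reliably tightens the
  flat tails of the cubic criteria).  Because power-sum gradients vanish
  at zero force, an SQP run started near a muscle-only solution can fail
  to discover that cost-free ligaments could take over entirely; each
  solve is therefore also seeded from the exactly-solved LP of the
  criterion's *linear analog*, and the better of the two results is kept.

**Feasibility.** Before optimizing, a bounded least-squares projection
(BVLS) of `b` onto the feasible box decides feasibility; infeasible frames
are reported with status `infeasible` and the least-squares-closest point
and its residual — never silently relaxed or dropped.

**Minimum-norm tie-break.** The criteria cost only muscles, so ligament
and contact magnitudes are degenerate along internal "preload" loops —
ligament tension balanced by joint compression changes neither the
constraints nor the objective.  An LP vertex or a warm-started SQP run
would report an arbitrary point on this optimal face, sometimes with
bound-saturated co-contraction.  The solver therefore runs a second stage:
minimize `‖x‖²` subject to the same constraints and
`J(x) ≤ J*·(1 + 1e-9)`, reporting the optimal solution with the least
internal co-contraction.  The polished point is accepted only if it is
verifiably at least as good (feasible, within the criterion cap, and of no
larger norm); otherwise the stage-1 point stands.  Reported objective
values are unaffected to within the cap's slack.

Frames are solved in cycle order with the previous optimal solution as a
warm start; all steps are deterministic, so identical inputs give
bit-identical outputs.

## Synthetic gait trials

No motion-capture inputs ship with the package; the generator produces
trials with the statistical and mechanical structure the analysis assumes.

**Loads** are Gaussian-bump mixtures on a 0–100 % gait-cycle grid —
chosen over Fourier series because peak counts, locations and widths are
individually testable parameters.  The default template models level
walking for the reference 56.4-kg subject (forces scale with body weight,
moments proportionally):

| component | default waveform |
|---|---|
| axial force Fy | −0.08 BW baseline, bumps −1.05 BW @ 10 % and −0.95 BW @ 40 % (two-peak compressive stance, quiet swing) |
| A–P force Fx | −0.12 BW @ 8 %, +0.14 BW @ 45 % |
| M–L force Fz | −0.02 BW @ 12 %, −0.018 BW @ 42 % |
| frontal moment Mx | −17 N·m @ 12 %, −15 N·m @ 42 % (two-peak abductor) |
| axial moment My | 0 |
| sagittal moment Mz | +32 N·m @ 15 %, −26 N·m @ 48 %, −6 N·m @ 85 % (biphasic extensor/flexor) |

The axial-twist moment defaults to zero: the 12-muscle, sagittal-dominant
structure set has only millimeter-scale vertical moment arms, so any My
demand would be reconstructed at hundreds of newtons of muscle force per
N·m and would dominate every other quantity.  Gaussian noise is available
on every component but defaults to zero so the default trial is a pure
function of its parameters.

**Flexion** is a bump mixture as well: a small stance wave (≈20° near
15 % GC) and a swing peak (≈60° near 72 % GC) over a 3° baseline.

**Geometry** is a smooth closed-form template in the flexion angle, not a
mechanism solution — the analysis consumes only lines of action and lever
arms.  Its structure encodes four principles, arrived at by analyzing which
geometries let the optimization produce physiologically structured
solutions:

1. *Shared tendon lines within muscle groups.*  All four quadriceps act
   through one patellar-tendon direction (inclination 20° at extension,
   decreasing with flexion; extensor moment arm ≈ 4.3 cm); the hamstrings
   share one posterior wrap (flexor arms ≈ 3 cm), the gastrocnemius heads
   a slightly steeper one.  Group members differ in the mediolateral
   offset of their insertion, i.e. in their frontal-plane side-effect, not
   in their sagittal mechanics.  Criteria then differ in *how* they
   distribute a group's load without changing the group's total, which is
   what keeps the fully constrained RFML solution insensitive to the
   criterion.
2. *No cost-free sagittal or axial moment.*  Contact points lie on the
   plateau plane through the joint center (zero sagittal arm), and each
   cruciate's sagittal moment arm is tied to the anterior component of its
   pull through a fixed ratio κ (default 2.5 mm per unit shear, ACL flexor
   / PCL extensor).  Any combination of passive structures with zero net
   shear then has exactly zero sagittal moment: the extensor/flexor moment
   must be bought from muscle.  A *lone* cruciate is still a usable —
   very expensive — moment channel, which is precisely what the
   moment-only formulations exploit, reproducing the ligament-force
   overestimation of RML.
3. *Contacts as a pure compression pair.*  The two contact normals point
   straight down at the plateau points (|z| = 22.5 mm), so the medial/
   lateral split is a free frontal-moment channel of capacity
   0.0225 m × compression, and the compression total is pinned by the
   force balance (in RFML) and only by the frontal moment (in RM/RML) —
   the mechanism behind the across-criterion contact-force variability of
   the moment-only formulations.
4. *Collaterals as distraction restraints.*  MCL and LCL run
   near-vertically with small frontal tilts at half the plateau offset
   (|z| = 6 mm): inferior frontal-moment generators that engage only when
   a frontal moment would unload a compartment (lift-off), and the
   model's passive mediolateral shear channel.

All geometry knobs (tendon angles, wrap gains, κ, plateau and collateral
offsets, optional rollback and contact tilt, direction jitter) live on
`GeometryParams`.

**What the generator does not emulate.**  No marker data, soft tissue or
skin-motion artefact; no force–length–velocity muscle physiology; no
patellofemoral joint; no trial-to-trial or subject-to-subject variability
beyond the seed; moments and forces are smooth bump mixtures rather than
measured waveforms; the geometry is a template, not a solved spatial
mechanism.  Passing tests therefore demonstrate the *mechanics of the
formulations* — feasibility, nesting, variability reduction, ligament
overestimation — on a controlled stand-in, not agreement with any real
subject.

**Default PCSAs** (cm²) are an anatomically plausible configurable table;
stress-based criteria only need relative areas.

## Numerical choices

* Equality tolerance: `1e-6 · max(1, ‖b‖∞)` on the unscaled residual
  (frame status), 1e-14 inside the BVLS feasibility probe.
* SLSQP: `ftol = 1e-12` on the rescaled objective, 500 iterations,
  warm start from the previous frame, zeros otherwise.
* Tie-break stage: `ftol = 1e-10`, criterion cap slack 1e-9 relative,
  equality rows normalized by `max(1, ‖b‖∞)`.
* Degenerate inputs: zero loads yield the zero solution; infeasible loads
  yield `infeasible` status with the closest point; duplicate or unsorted
  frames in input files are rejected or sorted with a warning.
* Tiny negative magnitudes (> −1e-7 N) from solver round-off are clipped
  to zero before residuals are recomputed.

## Known limitations

* The minimum-norm tie-break is a modeling choice, not physics: real
  joints do carry ligament preloads.  Quantities that depend on the
  degenerate face (individual ligament/contact splits in moment-only
  formulations) are tie-break-dependent, while optimal criterion values
  are not.
* With all ligaments near their shared upper bound, RML solutions sit on
  many simultaneous constraint boundaries; objective values there are
  exact but individual-structure forces can be sensitive to solver
  tolerances at the 1e-6 level.
* The geometry template is right-knee specific and valid for flexion in
  [0°, 90°].
* Contact forces are reported as the medial + lateral sum; the
  compartment split is available in the per-frame solution tables.
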