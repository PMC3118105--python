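# Methods

## Model structure

The limb is a single hinge joint of inertia `I` carrying an antagonistic
muscle pair with constant, equal moment arms `r` (flexion positive; the
dystonic deviation of interest is flexion, the dominant clinical pattern).
Each muscle is a Hill-type musculotendon: a contractile element (CE) in
series with an exponential series-elastic element (SE); no parallel elastic
element is modelled — passive joint stiffness is carried by the SE plus the
resting muscle tone, and passive damping by the joint coefficient
`b_passive`.

Per muscle the continuous states are activation `a` and CE length `l_ce`.
The CE velocity is not a state: at every instant the SE force at
`l_se = l_mt − l_ce` must equal the CE force `a·F_max·f_l·f_v`, and the Hill
force–velocity relation is inverted for the CE velocity that balances it
(the standard reduction of the Hill DAE, keeping the ODE non-stiff).  When
the demanded force–velocity factor is at or above the eccentric plateau the
CE lengthens at its cap `+v_max` — this is what lets a near-silent muscle
yield to a taut tendon.

Sub-models:

* `f_l(l_ce) = exp(−((l_ce/l_opt − 1)/w)²)`: unimodal, symmetric, 1 at the
  optimum; width `w = 0.4`.
* `f_v`: classic hyperbola `(1 + v̂)/(1 − v̂/a_h)` for shortening
  (`v̂ = v_ce/(v_max·l_opt)`, zero at `−v_max`), and for lengthening a
  slope-continuous saturating branch with plateau 1.3 × isometric —
  bounded forces under stretch.
* SE: `F = F_max·(e^{k·ε/ε₀} − 1)/(e^k − 1)` with strain
  `ε = (l_se − l_slack)/l_slack`, shape `k = 1.5`, and reference strain
  `ε₀ = 0.04` at which the tendon carries exactly `F_max`.  `ε₀` is a fixed
  model constant, not a per-muscle parameter.
* activation: first-order with `τ_act = 40 ms`, `τ_deact = 60 ms`
  (deactivation slower than activation).

## Reflex feedback

Three pathways excite each muscle's CE, each read at its own neural latency
from a per-step history buffer:

| pathway | receptor | signal | rectification |
|---|---|---|---|
| position | spindle (II) | `(l_ce − l_ce,rest)/l_opt` | lengthening only |
| velocity | spindle (Ia) | `v_ce/l_opt` | lengthening only |
| force | GTO (Ib) | `F/F_max` | none (bidirectional) |

Total drive is `u = clip(u_baseline + u_voluntary + Σ (k·signal + e), 0, 1)`
per muscle.  All gains and offsets are excitatory, including the force
pathway — the model's central *disinhibition* assumption (physiological Ib
feedback is inhibitory; here the spinal inhibitory interneuron is assumed
disabled, making the loop self-excitatory).  Offsets add downstream of the
gain, so an offset drives the muscle tonically even with silent afferents.
Reflex adaptation is deliberately absent: gains are constant across all
phases, so both external force and voluntary movement elicit reflexes.
Stretch is referenced to the resting CE length (the tonic-equilibrium
length at neutral angle), so the reference configuration is exactly neutral
at rest.

## Scenarios and protocol

A scenario transforms the reference configuration: `increased_sensitivity`
multiplies one pathway's gain in both muscles; `imbalanced_sensitivity`
multiplies it in the agonist (flexor by default) only; `imbalanced_offset`
sets the agonist's pathway offset.  Applied to each of the three pathways
this yields nine aberrant conditions plus the reference.  Every condition
runs the same 20 s protocol: 5 s constant external torque
(flexion-assisting), 5 s rest, 5 s constant voluntary drive to the agonist,
5 s rest.  The voluntary command goes to the agonist only, which makes loss
of voluntary control directly measurable.

## Integration

Fixed-step RK4 at `dt = 1 ms` (≥ 20 steps per shortest delay; a condition
simulates in well under a second).  Delays are handled by recording the six
afferent signals once per step and reading them back `τ/dt` steps in the
past, with linear interpolation for the RK4 mid-stages; before `t = 0` all
signals hold their neutral-rest values.  The integrator is deterministic —
identical inputs give bit-identical outputs — and a forward-Euler mode at
`dt = 10 µs` serves as a brute-force cross-check (the acceptance suite
requires sup-norm agreement within 1 mrad on the reference run).  A run
whose angle leaves ±3 rad or whose state becomes non-finite is flagged
`unstable` in its metadata (remaining samples hold the last stable values)
rather than raising, so unstable aberrant conditions remain reportable.

## Parameters

The two presets are representative, order-of-magnitude parameter sets for a
wrist (hand inertia, distal 30 ms latencies) and a shoulder (arm inertia,
proximal 20 ms latencies) — the literature values behind the original
simulations are not published, so these are this package's own choices,
calibrated to two documented requirements: the reference run is stable,
quiet and returns to neutral within ~2 s of each phase end, and the battery
expresses the qualitative regimes described below.  Headline values (full
set in `src/dystonia_reflex/data/presets.yaml`): wrist `F_max = 100 N`,
`l_opt = 5 cm`, `l_slack = 17 cm`, `r = 1.5 cm`, `I = 0.003 kg m²`,
`b = 0.04 N m s/rad`; shoulder `F_max = 500 N`, `l_opt = 10 cm`,
`l_slack = 30 cm`, `r = 5 cm`, `I = 0.25 kg m²`, `b = 1.5 N m s/rad`;
reference gains `k_p = 1.6`, `k_v = 0.3`, `k_f = 0.25`, resting drive
`u_baseline = 0.01`; default aberration magnitudes: gain × 8, offset 0.03
(wrist) / 0.032 (shoulder); severity sweep × 2, × 4, × 8.

Two calibration points deserve comment.  The shoulder's long series-elastic
slack is what gives its saturated co-contracted state mechanical stiffness:
at high force the tendon stretch displaces the CE onto the steep flank of
the force–length curve, so co-contraction resists external torque.  The
default gain multiplier (× 8) places the agonist's force-feedback loop gain
`k_f · m = 2` above unity: the loop self-excites, and the runaway is checked
not by the antagonist alone but by the agonist's own force–length drop as
the joint flexes — which is also why the abnormal angle grows smoothly with
the degree of imbalance instead of snapping to a limit.

## Dystonia scoring

The five clinical characteristics are qualitative; the package scores them
with explicit numeric criteria on settled windows (the final second of each
phase), all thresholds configurable and reported alongside the scores:

* **abnormal posture** — settled final-rest angle `> 0.05 rad`;
* **sustained contraction** — the *weaker* muscle's settled resting
  activation exceeds the reference's by `> 0.05` (keyed to the minimum of
  the pair so it detects co-contraction, not one-sided drive);
* **increased stiffness** — peak deviation from the condition's own resting
  posture during the settled half of the external-force phase is below
  0.5 × the reference's (deviation is measured from the condition's own
  rest so an abnormal posture is not itself mistaken for compliance);
* **worsening with activity** — the settled voluntary-phase deviation
  exceeds the reference's voluntary-phase deviation by `> 0.02 rad`;
* **loss of voluntary control** — the voluntary excursion (settled
  voluntary-phase angle minus own resting posture) is below 0.5 × the
  reference's.

On "worsening": a natural alternative — requiring the final-rest posture to
exceed the first-rest posture — cannot fire in this model class: the
aberrant conditions relax to a unique posture equilibrium within each 5 s
rest (the only state memory is the ~30 ms delay buffer), so both rests
settle at the same angle.  The criterion used here captures the clinical
observation the rubric names: during use, the dystonic limb deviates beyond
the range that normal voluntary activity produces.

With the default presets the battery reproduces the qualitative regime map:
oscillation (≥ 5 velocity zero-crossings in a 2 s window; the reference is
quiet by the same measure) without abnormal posture for increased position
or velocity sensitivity; rigidity — reduced excursion in both loaded phases
— without abnormal posture for increased force sensitivity; abnormal
posture without the other characteristics for the offset scenarios; all
five characteristics, and strictly the top total, only for imbalanced force
sensitivity, in both presets.

## Clinical analytics

Cohorts are one row per limb (the limb is the analysis unit of the
combination tables): patient id, side, limb type, one posture category per
joint, and a four-grade severity.  A limb with all joints `none` is
non-dystonic and must carry severity `none`.  The combination table maps
each dystonic limb to four indicator bits — arms: finger/wrist/elbow
flexion, shoulder adduction; legs: toe plantar flexion, the *merged* ankle
indicator (plantar flexion, inversion, or both), knee flexion, hip internal
rotation — and counts limbs per combination; limbs with no indicator set
are tallied separately, so table total + other-pattern + non-dystonic
conserves the cohort.  Containment checks that shoulder involvement implies
finger involvement and hip involvement implies ankle involvement.
Left/right symmetry is tested on the side × dystonia-present 2 × 2 table
with the exact two-sided Fisher test (sum of hypergeometric probabilities
≤ the observed table's; degenerate margins return p = 1 with a warning).
Per-patient severity is the maximum grade over the patient's dystonic
limbs.

## Synthetic cohorts

The study's raw per-limb records are unpublished, so the generator emulates
their statistical structure: each patient contributes two arms and two
legs; each limb is independently affected with a side-independent
probability solved from the reported bilateral fractions (both arms
affected in 46/77 arm-affected patients → per-side probability 0.748; legs
37/77 → 0.649); affected limbs draw a combination pattern at the published
table frequencies, with the rare postures (e.g. finger extension, knee
extension) as explicit low-probability categories so the other-pattern path
is exercised; the merged ankle indicator is realised as a concrete subtype
at the reported 73 : 11 : 16 split.  Severity is drawn per patient: the
maximal grade follows the published distribution (11.8 / 41.2 / 24.7 /
22.3 %), is assigned to one randomly chosen affected limb, and the
remaining limbs draw uniformly from the grades at or below it — so the
per-patient severity summary recovers the published distribution by
construction.  All sampling flows from one seeded generator; the same seed
gives byte-identical cohort files.

What the generator does **not** emulate: correlations between a patient's
limbs (beyond the shared severity cap), disease duration and progression,
distal-to-proximal spread as a process, demographics, and any association
between pattern and severity.  Tests that pass on synthetic cohorts
therefore validate the analysis operations and the published summary
statistics, not patient-level structure — patient-level results of the
original study (mean age, exact p-values, etc.) are out of reach by design.
Deterministic fixture cohorts that realise the published combination tables
exactly (118 arm and 113 leg records) back the exact table-reproduction
tests; their files are labelled fixtures and contain no real patient data.

## Problem sizes and numerical checks

The shipped analyses use: 20 s simulations at `dt = 1 ms` (20 001 samples),
ten conditions per preset plus a three-point severity sweep; the Euler
cross-check at `dt = 10 µs`; the Fisher test verified against exact
enumeration over all 2 × 2 tables with margins ≤ 12; synthetic-cohort
recovery at 20 000 patients (80 000 limbs), with pattern frequencies
recovered within 0.02 and severity within 3 percentage points.  Tie-breaks
and degenerate inputs: phase boundaries are half-open (`[start, end)`);
activations are clamped to [0, 1] after each step against integration
round-off; a muscle with `a·f_l` below 10⁻⁹ is given that floor when
inverting the force–velocity relation; cohort analyses of empty cohorts
return empty tables, and degenerate symmetry tables return p = 1.

## Known limitations

Single joint, constant moment arms, no parallel elastic element, no muscle
fatigue or calcium dynamics, no fusimotor (γ) modulation, no reflex
adaptation, symmetric muscle pair (real agonist/antagonist strength
asymmetries would themselves bias force feedback).  The force–length curve
is symmetric about the optimum; with both muscles fully saturated this
leaves the joint only marginally stable, which bounds how large a feedback
imbalance the model can express as a *stable* posture.  The scoring
thresholds are one defensible operationalization of a qualitative clinical
rubric; conclusions should be read at the level of the regime map, not of
individual threshold crossings.
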