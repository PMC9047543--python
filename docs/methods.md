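# Methods

This note documents the models, numerical choices, and open design
decisions behind `stsbiomech`. It is written for a reader who wants to
know exactly what the pipeline computes and what its tests do and do not
demonstrate.

## The measurement model

A sit-to-stand (STS) trial is observed as planar positions of five
landmarks — ankle, knee, hip, L5S1 (lumbosacral junction), and a
torso-end point — sampled at 30 Hz with additive i.i.d. Gaussian noise of
1.8 cm per coordinate, the landmark accuracy reported for depth-camera
body tracking against marker-based capture. The body is a quadruple
pendulum in the sagittal plane: rigid shank, thigh, pelvis and torso
links articulated at the ankle, knee, hip and L5S1, ankle fixed at the
world origin. Both legs are lumped into single shank/thigh links (the
task is bilaterally symmetric); the torso link carries the head and arms
(arms held at the sides).

Conventions, fixed everywhere: anterior is +x, vertical +y; world segment
angles are measured from the upward vertical, positive tilting anterior;
joint angles are differences of adjacent world angles, so trunk/hip
flexion is positive; joint torques are extension-positive; joint power is
torque times extension rate, so concentric extension is positive work.
The planar sagittal-vertical-axis (SVA) surrogate is the anterior offset
of the torso-end landmark from the ankle, in meters. The clinical SVA is
a radiographic C7–S1 plumbline measure; the surrogate shares its sign and
monotonicity, not its absolute value.

## Body model

Segment lengths, masses, CoM offsets and gyration radii scale
allometrically from sex, height H and mass M: length = fraction × H,
mass = fraction × M, I_com = m (gyration-fraction × length)². The
packaged fraction table (`data/anthropometry.csv`) adapts de Leva-style
sex-specific coefficients to the four-link lumping; it is a deliberate
package default, injectable as a CSV, because published planar-STS models
draw on several anthropometric sources whose exact blend is not
recoverable. Everything downstream treats the table as data, and all
tested properties are scale laws (lengths ∝ H, masses ∝ M,
inertias ∝ M·H²) that hold for any plausible table.

## Synthetic cohorts and trials

No raw recordings are distributed with the study this pipeline
implements, so the generator is a first-class, tested module that
emulates the study conditions: cohorts of 26 controls, 43 non-specific
low-back-pain (NS-LBP) and 42 spinal-deformity (SD-LBP) subjects with
demographics sampled from the published group means/SDs (age truncated at
18, BMI at 15; VAS/ODI clipped to scale and missing for all controls),
and three self-paced STS repetitions per subject.

Trial generation is kinematic, not forward-dynamic: world-angle keyframes
(seated, peak-lean near seat-off, rise, swing-back overshoot, standing)
are interpolated by minimum-jerk quintics and passed through the chain's
forward kinematics. The pipeline being tested is purely inverse, so a
muscle-driven simulator would add parameters without adding testability.
A strategy is five numbers: peak torso lean (rad), momentum scale
(dimensionless; compresses the rise in time, scaling peak velocities),
residual standing flexion (rad), swing-back amplitude (rad), and duration
(s). Group defaults encode the study's constructs — controls
0.35/1.15/0.02/0.02/1.7 s, NS-LBP 0.62/0.95/0.08/0.10/2.0 s, SD-LBP
0.88/0.75/0.20/0.16/2.3 s — ordered so lean increases and momentum
decreases from control to SD-LBP.

Two levels of variability sit on top of the group means, both free
parameters of the generator chosen once as realistic for adult cohorts:

* between subjects, habitual strategies are drawn with independent SDs
  (lean 0.10 rad, momentum 0.12, end flexion 0.05 rad, swing-back
  0.04 rad, duration 0.25 s). Independence matters structurally: if lean
  and momentum varied only through the group contrast they would be
  collinear, a single component would absorb all group signal, and no
  separate leaning construct could exist. Real cohorts vary in how far
  they lean largely independently of how vigorously they rise.
* between repetitions, 5% multiplicative jitter on the strategy
  parameters, so averaging across a subject's trials is non-degenerate.

What the generator does **not** emulate: arm or foot compensations,
out-of-plane motion, chair contact forces, marker dropout, soft-tissue
artifact, or any dependence of strategy on demographics beyond group
membership. Passing tests therefore demonstrate that the estimation and
phenotyping machinery is correct and calibrated under the stated noise
model — not that the specific clinical effect sizes would replicate on
recorded patients.

## Inverse kinematics

An unscented Kalman filter estimates the four joint angles from the ten
landmark coordinates. State: angles and angular rates under a
constant-velocity process model (white angular-acceleration spectral
density 50 rad²/s³ by default); measurement model: the chain's forward
kinematics; scaled sigma points (α = 1e-3, β = 2, κ = 0); the state is
initialized from closed-form geometric angles of the first frame. The
measurement noise should match the landmark noise scale and is floored at
1 mm so noiseless input remains well conditioned. Filter divergence (RMS
innovation above 0.25 m for more than 10 consecutive frames) raises a
numerical-failure error naming the frame. On noiseless synthetic trials
the filter recovers the generating angles to ~5e-4 rad RMS; at 1.8 cm
noise, re-projected landmarks are roughly twice as accurate as the raw
measurements.

Derivatives follow the sequential scheme: zero-phase (forward–backward)
second-order Butterworth low-pass at 5 Hz before each differentiation
stage (angles → filter → central difference → filter → difference →
filter), suppressing noise amplification per stage at the cost of
passband attenuation above ~2 Hz. Segment CoM positions, velocities and
accelerations follow from the chain rule in a forward recursion and are
expressed in three frames: world (lab axes), body (along/normal to the
segment's own axis), and joint (along/normal to the parent segment's
axis; ground for the shank).

Event segmentation, needed because the protocol gives no timestamps:
movement start is the first frame where torso angular speed exceeds 5°/s
sustained for 0.2 s; seat-off is the first subsequent frame where the hip
rises faster than 0.05 m/s; movement end is the first frame after peak
hip height where all joint speeds stay below 5°/s for 0.5 s. All
thresholds are configuration.

## Inverse dynamics and verification

Joint kinetics come from the classical Newton–Euler backward recursion
(torso → ankle): per segment, F = m·a_com + m·g plus the force from
above gives the lower-joint reaction; the Euler balance about the CoM
gives the net joint torque. Chair contact is not modelled, so torque,
power and force features are summarized from seat-off onward, where the
no-external-contact assumption holds; pre-seat-off kinetics would require
a seat force sensor. Concentric/eccentric work are trapezoidal integrals
of the positive/negative parts of power (eccentric stored negative).
Forces, torques and powers are made dimensionless by F/(Mg), τ/(MgH),
P/(Mg^{3/2}H^{1/2}).

Verification is dual-route. The same chain's equations of motion are
derived independently in Lagrangian mass-matrix form over absolute
angles; both routes agree to 1e-6 N·m on smooth motions, and statics
reduce to closed forms (upright stack: zero torques, ankle carries the
full weight; leaned torso: τ = m g c sinφ exactly). For the end-to-end
round trip, the chain is forward-integrated while PD-tracking a reference
rise — the upright chain is an unstable inverted pendulum, so open-loop
torque playback diverges; with tracking, the *total* applied torque is
known in closed form from the simulated state at every instant. Feeding
the resulting noiseless landmarks through UKF + filtering +
Newton–Euler recovers the applied torques to well under 2% of peak on a
slow deliberate rise (3 s, 0.4 rad lean), evaluated away from 0.3 s
filter edge windows. Faster motions push genuine signal past the 5 Hz
passband and the error grows to a few percent — an inherent property of
the prescribed filtering, not of the recursion. An energy audit (net
joint work vs. mechanical energy change) closes to 0.05% at dense
sampling.

## L5S1 load model

A planar equivalent-muscle model resolves the net L5S1 torque into
tissue loads. The extensor equivalent acts parallel to the torso axis at
moment arm d_m = 5 cm posterior to the joint; an abdominal-pressure force
acts at d_a = 8 cm anterior and relieves extension demand following a
Chaffin-style closed form, F_a = min(c_a·τ⁺, F_max) with c_a = 1.8 m⁻¹
and F_max = 400 N. Antagonist co-contraction is modelled as the
antagonist carrying a fixed fraction (default 0.1) of the agonist force
inside the moment balance: under extension demand
F_ext = max(0, (τ − F_a·d_a)/(d_m − cc·d_a)); under flexion demand the
abdominal flexor is the agonist, F_flex = |τ|/(d_a − cc·d_m), with the
extensor at cc·F_flex. With cc = 0 the model reduces exactly to the
classical single-muscle balance max(0, (τ − F_a·d_a)/d_m), and all
reduction and monotonicity properties are tested in that limit. The
co-contraction term exists because trunk muscle pairs are never silent,
and its side effect is structural: without it the *minimum* extensor
force is identically zero on every trial (every rise has a brief
flexion-demand instant) and the corresponding feature column would be
constant — unscalable by any ordinal method.

The total disc load is the joint reaction plus net axial muscle load
(F_ext + F_flex − F_a along the torso axis). Lumbar compression and
anterior shear resolve it along/normal to the torso axis; sacral
compression resolves it onto the pelvis axis, the planar reading of the
sacral endplate direction. Loads are reported in newtons and in body
weights.

## Feature table

59 time-series channels are summarized by their minimum and maximum over
the trial (118 features), then averaged across a subject's repetitions so
each subject is one independent row. The default roster: 8 joint-angle
channels (4 joints × joint/world frame), the SVA, 4 normalized torques, 4
normalized powers, 4 normalized L5S1 force channels, and 38 translational
CoM channels (velocity/acceleration × anterior/vertical over torso,
pelvis in world/body/joint frames, thigh in world/body, shank in world,
plus thigh joint-frame anterior velocity/acceleration). The shank's
body-frame vertical velocity is excluded by construction: the shank
pivots about the fixed ankle, so that channel is identically zero. The
roster ships as a versioned JSON (`data/channel_dictionary.json`),
validated on load (exactly 59 unique, resolvable channels) and fully
replaceable. Kinematic channels are windowed start→end, kinetic channels
seat-off→end (see above).

## Nonlinear PCA by optimal scaling

Each feature is replaced by a monotone non-decreasing transformation of
itself (ordinal scaling level), parameterized as a quadratic B-spline
with three interior knots at the quartiles of the variable. Writing Z for
the transformed data (columns centered, norm √n), the Gifi loss
‖Z − X Aᵀ‖² is minimized by alternating least squares:

1. model step — the best rank-r approximation of Z by SVD;
2. scaling step — each variable's model reconstruction is projected onto
   the convex cone of centered monotone splines (non-negative-increment
   B-spline coefficients, solved by NNLS on the cumulative basis) and
   rescaled to norm √n. Projecting onto a cone and rescaling is the exact
   minimizer over the cone ∩ sphere, so both steps lower the same loss
   and the recorded loss trace is monotonically non-increasing by
   construction, not by luck.

Transformations are initialized at the z-scored raw data, making the fit
deterministic; ties in a variable map to equal quantified values because
equal inputs share basis rows. Convergence is declared when the
normalized loss changes by less than 1e-7 (princals-like), capped at 100
iterations; non-convergence is carried as a flag, not an exception.
Loadings are standardized (the correlation between a quantified variable
and a component, |loading| ≤ 1), scores are √n-scaled left singular
vectors (orthogonal columns), VAF per component is its eigenvalue share
λ_k/p of the quantified-data correlation structure, and each component's
sign is fixed so its largest-magnitude loading is positive. When all
relations are linear the solution coincides with linear PCA to the
stated tolerance (1e-3 per component VAF in the acceptance check; in
practice ~1e-6).

Known limitation: ordinal quantification can stretch extreme
observations into high-leverage points (|z| of 6–8 on √n-normalized
columns at n ≈ 100–150). This is the familiar degeneracy of optimal
scaling and is precisely why solution stability is bootstrapped rather
than assumed; at small n the leverage noise, not factor strength, can
dominate replicate-to-replicate loading rotation.

## Retention and stability

Retention follows a permD-style permutation test: each permutation
shuffles every column's rows independently (destroying inter-variable
structure, preserving marginals), the NLPCA is refit with the same
configuration, and a component is significant when its observed VAF
exceeds the 95th percentile of its own permutation null. The null for
the first component sits well above 1/p (max-eigenvalue bias), which is
the reason a permutation null is used instead of an analytic one. The
report also carries the Kaiser rule (eigenvalue > 1 on the quantified
data), the count of salient loadings (|loading| ≥ 0.5), and an
acceleration-based scree elbow flagged advisory-only.
`select_components` returns the conservative minimum over the enabled
rules. Default 1,000 permutations; the type-I error of the procedure is
checked by simulation on pure-noise tables (~5% per component within the
binomial band).

Stability follows the linear-approximation reading: 300 balanced
bootstrap resamples (every subject appears exactly 300 times across
replicates) of the *fixed* quantified data are re-decomposed by linear
PCA; the transformations are not re-estimated per replicate. Replicate
components are matched to the reference by maximal |Tucker congruence|
under a one-to-one assignment, sign-aligned, and compared by RMS loading
difference, Tucker's φ (uncentered cosine), and Pearson's r (its centered
analogue), each summarized by the mean and non-parametric 95% CI.
Identity resamples reproduce the reference exactly (congruence 1, RMS 0),
and all metrics are invariant to component sign flips.

## Cohort statistics

One-way ANOVA with Tukey HSD on component scores and demographics;
Pearson chi-square (no continuity correction) for the sex distribution;
OLS of VAS/ODI on PC1–PC3 with age and BMI as covariates, with
variance-inflation factors per predictor. Controls carry no
patient-reported outcomes and are dropped from outcome models by the
missing-outcome rule; the two patient groups are pooled (a group
indicator is available as an optional covariate, off by default). A
summary-statistics ANOVA recovers F(2, 108) from published group
means/SDs/sizes alone — it agrees with a raw-data ANOVA exactly when fed
exact summaries, and reproduces the published age F = 54.13 within 0.3%
from the rounded printed values. Integer sex counts are reconstructed
from printed proportions by rounding n×proportion (24/13/13 males),
giving χ²(2) = 5.64 as printed.

## Problem sizes used in the checked experiments

The packaged verification experiments run at sizes chosen to make each
question statistically answerable at desk scale: the torque round trip
uses one 4.5 s motion at 30 Hz; the NLPCA linear limit uses 111 × 20
tables; the type-I calibration uses 20 independent 111 × 20 noise tables
at 200 permutations each (100 retention decisions); the end-to-end
construct recovery runs the full 111-subject default cohort with 200
permutations — the leading components' VAF sits far above the null's
95th percentile, so the retention decision is insensitive to the
permutation count. The pipeline defaults remain 1,000 permutations and
300 bootstrap replicates.

## Reproducibility

Every random stage (cohort, trials, permutations, bootstrap) takes an
explicit seed from the run configuration; there are no wall-clock
defaults. `run_pipeline` serializes every intermediate as plain CSV/JSON
and writes a manifest with a configuration hash and per-artifact
checksums; a rerun with the same configuration reproduces identical
checksums.
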