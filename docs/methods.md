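# Methods

This note documents the models, estimators, and numerical choices in
`vmtrack`, and what the synthetic-data generators do and do not emulate.

## Stimulus design

The sum-of-sines target is `Σ A_i sin(2π f_i t + φ_i)` with the 15
frequencies `f_i = m_i · 0.05 Hz`, `m_i ∈ {2,3,5,…,47}` prime.  Prime
multiples guarantee no component is an integer multiple of another, so
the waveform is non-harmonic and hard to anticipate while concentrating
all stimulus power on exact DFT bins of the 20 s fundamental period
(five periods tile the 100 s trial).  Each amplitude is
`min(positional_cap, velocity_cap / 2π f_i)`; with the default caps
(2°, 720°/s) the velocity constraint is never binding below ~57 Hz, so
every default component sits at 2°.  The per-component amplitude rule
is a package choice — only the two caps are experimentally prescribed.
Phases are drawn uniformly on [0, 2π), one per component, from a named
seed.  Single-sine probes use every other sum-of-sines frequency with
component-matched amplitudes.

## Closed-loop subject simulation

A tracking subject is a delayed, scaled integrator in a visual loop:
the commanded elbow velocity is `k` times the error between the
gain-scaled, delayed target (`G`, `Tv`) and the delayed cursor feedback
of the subject's own elbow (`Tf`), where the cursor is the elbow times
the applied feedback gain, delayed by the measured 45.8 ms display
latency.  The display latency sits on both the target and cursor paths,
so identified subject delays absorb it — fitted delay totals are
therefore comparable to values estimated from real apparatus data.
With the optional Smith predictor the subject maintains an internal
copy of its plant (an integrator over the outgoing command) and of its
feedback delay; the compensation term cancels `Tf` from the loop
exactly, so a matched-predictor subject equals a `Tf = 0` subject — the
architecture hypothesised for healthy controls.

Integration is trapezoidal on an internal grid oversampled 10× relative
to the 1 kHz recording rate.  Forward Euler at 1 kHz would leave ~0.5 %
response error at 2.35 Hz; the trapezoidal rule at 10 kHz leaves
~2×10⁻⁷, and the 0.1 ms grid represents the 45.8 ms display latency as
an exact integer number of samples.  All delays are quantised to the
internal grid (≤0.05 ms rounding).  Because every feedback lag is many
samples long, the recursion collapses into block cumulative sums, so a
100 s trial simulates in well under a second; a scalar implicit solver
covers the zero-lag corner case.  Motor noise is an additive white
perturbation of the commanded velocity with intensity in deg·s^(−1/2)
(the elbow acquires a random walk with sd `noise·√t`); no noise model
is experimentally prescribed, and tests mostly inject noise at the
phasor level instead.  A runaway guard aborts unstable loops (a delayed
integrator destabilises near `k·Tf ≈ π/2`).

`closed_loop_fr` evaluates the loop's continuous-time frequency
response using the same quantised delays; the simulation and the
formula agree to the integrator's discretisation floor, which is the
oracle-equivalence check in the test suite.

Subjects exposed to a manipulated cursor gain `g` are modelled as
partially compensating: `adapted_subject` sets `k' = k/g` and
`G' = G·g^(1−c)` with compensation exponent `c = 0.6`, which rescales
the closed-loop response by exactly `g^(−c)` at every frequency.  This
reproduces the observed behaviour — scaling factors near 1.2 under a
1.35 gain and near 0.8 under 0.65, with fitted `k` decreasing and `G`
increasing at high gain (and the reverse at low gain) while delays stay
put.

## Frequency-response estimation

The first 20 s of each trial (one fundamental period) are discarded as
transient.  In sum-of-sines mode the elbow series are averaged across
trials per time instant, honouring per-sample validity masks (samples
masked in every trial are linearly interpolated); single-sine mode
processes trials individually with no averaging or masking, averaging
per-trial phasors at the end.  Phasors are complex amplitude ratios at
the stimulated frequencies.  Rather than subtracting a separately
fitted trend line before the DFT, the linear trend is folded into a
joint harmonic regression (intercept, slope, and one sine/cosine pair
per stimulated frequency).  On an integer number of fundamental periods
the sinusoid basis coincides with the DFT bins, while the joint fit is
exactly invariant to added linear trends; a subtract-then-DFT pipeline
leaks ~10⁻³ of the trend-fit into every bin, which would swamp
noiseless synthetic checks (it is harmless at empirical noise levels).
Off-bin frequencies are rejected by name.  Phase lags are reported
clockwise in [0, 360).

Derived quantities: tracking error `|phasor − 1|` per frequency with an
aggregate over the five lowest frequencies; position relative to the
effort/error circle (radius 0.5 at +0.5, the locus of error-minimising
gains given a phase lag), with a configurable on-circle tolerance
(10⁻⁶ default, suited to synthetic data); the scaling factor
`s = Σ Re(conj(p)·v) / Σ |p|²` over the five lowest frequencies (the
closed-form least-squares alignment of condition phasors `p` with
veridical phasors `v`; phase is untouched by construction); and
unit phase-lag vectors with circular means via vector sums.

## Crossover-model fitting and selection

The joint patient+control model has eight parameters; a structure yokes
gains with gains and delays with delays (all 15 × 15 set partitions,
each delay class optionally pinned to zero, ~1400 distinct structures
after canonicalisation) plus named degenerate families (pure gain,
delayed gain, open-loop integrator).  Fitting minimises the summed
squared complex-difference moduli over the 15 frequencies and both
cohorts (unweighted, which is the natural reading of the fit criterion)
with Nelder–Mead from random restarts: log-uniform `k ∈ [0.1, 20]`,
uniform `G ∈ [0, 1.5]`, uniform delays `∈ [0, 0.5] s`; positivity is
enforced by an absolute-value reparameterisation; simplex tolerances
are 10⁻⁸.  One hundred restarts is the reference setting; twenty
suffice for four-parameter structures on cohort-averaged data and are
used in the faster checks.

Leave-one-out evaluation fits each structure on the average of all but
one subject pair and scores it on the held-out pair; the per-fold
parameter sets form an `n_pairs × 8` matrix whose residual (columns
minus their means) largest singular value gauges consistency.  The
matrix deliberately mixes units (1/s and s) with no rescaling, so
selection behaviour matches the published procedure.  Structures are
then ranked on the (leave-one-out error, consistency) Pareto front,
tie-broken toward fewer free parameters, with "lowest error" / "lowest
variance" labels per free-parameter stratum.  Bootstrap confidence
intervals resample subject *pairs* with replacement (patient and
control move together) and take percentile intervals over refits.

Time-domain validation simulates the fitted loop (display latency
excluded, since fitted delays absorb it; a flag restores it) against
cohort-mean elbow series, scoring the mean squared difference over the
final 80 s at 1 ms resolution, summed over cohorts.

## Smith-predictor equivalences

With the controller-plant cascade lumped as `C·P = k/s` (the split is
not separately identifiable and only the product matters), the full
diagram response is
`H = G e^(−sT) CP / (1 + CP̂(1 − e^(−sT̂)) + CP e^(−sT))`, with a single
shared visual delay on the reference and feedback paths as drawn in the
generic sensorimotor loop.  A matched predictor (`P̂ = P`, `T̂ = T`)
cancels the denominator delay terms, leaving the delay-free-feedback
(control-subject) structure; removing the predictor leaves the
delayed-feedback (patient) structure.  Both identities are exact in
floating point and are verified over the 15 stimulated frequencies and
property-swept over `k`, delay, gain; mismatched copies break the
identity measurably (a 10 ms delay-copy error exceeds 10⁻³ modulus
difference at 2.35 Hz), which is the diagnostic value of the check.

## Reaching, dysmetria, and PEST

The discrete-reach simulator drives a second-order elbow plant
(`J θ̈ = τ − b θ̇`, J = 0.2, b = 0.4, angles in degrees) through a 30°
flexion along a minimum-jerk plan (0.7 s).  The feedforward command is
computed from the subject's *internal* inertia estimate `Ĵ`: with
damping compensated, the noise-free trajectory scales as `(Ĵ/J)·plan`,
so `Ĵ/J > 1` overdrives the plant (hypermetric) and `Ĵ/J < 1`
underdrives it (hypometric) — the templates use ±20 % mismatch.  A
delayed visual position correction (`kp = 2`, latency 120 ms) acts on
the *displayed cursor* and ramps in over the deceleration phase of the
plan (50–80 % of movement time): the launch is ballistic, so
internal-model errors are expressed as dysmetria rather than servoed
away, while braking is visually regulated — which is exactly the
pathway through which acceleration-dependent cursor feedback acts.
This gating is a modelling choice; only the sign conventions (inertia
overestimate → hypermetric; increasing `ka` → increasing first
correction) are empirically constrained, and both were verified over
the full `ka ∈ [−0.02, 0.02]` range.  The corrective gain is
deliberately weak: the cursor term `ka·accel` re-enters the torque with
gain `kp·ka`, and values of `kp` much above ~4 destabilise the loop at
the gain clamp `|ka| = 0.02` (the same conflict that made real subjects
pause mid-reach at high gains).  A consequence of the weak loop is that
the dose-response of hypermetric reachers is shallow on the negative-
`ka` side — their early stall leaves the delayed brake little time to
act — so the staircase identifies the correct direction for them
without always reaching the on-target band.

The displayed cursor is `elbow + ka·â` where `â` is the causal online
estimator used in the real-time display: a second difference followed
by a trailing 100-sample moving average, whose group delay at 1 kHz is
`(W−1)/2 = 49.5 ms` (computed from the filter's phase slope); the
start of the series assumes zero acceleration.

The angle of first correction is the elbow excursion where the signed
velocity first returns to (near) zero after the peak; the default
detection band (15 % of peak speed) also scores undershoots whose
velocity brushes zero before a corrective push, at the cost of reading
a consistent few tenths of a degree below the apex of a reversing
reach.  Ratios to the 30° goal classify reaches (hypometric < 0.97,
hypermetric > 1.03).  Block modes break ties toward on-target, then
toward the previous staircase direction.

The PEST staircase starts at `ka = 0` with step 0.01, decreases the
gain on hypermetric block modes and increases it on hypometric ones,
and follows the classical sequential-testing step rules: halve on
reversal, hold on the second same-direction step, double from the
third onward except immediately after a reversal that followed a
doubled step.  Steps are clipped to [0.0035, 0.01] and the gain to
±0.02; termination requires two on-target blocks at the same gain, or
a block budget (default 40, standing in for the experiment's
time/fatigue stop) with a best-so-far fallback (the block median ratio
closest to 1).  The nine-gain sweep (0, ±0.005, ±0.01, ±0.015, ±0.02,
applied in the experimental order) reports median first corrections
per gain; its monotone non-decreasing trend is checked on the matched
(control-like) reacher, which is the population that performed it.

## What the synthetic data does and does not capture

The generators share the real experiments' structure — loop wiring,
delays, gain conditions, trial lengths, sampling, classification
thresholds, staircase rules — so estimator and selection code paths are
exercised end to end with known ground truth.  They do not emulate:
non-stationary human behaviour (fatigue, learning, attention lapses),
within-subject parameter drift, the oscillations real patients show
after the first correction, multi-joint dynamics, or realistic
measurement artifacts (the mask mechanism is exercised with synthetic
gaps).  Passing tests therefore demonstrate correctness of the
analysis machinery and internal consistency of the models, not
validity of the models for any particular patient.

## Problem sizes in tests and the acceptance script

Unit tests use 40 s trials (one retained fundamental period), cohorts
of 3–5 pairs, 3–10 optimizer restarts, and bootstrap draws of 4–8.
The acceptance checks use the full study geometry where it matters:
100 s trials, 11-pair cohorts with phasor noise sd 0.05, 20 restarts,
20 recovery seeds, and five candidate structures in the selection
check.  The reference settings (100 restarts, B = 1000 bootstrap) are
the library defaults.
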