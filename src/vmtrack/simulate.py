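"""Synthetic closed-loop subjects.

Tracking subjects are modelled as delayed, scaled integrators closing a
visual feedback loop (the crossover-model structure): the commanded elbow
velocity is ``k`` times the perceived error between the (gain-scaled,
delayed) target and the (delayed) cursor feedback of the subject's own
elbow.  An optional Smith predictor gives the subject an internal copy of
its plant and self-feedback delay, cancelling the feedback delay from the
loop — the structure identified for healthy controls.

Discrete reaches are produced by a second-order elbow plant driven by a
feedforward command computed from a possibly *mismatched* internal inertia
model (the mechanism proposed for cerebellar dysmetria) plus a delayed
visual corrective loop acting on the displayed cursor, which may carry
acceleration-dependent feedback.

Numerical scheme
----------------
The tracking loop is integrated with the trapezoidal rule on an internal
grid oversampled relative to the 1 kHz recording rate (10x by default, so
0.1 ms resolution).  This keeps the discretisation error of the loop
frequency response near 2e-7 at the highest stimulated frequency and makes
the measured 45.8 ms display latency an exact integer number of internal
samples.  All delays are quantised to internal samples.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .stimulus import TargetTrajectory
from .reach import ReachTrial, estimate_filtered_acceleration

__all__ = [
    "SubjectParams",
    "LoopConfig",
    "TrialRecord",
    "ReacherParams",
    "LoopUnstableError",
    "simulate_tracking",
    "closed_loop_fr",
    "simulate_reach",
    "make_cohort",
    "PATIENT_TEMPLATE",
    "CONTROL_TEMPLATE",
]


class LoopUnstableError(RuntimeError):
    """The closed loop ran away (elbow exceeded the runaway bound)."""


@dataclass(frozen=True)
class SubjectParams:
    """Crossover-model subject parameters.

    Parameters
    ----------
    k : float
        Controller/plant lumped integrator gain, 1/s.
    visual_gain : float
        Fraction of the target magnitude the subject attempts to
        reproduce (dimensionless, typically ~0.4 for this task).
    visual_delay : float
        Latency on the visual measurement of target motion, s.
    feedback_delay : float
        Latency on self-movement (cursor) feedback, s.
    motor_noise_sd : float
        Intensity of additive white noise on the commanded velocity,
        deg/sqrt(s); the resulting elbow noise is a random walk with
        standard deviation ``motor_noise_sd * sqrt(t)``.
    use_smith_predictor : bool
        If True the subject runs an internal plant copy and delay buffer
        that cancel ``feedback_delay`` from the loop (the control-like
        architecture); the effective loop then matches a subject with
        zero feedback delay.
    """

    k: float = 2.7
    visual_gain: float = 0.39
    visual_delay: float = 0.141
    feedback_delay: float = 0.0
    group_label: str = "control"
    motor_noise_sd: float = 0.0
    use_smith_predictor: bool = False

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.visual_gain < 0:
            raise ValueError("visual_gain must be non-negative")
        if self.visual_delay < 0 or self.feedback_delay < 0:
            raise ValueError("delays must be non-negative")


#: Patient-like and control-like templates (identified crossover-model
#: values for the veridical-feedback condition).
PATIENT_TEMPLATE = SubjectParams(
    k=2.7, visual_gain=0.39, visual_delay=0.210, feedback_delay=0.141,
    group_label="patient",
)
CONTROL_TEMPLATE = SubjectParams(
    k=2.7, visual_gain=0.39, visual_delay=0.141, feedback_delay=0.0,
    group_label="control",
)


@dataclass(frozen=True)
class LoopConfig:
    """Configuration of the experimental loop around the subject.

    ``display_delay`` is the measured latency of the projection system
    (0.0458 s); it delays both the displayed target and the displayed
    cursor, so identified subject delays absorb it.  ``oversample``
    multiplies the recording rate to form the internal integration grid.
    """

    applied_feedback_gain: float = 1.0
    display_delay: float = 0.0458
    sample_rate: float = 1000.0
    oversample: int = 10
    n_trials: int = 5
    seed: int | None = None
    runaway_bound: float = 1e4

    def __post_init__(self) -> None:
        if self.applied_feedback_gain <= 0:
            raise ValueError("applied_feedback_gain must be positive")
        if self.display_delay < 0:
            raise ValueError("display_delay must be non-negative")
        if self.oversample < 1:
            raise ValueError("oversample must be >= 1")

    @property
    def internal_rate(self) -> float:
        return self.sample_rate * self.oversample


@dataclass
class TrialRecord:
    """One recorded tracking trial at the 1 kHz recording rate.

    ``cursor`` is the displayed elbow angle: the applied feedback gain
    times the elbow, delayed by the display latency.  ``mask`` flags
    per-sample validity (True = keep); simulated trials are fully valid.
    """

    time: np.ndarray
    target: np.ndarray
    elbow: np.ndarray
    cursor: np.ndarray
    metadata: dict = field(default_factory=dict)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("target", "elbow", "cursor"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match time")
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        elif len(self.mask) != n:
            raise ValueError("mask length does not match time")

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


def _delay_samples(delay_s: float, rate: float) -> int:
    return int(round(delay_s * rate))


def _simulate_loop(
    subject: SubjectParams,
    trajectory: TargetTrajectory,
    loop: LoopConfig,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the closed loop on the internal grid.

    Returns internal-rate elbow and predictor-free elbow arrays
    (``elbow``, length N+1 including the initial sample).
    """
    rate = loop.internal_rate
    dt = 1.0 / rate
    n_out = len(trajectory.time)
    n = n_out * loop.oversample
    g = loop.applied_feedback_gain
    k = subject.k

    d_disp = _delay_samples(loop.display_delay, rate)
    dv = _delay_samples(loop.display_delay + subject.visual_delay, rate)
    df = _delay_samples(loop.display_delay + subject.feedback_delay, rate)
    d_hat = _delay_samples(subject.feedback_delay, rate)
    smith = subject.use_smith_predictor

    # Perceived target drive, evaluated analytically on the delayed grid
    # (the sinusoids extend to t < 0, giving a steady-state input).
    t_int = (np.arange(n + 1) - dv) * dt
    drive = subject.visual_gain * trajectory.evaluate(t_int)

    # Motor noise: random-walk increments on the elbow.
    if subject.motor_noise_sd > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        w = subject.motor_noise_sd * np.sqrt(dt) * rng.standard_normal(n)
        walk = np.concatenate([[0.0], np.cumsum(w)])
    else:
        walk = np.zeros(n + 1)

    # x is the internal plant state (integral of the commanded velocity,
    # noise-free); elbow = x + walk.  The command at step m is
    #   u(m) = k * (drive(m) - g*elbow(m-df) - comp(m))
    # with the Smith compensation
    #   comp(m) = g*(x(m-d_disp) - x(m-d_disp-d_hat))
    # and trapezoidal update x(m+1) = x(m) + dt/2*(u(m) + u(m+1)).
    x = np.zeros(n + 1)
    lags = [df] + ([d_disp, d_disp + d_hat] if smith else [])
    min_lag = min(lags)

    def lagged(idx, lag, noise=True):
        j = np.asarray(idx) - lag
        out = np.where(j >= 0, x[np.maximum(j, 0)], 0.0)
        if noise:
            out = out + np.where(j >= 0, walk[np.maximum(j, 0)], 0.0)
        return out

    def command(idx):
        fb = g * lagged(idx, df)
        if smith:
            fb = fb + g * (
                lagged(idx, d_disp, noise=False)
                - lagged(idx, d_disp + d_hat, noise=False)
            )
        return k * (drive[idx] - fb)

    if min_lag >= 1:
        # Every state-dependent lag is at least one internal sample, so
        # within a block of `min_lag` steps the commands depend only on
        # already-computed state: the trapezoidal recursion collapses to
        # a cumulative sum.
        m = 0
        while m < n:
            stop = min(m + min_lag, n)
            u = command(np.arange(m, stop + 1))
            x[m + 1 : stop + 1] = x[m] + np.cumsum(
                0.5 * dt * (u[:-1] + u[1:])
            )
            if np.abs(x[stop] + walk[stop]) > loop.runaway_bound:
                raise LoopUnstableError(
                    f"elbow exceeded {loop.runaway_bound} deg at "
                    f"t={stop * dt:.3f} s"
                )
            m = stop
    else:
        # A zero-lag feedback path makes the trapezoidal step implicit in
        # x(m+1); the dependence is linear, so solve it in closed form.
        # `c` counts how many times x(m+1) enters the command at m+1.
        c = (1 if df == 0 else 0)
        if smith:
            c += (1 if d_disp == 0 else 0) - (1 if d_disp + d_hat == 0 else 0)
        a = 0.5 * dt * k * g * c
        for m in range(n):
            u_m = float(command(m))
            u_next0 = float(command(m + 1))  # with x[m+1] still at 0
            x[m + 1] = (x[m] + 0.5 * dt * (u_m + u_next0)) / (1.0 + a)
            if abs(x[m + 1] + walk[m + 1]) > loop.runaway_bound:
                raise LoopUnstableError("loop unstable (runaway elbow)")

    elbow = x + walk
    return elbow, x


def simulate_tracking(
    subject: SubjectParams,
    trajectory: TargetTrajectory,
    loop: LoopConfig | None = None,
) -> list[TrialRecord]:
    """Simulate ``loop.n_trials`` tracking trials of one subject.

    Noiseless subjects produce identical trials whose estimated phasors
    match :func:`closed_loop_fr` to the discretisation floor (~1e-7
    relative).  With motor noise, trials differ but are reproducible from
    ``loop.seed``.
    """
    if loop is None:
        loop = LoopConfig()
    seeds = np.random.SeedSequence(loop.seed).spawn(loop.n_trials)
    os = loop.oversample
    d_disp = _delay_samples(loop.display_delay, loop.internal_rate)
    trials = []
    for i in range(loop.n_trials):
        rng = np.random.default_rng(seeds[i])
        elbow_int, _ = _simulate_loop(subject, trajectory, loop, rng)
        elbow = elbow_int[: len(elbow_int) - 1 : os][: len(trajectory.time)]
        shifted = np.concatenate([np.zeros(d_disp), elbow_int[: len(elbow_int) - 1 - d_disp]]) \
            if d_disp > 0 else elbow_int[:-1]
        cursor = loop.applied_feedback_gain * shifted[::os][: len(trajectory.time)]
        trials.append(
            TrialRecord(
                time=trajectory.time.copy(),
                target=trajectory.angle.copy(),
                elbow=elbow,
                cursor=cursor,
                metadata={
                    "group": subject.group_label,
                    "applied_feedback_gain": loop.applied_feedback_gain,
                    "trial_index": i,
                },
            )
        )
    return trials


def closed_loop_fr(
    subject: SubjectParams,
    frequencies: np.ndarray,
    loop: LoopConfig | None = None,
) -> np.ndarray:
    """Analytic closed-loop frequency response target -> elbow.

    ``H(jw) = G e^{-jw Tv'} k/(jw) / (1 + k/(jw) * F(jw))`` where the
    feedback term ``F`` is ``g e^{-jw Tf'}`` for a plain subject and
    additionally carries the Smith-predictor compensation
    ``g (e^{-jw Td} - e^{-jw (Td+That)})`` when the predictor is active.
    Primed delays include the display latency and are quantised to the
    simulator's internal grid, so this is the exact steady-state response
    of the simulated loop up to integrator discretisation (~2e-7).
    """
    if loop is None:
        loop = LoopConfig()
    f = np.asarray(frequencies, float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive (w=0 is excluded)")
    rate = loop.internal_rate
    q = lambda d: _delay_samples(d, rate) / rate
    tv = q(loop.display_delay + subject.visual_delay)
    tf = q(loop.display_delay + subject.feedback_delay)
    td = q(loop.display_delay)
    th = q(subject.feedback_delay)
    g = loop.applied_feedback_gain
    s = 2j * np.pi * f
    fwd = subject.visual_gain * np.exp(-s * tv) * subject.k / s
    fb = g * np.exp(-s * tf)
    if subject.use_smith_predictor:
        fb = fb + g * (np.exp(-s * td) - np.exp(-s * (td + th)))
    return fwd / (1.0 + fb * subject.k / s)


# ---------------------------------------------------------------------------
# Discrete reaches


@dataclass(frozen=True)
class ReacherParams:
    """Parameters of a simulated reaching subject.

    The elbow plant is ``J theta'' = tau - b theta'`` (angles in degrees;
    torques in consistent units).  The feedforward command is computed
    from a minimum-jerk desired trajectory using the *internal* inertia
    estimate ``internal_inertia``; a ratio ``internal_inertia/inertia``
    above 1 overdrives the plant and produces hypermetric reaches, below
    1 hypometric ones.  A delayed PD loop on the displayed cursor
    corrects deviations from the desired trajectory.
    """

    inertia: float = 0.2
    internal_inertia: float = 0.2
    damping: float = 0.4
    kp: float = 2.0
    visual_delay: float = 0.12
    start_angle: float = 55.0
    goal_angle: float = 85.0
    movement_time: float = 0.7
    ramp_start: float = 0.5
    ramp_end: float = 0.8
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.inertia <= 0 or self.internal_inertia <= 0:
            raise ValueError("inertias must be positive")
        if self.damping < 0:
            raise ValueError("damping must be non-negative")

    @property
    def goal_excursion(self) -> float:
        return self.goal_angle - self.start_angle


def adapted_subject(
    template: SubjectParams,
    applied_gain: float,
    compensation: float = 0.6,
) -> SubjectParams:
    """Subject parameters after partial adaptation to a cursor gain.

    People rescale their movements under a manipulated feedback gain
    ``g``, but only partially: the elbow response scales by ``g**-c``
    with a compensation exponent ``c`` below 1 (c ~ 0.6 reproduces the
    observed rescaling of roughly 1.2x under a 1.35 gain and 0.8x under
    0.65).  Setting ``k' = k/g`` and ``G' = G * g**(1-c)`` leaves the
    loop denominator unchanged, so the closed-loop response under gain
    ``g`` is exactly ``g**-c`` times the veridical response at every
    frequency.  The fitted parameter shifts this produces (k down and
    visual gain up under g > 1, and the reverse under g < 1) match the
    direction observed empirically.
    """
    if applied_gain <= 0:
        raise ValueError("applied_gain must be positive")
    return dataclasses.replace(
        template,
        k=template.k / applied_gain,
        visual_gain=template.visual_gain * applied_gain ** (1.0 - compensation),
    )


#: Reaching templates: a well-calibrated internal model, and internal
#: inertia estimates 20% above/below the true inertia (the mismatch
#: direction that produces hypermetric/hypometric reaches respectively).
MATCHED_REACHER = ReacherParams()
HYPERMETRIC_REACHER = ReacherParams(internal_inertia=0.24)
HYPOMETRIC_REACHER = ReacherParams(internal_inertia=0.16)


def _min_jerk(t: np.ndarray, T: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalised minimum-jerk position, velocity, acceleration on [0, T]."""
    s = np.clip(t / T, 0.0, 1.0)
    pos = 10 * s**3 - 15 * s**4 + 6 * s**5
    vel = (30 * s**2 - 60 * s**3 + 30 * s**4) / T
    acc = (60 * s - 180 * s**2 + 120 * s**3) / T**2
    vel[t > T] = 0.0
    acc[t > T] = 0.0
    return pos, vel, acc


def simulate_reach(
    reacher: ReacherParams,
    ka: float = 0.0,
    duration: float = 2.0,
    sample_rate: float = 1000.0,
    accel_window: int = 100,
    rng: np.random.Generator | None = None,
    ka_limit: float = 0.02,
) -> ReachTrial:
    """Simulate one 30-degree reach under acceleration-dependent feedback.

    The cursor shown to the subject is
    ``elbow + ka * <trailing-average acceleration>`` — the same causal
    estimator used online in the experiment (second difference followed
    by a trailing ``accel_window``-sample mean).  The subject's delayed
    corrective loop acts on this cursor, so a positive ``ka`` (which makes
    the cursor lag during deceleration) pushes the reach hypermetric and
    a negative ``ka`` hypometric.
    """
    if abs(ka) > ka_limit + 1e-12:
        raise ValueError(f"|ka| exceeds the clamp {ka_limit}")
    dt = 1.0 / sample_rate
    n = int(round(duration * sample_rate))
    t = np.arange(n) * dt
    d = int(round(reacher.visual_delay * sample_rate))

    excursion = reacher.goal_excursion
    pos_n, vel_n, acc_n = _min_jerk(t, reacher.movement_time)
    des = reacher.start_angle + excursion * pos_n
    des_v = excursion * vel_n
    des_a = excursion * acc_n
    tau_ff = reacher.internal_inertia * des_a + reacher.damping * des_v

    theta = np.full(n, reacher.start_angle)
    vel = np.zeros(n)
    cursor = np.full(n, reacher.start_angle)
    # trailing second-difference acceleration state
    acc_buf = np.zeros(n)
    filt = np.zeros(n)

    # Visual correction ramps in over the late (deceleration) phase of
    # the planned movement: the launch is feedforward-dominated and the
    # braking is regulated from the displayed cursor.
    T = reacher.movement_time
    w = np.clip(
        (t - reacher.ramp_start * T) / ((reacher.ramp_end - reacher.ramp_start) * T),
        0.0,
        1.0,
    )

    J, b = reacher.inertia, reacher.damping
    noise = (
        reacher.noise_sd * rng.standard_normal(n)
        if (reacher.noise_sd > 0 and rng is not None)
        else np.zeros(n)
    )

    for i in range(1, n):
        # The position correction acts on the *displayed* cursor after
        # the visual latency; gating it by the deceleration-phase ramp
        # keeps the launch ballistic, so internal-model errors are
        # expressed as dysmetria rather than servoed away.
        if i >= d:
            j = i - d
            tau_fb = w[j] * reacher.kp * (des[j] - cursor[j])
        else:
            tau_fb = 0.0
        acc = (tau_ff[i - 1] + tau_fb + noise[i - 1] - b * vel[i - 1]) / J
        vel[i] = vel[i - 1] + dt * acc
        theta[i] = theta[i - 1] + dt * vel[i]
        # online acceleration estimate: second difference, trailing mean
        if i >= 2:
            acc_buf[i] = (theta[i] - 2 * theta[i - 1] + theta[i - 2]) / dt**2
        lo = max(0, i - accel_window + 1)
        filt[i] = acc_buf[lo : i + 1].sum() / accel_window
        cursor[i] = theta[i] + ka * filt[i]

    return ReachTrial(
        time=t,
        elbow=theta,
        velocity=vel,
        acceleration_estimate=filt,
        cursor=cursor,
        ka=ka,
        start_angle=reacher.start_angle,
        goal_angle=reacher.goal_angle,
    )


def make_cohort(
    n_pairs: int,
    patient_template: SubjectParams = PATIENT_TEMPLATE,
    control_template: SubjectParams = CONTROL_TEMPLATE,
    jitter: dict[str, float] | None = None,
    seed: int | None = None,
) -> list[tuple[SubjectParams, SubjectParams]]:
    """Draw a paired cohort of (patient, control) subjects around templates.

    ``jitter`` maps field names (``k``, ``visual_gain``, ``visual_delay``,
    ``feedback_delay``, ``motor_noise_sd``) to Gaussian spreads; draws are
    clipped to the parameter's valid range.  Ground truth is the returned
    parameter objects themselves.
    """
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    jitter = jitter or {}
    rng = np.random.default_rng(seed)

    def perturb(template: SubjectParams) -> SubjectParams:
        updates = {}
        for name, sd in jitter.items():
            base = getattr(template, name)
            val = base + sd * rng.standard_normal()
            lo = 1e-6 if name == "k" else 0.0
            updates[name] = max(lo, val)
        return dataclasses.replace(template, **updates)

    return [(perturb(patient_template), perturb(control_template)) for _ in range(n_pairs)]
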