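"""Acceleration-dependent cursor feedback, dysmetria metrics, and PEST.

During discrete 30-degree elbow reaches the displayed cursor can be
shifted by a term proportional to the elbow's angular acceleration:

    cursor(t) = elbow(t) + ka * a_hat(t)

where ``a_hat`` is the causal online estimate used by the real-time
display: a second difference of the elbow angle followed by a trailing
100-sample moving average (at 1 kHz this filter contributes a 49.5 ms
group delay).  Positive ``ka`` lends the cursor phase lead during
acceleration and lag during deceleration, which drives reaches
hypermetric; negative ``ka`` drives them hypometric.

Dysmetria is quantified by the *angle of first correction*: the elbow
excursion at the first velocity zero-crossing after reach initiation,
divided by the 30-degree goal.  Ratios above 1.03 are hypermetric, below
0.97 hypometric, otherwise on target.  The PEST (Parameter Estimation by
Sequential Testing) staircase adapts ``ka`` block-by-block from the modal
classification of each block of reaches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ReachTrial",
    "ReachClassification",
    "PestState",
    "PestResult",
    "estimate_filtered_acceleration",
    "acceleration_feedback",
    "filter_group_delay",
    "angle_of_first_correction",
    "classify_reach",
    "block_mode",
    "pest_step",
    "run_pest",
    "fixed_gain_sweep",
    "DEFAULT_SWEEP_GAINS",
]

HYPO, ON_TARGET, HYPER = "hypometric", "on_target", "hypermetric"

#: The fixed-gain sweep applied in experiment order.
DEFAULT_SWEEP_GAINS: tuple[float, ...] = (
    0.0, 0.005, 0.010, 0.015, 0.020, -0.005, -0.010, -0.015, -0.020,
)


@dataclass
class ReachTrial:
    """Kinematics of one discrete reach at 1 kHz."""

    time: np.ndarray
    elbow: np.ndarray
    velocity: np.ndarray
    acceleration_estimate: np.ndarray
    cursor: np.ndarray
    ka: float
    start_angle: float = 55.0
    goal_angle: float = 85.0

    @property
    def goal_excursion(self) -> float:
        return self.goal_angle - self.start_angle

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


def estimate_filtered_acceleration(
    elbow: np.ndarray, sample_rate: float = 1000.0, window: int = 100
) -> np.ndarray:
    """Causal acceleration estimate: second difference + trailing mean.

    The first two samples of the second difference are taken as zero
    (zero-acceleration start assumption) and the moving average always
    divides by ``window``, exactly matching the online estimator.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(elbow, float)
    acc = np.zeros_like(x)
    acc[2:] = (x[2:] - 2.0 * x[1:-1] + x[:-2]) * sample_rate**2
    return np.convolve(acc, np.ones(window) / window, mode="full")[: len(x)]


def acceleration_feedback(
    elbow: np.ndarray,
    ka: float,
    window: int = 100,
    sample_rate: float = 1000.0,
) -> np.ndarray:
    """Displayed cursor series under acceleration-dependent feedback."""
    elbow = np.asarray(elbow, float)
    if len(elbow) < window:
        warnings.warn(
            "series shorter than the acceleration window; trailing average "
            "is zero-padded at the start",
            stacklevel=2,
        )
    return elbow + ka * estimate_filtered_acceleration(elbow, sample_rate, window)


def filter_group_delay(
    window: int = 100, sample_rate: float = 1000.0
) -> float:
    """Group delay of the trailing moving average, in ms, from the phase
    slope of its frequency response at low frequency.

    For a ``window``-sample trailing average this evaluates to
    ``(window - 1) / 2`` samples (49.5 ms for 100 samples at 1 kHz).
    """
    w = np.array([1e-4, 2e-4])  # rad/sample, well below the first null
    m = np.arange(window)
    h = np.exp(-1j * np.outer(w, m)).sum(axis=1) / window
    slope = -(np.angle(h[1]) - np.angle(h[0])) / (w[1] - w[0])
    return slope / sample_rate * 1000.0


def angle_of_first_correction(
    trial: ReachTrial,
    init_frac: float = 0.05,
    stop_frac: float = 0.15,
) -> float:
    """Elbow excursion (deg) at the end of the primary movement — where
    the velocity first returns to (near) zero after reach initiation.

    Initiation is the first sample where speed in the reach direction
    exceeds ``init_frac`` of peak speed.  The stop is the first sample
    after the velocity peak where signed velocity falls to
    ``stop_frac`` of peak speed or below (0 catches strict sign changes
    only; the default band also scores reaches whose velocity brushes
    zero without reversing — an undershoot followed by a corrective
    push — and reads a consistent few tenths of a degree below the apex
    of a reversing reach).  A reach that never slows back down raises
    ``ValueError``.
    """
    sign = 1.0 if trial.goal_angle >= trial.start_angle else -1.0
    v = sign * np.asarray(trial.velocity, float)
    peak = v.max()
    if peak <= 0.0:
        raise ValueError("no movement in the direction of the goal")
    above = np.nonzero(v > init_frac * peak)[0]
    if len(above) == 0:
        raise ValueError("reach never initiated")
    i_peak = int(np.argmax(v))
    stopped = np.nonzero(v[i_peak:] <= stop_frac * peak)[0]
    if len(stopped) == 0:
        raise ValueError("incomplete reach: velocity never returned to zero")
    idx = i_peak + stopped[0]
    return float(sign * (trial.elbow[idx] - trial.start_angle))


@dataclass(frozen=True)
class ReachClassification:
    """Ratio of first-correction angle to goal excursion, with label."""

    ratio: float
    label: str

    HYPO_THRESHOLD = 0.97
    HYPER_THRESHOLD = 1.03


def classify_reach(
    first_correction: float, goal_excursion: float = 30.0
) -> ReachClassification:
    """Classify one reach as hypometric / on-target / hypermetric."""
    if goal_excursion <= 0:
        raise ValueError("goal_excursion must be positive")
    ratio = first_correction / goal_excursion
    if ratio > ReachClassification.HYPER_THRESHOLD:
        label = HYPER
    elif ratio < ReachClassification.HYPO_THRESHOLD:
        label = HYPO
    else:
        label = ON_TARGET
    return ReachClassification(ratio=ratio, label=label)


def block_mode(
    classifications: Sequence[ReachClassification | str],
    previous_direction: int = 0,
) -> str:
    """Modal label of a block of reaches.

    Ties including ``on_target`` resolve to ``on_target``; a
    hypometric/hypermetric tie falls back to the direction of the
    previous PEST step (+1 -> hypometric, -1 -> hypermetric), or to
    ``on_target`` if there is no previous direction.
    """
    labels = [
        c.label if isinstance(c, ReachClassification) else c
        for c in classifications
    ]
    if not labels:
        raise ValueError("empty block")
    counts = {lab: labels.count(lab) for lab in (HYPO, ON_TARGET, HYPER)}
    top = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == top]
    if len(winners) == 1:
        return winners[0]
    if ON_TARGET in winners:
        return ON_TARGET
    if previous_direction > 0:
        return HYPO
    if previous_direction < 0:
        return HYPER
    return ON_TARGET


@dataclass(frozen=True)
class PestState:
    """State of the PEST staircase over the feedback gain ka.

    Step-size bookkeeping follows the classic sequential-testing rules:
    halve on reversal; keep the size on the second same-direction step;
    double from the third same-direction step onward, except that the
    step after a reversal that was preceded by a doubled step delays the
    doubling by one.  Steps are clipped to [min_step, max_step] and ka to
    [-ka_limit, +ka_limit].
    """

    current_ka: float = 0.0
    step_size: float = 0.01
    min_step: float = 0.0035
    max_step: float = 0.01
    ka_limit: float = 0.02
    last_direction: int = 0
    run_length: int = 0
    last_step_doubled: bool = False
    doubled_before_reversal: bool = False
    history: tuple[tuple[float, str], ...] = ()
    terminated: bool = False
    termination_reason: str | None = None
    best_ka: float | None = None


def pest_step(state: PestState, mode: str) -> PestState:
    """Advance the staircase by one block outcome."""
    if state.terminated:
        raise RuntimeError("PEST already terminated")
    if mode not in (HYPO, ON_TARGET, HYPER):
        raise ValueError(f"unknown mode {mode!r}")
    history = state.history + ((state.current_ka, mode),)

    if mode == ON_TARGET:
        prev = state.history[-1] if state.history else None
        if prev is not None and prev == (state.current_ka, ON_TARGET):
            return replace(
                state,
                history=history,
                terminated=True,
                termination_reason="two on-target blocks at the same gain",
                best_ka=state.current_ka,
            )
        return replace(state, history=history)

    direction = 1 if mode == HYPO else -1
    doubled = False
    doubled_before_reversal = state.doubled_before_reversal
    if state.last_direction == 0:
        size = state.step_size
        run = 1
    elif direction == state.last_direction:
        run = state.run_length + 1
        if run == 2:
            size = state.step_size
        elif run == 3 and state.doubled_before_reversal:
            size = state.step_size  # post-doubling exception
            doubled_before_reversal = False
        else:
            size = 2.0 * state.step_size
            doubled = True
    else:  # reversal
        doubled_before_reversal = state.last_step_doubled
        size = 0.5 * state.step_size
        run = 1
    size = float(np.clip(size, state.min_step, state.max_step))
    ka = float(
        np.clip(state.current_ka + direction * size, -state.ka_limit, state.ka_limit)
    )
    return replace(
        state,
        current_ka=ka,
        step_size=size,
        last_direction=direction,
        run_length=run,
        last_step_doubled=doubled,
        doubled_before_reversal=doubled_before_reversal,
        history=history,
    )


@dataclass
class PestResult:
    """Outcome of a PEST run."""

    best_ka: float
    state: PestState
    blocks: list[dict] = field(default_factory=list)
    terminated: bool = False
    termination_reason: str | None = None


def _default_simulator():
    from .simulate import simulate_reach

    return simulate_reach


def run_pest(
    reacher,
    block_size: int = 10,
    max_blocks: int = 40,
    seed: int | None = None,
    simulate_fn: Callable | None = None,
) -> PestResult:
    """Run the PEST staircase on a simulated reaching subject.

    Starts at ka = 0, performs blocks of ``block_size`` reaches at a
    constant gain, classifies each reach, and steps the gain by the
    block-mode rule until two on-target blocks occur at the same gain or
    the block budget runs out (the budget stands in for the experiment's
    time/fatigue stop; the best-so-far gain is then returned).
    """
    simulate = simulate_fn or _default_simulator()
    seeds = np.random.SeedSequence(seed).spawn(max_blocks)
    state = PestState()
    blocks: list[dict] = []
    for b in range(max_blocks):
        rng = np.random.default_rng(seeds[b])
        ratios = []
        labels = []
        for _ in range(block_size):
            trial = simulate(reacher, state.current_ka, rng=rng)
            fc = angle_of_first_correction(trial)
            c = classify_reach(fc, trial.goal_excursion)
            ratios.append(c.ratio)
            labels.append(c.label)
        mode = block_mode(labels, previous_direction=state.last_direction)
        blocks.append(
            {
                "block": b,
                "ka": state.current_ka,
                "mode": mode,
                "median_ratio": float(np.median(ratios)),
            }
        )
        state = pest_step(state, mode)
        if state.terminated:
            break
    if state.terminated:
        best = state.best_ka
        reason = state.termination_reason
    else:
        best = min(blocks, key=lambda d: abs(d["median_ratio"] - 1.0))["ka"]
        reason = "block budget exhausted; best-so-far gain returned"
    return PestResult(
        best_ka=float(best),
        state=state,
        blocks=blocks,
        terminated=state.terminated,
        termination_reason=reason,
    )


def fixed_gain_sweep(
    reacher,
    gains: Sequence[float] = DEFAULT_SWEEP_GAINS,
    block_size: int = 5,
    seed: int | None = None,
    simulate_fn: Callable | None = None,
) -> dict[float, float]:
    """Median angle of first correction at each fixed gain.

    Returns ``{ka: median_first_correction_deg}`` over blocks of
    ``block_size`` reaches, the summary used to show the graded,
    monotone effect of the acceleration-dependent gain.
    """
    simulate = simulate_fn or _default_simulator()
    seeds = np.random.SeedSequence(seed).spawn(len(gains))
    out: dict[float, float] = {}
    for g, s in zip(gains, seeds):
        rng = np.random.default_rng(s)
        firsts = [
            angle_of_first_correction(simulate(reacher, g, rng=rng))
            for _ in range(block_size)
        ]
        out[float(g)] = float(np.median(firsts))
    return out
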