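"""Sum-of-sines and single-sine target trajectories.

The tracking target moves along a 1-D elbow-angle coordinate as a sum of
sinusoids whose frequencies are prime multiples of a common base frequency
(0.05 Hz by default).  Prime multiples guarantee that no component is an
integer multiple of another, so the stimulus is non-harmonic and, with
randomised phases, perceptually unpredictable, while still concentrating
all stimulus power on a small set of exact DFT bins.

Component amplitudes are capped both positionally (2 deg) and in peak
angular velocity (720 deg/s); each component takes the largest amplitude
compatible with both caps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SinusoidComponent",
    "StimulusSpec",
    "TargetTrajectory",
    "DEFAULT_PRIME_MULTIPLIERS",
    "DEFAULT_SINGLE_SINE_FREQS",
    "build_spec",
    "component_amplitudes",
    "generate_sum_of_sines",
    "generate_single_sine",
]

#: Prime multipliers of the 0.05 Hz base that give the 15 stimulated
#: frequencies 0.10 ... 2.35 Hz.
DEFAULT_PRIME_MULTIPLIERS: tuple[int, ...] = (
    2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47,
)

#: Every other sum-of-sines frequency, used for the standalone single-sine
#: trials.
DEFAULT_SINGLE_SINE_FREQS: tuple[float, ...] = (
    0.10, 0.25, 0.55, 0.85, 1.15, 1.55, 2.05, 2.35,
)


def _is_prime(n: int) -> bool:
    if n < 2:
        return False
    if n < 4:
        return True
    if n % 2 == 0:
        return False
    f = 3
    while f * f <= n:
        if n % f == 0:
            return False
        f += 2
    return True


@dataclass(frozen=True)
class SinusoidComponent:
    """One sinusoidal component of the target motion.

    Attributes
    ----------
    frequency : float
        Frequency in Hz (a prime multiple of the base frequency).
    amplitude : float
        Positional amplitude in degrees.
    phase : float
        Phase offset in radians; the component is
        ``amplitude * sin(2*pi*frequency*t + phase)``.
    """

    frequency: float
    amplitude: float
    phase: float = 0.0

    @property
    def peak_velocity(self) -> float:
        """Peak angular velocity of this component, deg/s."""
        return 2.0 * np.pi * self.frequency * self.amplitude


@dataclass(frozen=True)
class StimulusSpec:
    """Design parameters of the sum-of-sines stimulus.

    The defaults reproduce the experimental design: 15 prime multiples of
    0.05 Hz, 2 deg positional cap, 720 deg/s velocity cap, 100 s trials
    sampled at 1 kHz (five replicates of the 20 s fundamental period).
    """

    base_frequency: float = 0.05
    prime_multipliers: tuple[int, ...] = DEFAULT_PRIME_MULTIPLIERS
    positional_cap: float = 2.0
    velocity_cap: float = 720.0
    trial_duration: float = 100.0
    sample_rate: float = 1000.0
    phase_seed: int | None = None

    def __post_init__(self) -> None:
        mults = tuple(int(m) for m in self.prime_multipliers)
        object.__setattr__(self, "prime_multipliers", mults)
        for m in mults:
            if not _is_prime(m):
                raise ValueError(f"multiplier {m} is not prime")
        if len(set(mults)) != len(mults):
            raise ValueError("prime multipliers must be distinct")
        if self.base_frequency <= 0:
            raise ValueError("base_frequency must be positive")
        nyquist = self.sample_rate / 2.0
        for f in self.frequencies:
            if not (0.0 < f < nyquist):
                raise ValueError(
                    f"frequency {f} Hz outside (0, Nyquist={nyquist} Hz)"
                )
        period = self.fundamental_period
        n_periods = self.trial_duration / period
        if abs(n_periods - round(n_periods)) > 1e-9:
            raise ValueError(
                "trial_duration must be an integer multiple of the "
                f"fundamental period ({period} s)"
            )

    @property
    def frequencies(self) -> np.ndarray:
        """Stimulated frequencies in Hz."""
        return self.base_frequency * np.asarray(self.prime_multipliers, float)

    @property
    def fundamental_period(self) -> float:
        """Period of the full sum-of-sines pattern, s."""
        return 1.0 / self.base_frequency

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.sample_rate))


@dataclass(frozen=True)
class TargetTrajectory:
    """A sampled target trajectory plus its exact analytic description.

    ``angle`` is the deviation from the 0 deg centreline in degrees.  The
    components allow exact re-evaluation of the trajectory at arbitrary
    times (used by the closed-loop simulator, which integrates on a finer
    internal grid).
    """

    time: np.ndarray
    angle: np.ndarray
    components: tuple[SinusoidComponent, ...]
    fundamental_period: float
    sample_rate: float

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the analytic trajectory at arbitrary times (s)."""
        t = np.asarray(t, float)
        out = np.zeros_like(t)
        for c in self.components:
            out += c.amplitude * np.sin(2.0 * np.pi * c.frequency * t + c.phase)
        return out

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([c.frequency for c in self.components])


def build_spec(**overrides) -> StimulusSpec:
    """Build a validated :class:`StimulusSpec`, applying keyword overrides.

    Raises ``ValueError`` for non-prime multipliers, frequencies above
    Nyquist, or a trial duration that does not tile the fundamental period.
    """
    return StimulusSpec(**overrides)


def component_amplitudes(spec: StimulusSpec) -> np.ndarray:
    """Per-component amplitudes (deg) under the positional and velocity caps.

    Each component takes ``min(positional_cap, velocity_cap / (2*pi*f))``,
    the largest amplitude that keeps both the position below the positional
    cap and the peak angular velocity ``2*pi*f*A`` below the velocity cap.
    With the default caps the velocity constraint is never binding below
    ~57 Hz, so every default component sits at the 2 deg positional cap.
    """
    f = spec.frequencies
    return np.minimum(spec.positional_cap, spec.velocity_cap / (2.0 * np.pi * f))


def _make_components(
    spec: StimulusSpec, phases: Sequence[float]
) -> tuple[SinusoidComponent, ...]:
    amps = component_amplitudes(spec)
    return tuple(
        SinusoidComponent(frequency=f, amplitude=a, phase=p)
        for f, a, p in zip(spec.frequencies, amps, phases)
    )


def generate_sum_of_sines(
    spec: StimulusSpec | None = None,
    phases: Sequence[float] | None = None,
) -> TargetTrajectory:
    """Sample the sum-of-sines target trajectory.

    Phases are drawn uniformly on [0, 2*pi), one per component, from
    ``spec.phase_seed`` (reproducible), unless ``phases`` is given
    explicitly.
    """
    if spec is None:
        spec = StimulusSpec()
    if phases is None:
        rng = np.random.default_rng(spec.phase_seed)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=len(spec.prime_multipliers))
    phases = np.asarray(phases, float)
    if phases.shape != (len(spec.prime_multipliers),):
        raise ValueError("need one phase per component")
    components = _make_components(spec, phases)
    return _sample(spec, components)


def _sample(
    spec: StimulusSpec, components: tuple[SinusoidComponent, ...]
) -> TargetTrajectory:
    t = np.arange(spec.n_samples) / spec.sample_rate
    angle = np.zeros_like(t)
    for c in components:
        angle += c.amplitude * np.sin(2.0 * np.pi * c.frequency * t + c.phase)
    return TargetTrajectory(
        time=t,
        angle=angle,
        components=components,
        fundamental_period=spec.fundamental_period,
        sample_rate=spec.sample_rate,
    )


def generate_single_sine(
    frequency: float,
    spec: StimulusSpec | None = None,
    phase: float = 0.0,
    strict: bool = True,
) -> TargetTrajectory:
    """A single-sine trajectory whose amplitude matches the corresponding
    sum-of-sines component.

    In strict mode the frequency must be one of the standalone test
    frequencies (every other sum-of-sines frequency).
    """
    if spec is None:
        spec = StimulusSpec()
    if strict and not any(
        abs(frequency - f) < 1e-9 for f in DEFAULT_SINGLE_SINE_FREQS
    ):
        raise ValueError(
            f"{frequency} Hz is not one of the standalone single-sine "
            f"frequencies {DEFAULT_SINGLE_SINE_FREQS}; pass strict=False "
            "to override"
        )
    amplitude = float(
        min(spec.positional_cap, spec.velocity_cap / (2.0 * np.pi * frequency))
    )
    component = SinusoidComponent(frequency, amplitude, phase)
    return _sample(spec, (component,))
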