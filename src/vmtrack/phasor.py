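"""Frequency-response (phasor) estimation and phasor-plot quantities.

A subject's steady-state tracking response is summarised by one complex
*phasor* per stimulated frequency: the ratio of the DFT of the elbow
response to the DFT of the target trajectory.  The phasor's magnitude is
the response gain and its (clockwise) angle the phase lag.  Because the
retained analysis window spans an integer number of fundamental periods,
every stimulated frequency lands exactly on a DFT bin and a plain
rectangular window is leakage-free.

Derived quantities: per-frequency tracking error ``|phasor - 1|`` (the
error-signal amplitude as a proportion of the stimulus amplitude),
position relative to the effort/error circle (radius 0.5 centred at
+0.5, the locus of error-minimising gains for a given phase lag), the
real scaling factor aligning one feedback-gain condition's phasors with
the veridical condition, and unit phase-lag vectors with circular means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import TrialRecord

__all__ = [
    "AnalysisConfig",
    "FrequencyResponse",
    "ScalingResult",
    "estimate_frequency_response",
    "tracking_error",
    "circle_position",
    "fit_scaling_factor",
    "phase_lag_vectors",
    "circular_mean_lag",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Estimation settings.

    The first ``transient_discard`` seconds of each trial (one
    fundamental period by default) are dropped as transient.  Scaling
    factors and aggregate errors use the ``n_lowest_for_scaling`` lowest
    frequencies, where responses are robust.
    """

    transient_discard: float = 20.0
    n_lowest_for_scaling: int = 5
    circle_center: complex = 0.5 + 0.0j
    circle_radius: float = 0.5
    on_circle_tolerance: float = 1e-6


@dataclass
class FrequencyResponse:
    """Complex phasors at the stimulated frequencies.

    ``gain`` is the phasor modulus; ``phase_lag_deg`` is the clockwise
    angle in degrees, reported in [0, 360).
    """

    frequencies: np.ndarray
    phasors: np.ndarray
    n_trials_used: int = 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, float)
        self.phasors = np.asarray(self.phasors, complex)
        if self.frequencies.shape != self.phasors.shape:
            raise ValueError("one phasor per frequency required")

    @property
    def gain(self) -> np.ndarray:
        return np.abs(self.phasors)

    @property
    def phase_lag_deg(self) -> np.ndarray:
        return _wrap360(-np.degrees(np.angle(self.phasors)))

    def at(self, frequencies: np.ndarray) -> np.ndarray:
        """Phasors at the requested frequencies (must be present)."""
        out = np.empty(len(frequencies), complex)
        for i, f in enumerate(frequencies):
            j = np.nonzero(np.isclose(self.frequencies, f, atol=1e-9))[0]
            if len(j) == 0:
                raise KeyError(f"frequency {f} Hz not present")
            out[i] = self.phasors[j[0]]
        return out

    def lowest(self, n: int) -> "FrequencyResponse":
        order = np.argsort(self.frequencies)[:n]
        return FrequencyResponse(
            self.frequencies[order], self.phasors[order], self.n_trials_used
        )


@dataclass(frozen=True)
class ScalingResult:
    """Least-squares scaling of condition phasors onto veridical ones."""

    scaling_factor: float
    residual: float
    frequencies_used: tuple[float, ...]


def _wrap360(deg):
    """Wrap angles to [0, 360); values that round up to 360 map to 0."""
    wrapped = np.mod(deg, 360.0)
    return np.where(wrapped >= 360.0, 0.0, wrapped)


def _bin_index(f: float, duration: float) -> int:
    k = f * duration
    if abs(k - round(k)) > 1e-6:
        raise ValueError(
            f"stimulated frequency {f} Hz does not land on a DFT bin of a "
            f"{duration} s window (bin spacing {1.0 / duration} Hz)"
        )
    return int(round(k))


def _averaged_response(
    trials: list[TrialRecord], start: int
) -> tuple[np.ndarray, int]:
    """Cross-trial mean of the elbow response honouring per-sample masks.

    Samples masked in every trial are linearly interpolated from the
    surrounding valid samples of the mean.
    """
    resp = np.stack([t.elbow[start:] for t in trials])
    mask = np.stack([t.mask[start:] for t in trials])
    counts = mask.sum(axis=0)
    if np.all(counts == 0):
        raise ValueError("all samples are masked in the analysis window")
    summed = np.where(mask, resp, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, summed / np.maximum(counts, 1), np.nan)
    bad = counts == 0
    if np.any(bad):
        idx = np.arange(len(mean))
        mean[bad] = np.interp(idx[bad], idx[~bad], mean[~bad])
    return mean, len(trials)


def _window_phasors(
    response: np.ndarray,
    target: np.ndarray,
    stimulated: np.ndarray,
    sample_rate: float,
) -> np.ndarray:
    """Phasors (response/target complex amplitude ratios) at the
    stimulated frequencies.

    Linear detrending is folded into a joint harmonic regression:
    intercept, slope, and a sine/cosine pair per stimulated frequency
    are fitted together by least squares.  Over an integer number of
    fundamental periods the sinusoid basis matches the DFT bins exactly,
    while the joint fit keeps the trend basis from leaking into the
    stimulated bins (a separately fitted and subtracted line would leak
    ~1e-3 of relative amplitude at 80 s windows, swamping noiseless
    synthetic checks).
    """
    n = len(response)
    duration = n / sample_rate
    for f in stimulated:
        _bin_index(f, duration)  # raise on off-bin frequencies
    t = np.arange(n) / sample_rate
    cols = [np.ones(n), t - t.mean()]
    for f in stimulated:
        w = 2.0 * np.pi * f
        cols.append(np.cos(w * t))
        cols.append(np.sin(w * t))
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, np.column_stack([response, target]), rcond=None)
    # a*cos + b*sin  ->  complex amplitude a - 1j*b (lag positive clockwise)
    a = coef[2::2]
    b = coef[3::2]
    c_resp = a[:, 0] - 1j * b[:, 0]
    c_targ = a[:, 1] - 1j * b[:, 1]
    return c_resp / c_targ


def estimate_frequency_response(
    trials: list[TrialRecord],
    stimulated: np.ndarray,
    config: AnalysisConfig | None = None,
    average_across_trials: bool = True,
) -> FrequencyResponse:
    """Estimate phasors from one or more tracking trials.

    With ``average_across_trials`` (the sum-of-sines mode) the elbow
    series are averaged across trials per time instant, excluding masked
    samples, before detrending and the DFT.  In single-sine mode each
    trial is processed individually (no averaging, no masking) and
    per-trial phasors are averaged per frequency at the end.
    """
    if not trials:
        raise ValueError("need at least one trial")
    if config is None:
        config = AnalysisConfig()
    stimulated = np.asarray(stimulated, float)
    sr = trials[0].sample_rate
    start = int(round(config.transient_discard * sr))
    if start >= len(trials[0].time):
        raise ValueError("transient_discard exceeds the trial duration")
    target = trials[0].target[start:]

    if average_across_trials:
        mean, n_used = _averaged_response(trials, start)
        phasors = _window_phasors(mean, target, stimulated, sr)
    else:
        per_trial = np.stack(
            [
                _window_phasors(t.elbow[start:], t.target[start:], stimulated, sr)
                for t in trials
            ]
        )
        phasors = per_trial.mean(axis=0)
        n_used = len(trials)
    return FrequencyResponse(stimulated, phasors, n_trials_used=n_used)


def tracking_error(
    fr: FrequencyResponse, n_lowest: int = 5
) -> tuple[np.ndarray, float]:
    """Per-frequency error magnitudes ``|phasor - 1|`` and their sum over
    the ``n_lowest`` lowest frequencies (the aggregate tracking error)."""
    err = np.abs(fr.phasors - 1.0)
    order = np.argsort(fr.frequencies)
    aggregate = float(err[order[:n_lowest]].sum())
    return err, aggregate


def circle_position(
    phasor: complex, config: AnalysisConfig | None = None
) -> str:
    """Classify a phasor against the effort/error circle.

    Returns ``"inside"``, ``"on"``, or ``"outside"`` according to the
    distance from the circle centre, with an ``on_circle_tolerance``
    band around the radius.
    """
    if config is None:
        config = AnalysisConfig()
    d = abs(phasor - config.circle_center)
    if abs(d - config.circle_radius) <= config.on_circle_tolerance:
        return "on"
    return "inside" if d < config.circle_radius else "outside"


def fit_scaling_factor(
    fr_condition: FrequencyResponse,
    fr_veridical: FrequencyResponse,
    config: AnalysisConfig | None = None,
) -> ScalingResult:
    """Real scaling factor aligning condition phasors with veridical ones.

    Minimises ``sum |s*p_i - v_i|^2`` over the ``n_lowest_for_scaling``
    lowest common frequencies; the closed form is
    ``s = sum Re(conj(p_i) v_i) / sum |p_i|^2``.  Only the gain is
    affected; phase is untouched by construction.
    """
    if config is None:
        config = AnalysisConfig()
    n = config.n_lowest_for_scaling
    freqs = np.sort(fr_condition.frequencies)[:n]
    p = fr_condition.at(freqs)
    v = fr_veridical.at(freqs)
    denom = float(np.sum(np.abs(p) ** 2))
    if denom == 0.0:
        raise ValueError("condition phasors have zero power")
    s = float(np.sum(np.real(np.conj(p) * v)) / denom)
    residual = float(np.sum(np.abs(s * p - v) ** 2))
    return ScalingResult(
        scaling_factor=s,
        residual=residual,
        frequencies_used=tuple(float(f) for f in freqs),
    )


def phase_lag_vectors(
    fr: FrequencyResponse, frequencies: np.ndarray | None = None
) -> np.ndarray:
    """Unit-modulus complex vectors carrying only the phase lag.

    A lag of L degrees maps to ``exp(-1j * L * pi/180)`` (clockwise on
    the phasor plane).  Group means over such vectors are taken with
    :func:`circular_mean_lag`.
    """
    if frequencies is None:
        frequencies = fr.frequencies
    p = fr.at(np.asarray(frequencies, float))
    with np.errstate(invalid="ignore", divide="ignore"):
        u = p / np.abs(p)
    if np.any(~np.isfinite(u)):
        raise ValueError("zero-gain phasor has no defined phase")
    return u


def circular_mean_lag(lags_deg: np.ndarray) -> float:
    """Circular mean of phase lags (degrees in [0, 360)): the argument of
    the sum of the corresponding unit vectors."""
    vec = np.exp(-1j * np.radians(np.asarray(lags_deg, float))).sum()
    return float(_wrap360(-np.degrees(np.angle(vec))))
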