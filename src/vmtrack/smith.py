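"""Smith-predictor block diagrams and their crossover-model equivalences.

A generic sensorimotor loop: the reference (target) and the plant output
both pass through a single shared visual delay ``T`` before the error
computation; a visual gain ``G`` scales the reference; the brain is a
controller ``C`` whose cascade with the plant ``P`` is lumped as a
scaled integrator ``C*P = k/s`` (only the lumped product matters here).
The brain may additionally run a Smith predictor: an internal plant copy
``P_hat`` driven by the outgoing command, compared undelayed and through
an internal delay copy ``T_hat``, which (when matched) cancels the
self-feedback delay from the loop.

With the predictor matched (``P_hat = P``, ``T_hat = T``) the diagram
simplifies to the delay-free-feedback loop identified for healthy
controls; with the predictor removed it simplifies to the
delayed-feedback loop identified for cerebellar patients.  This module
verifies those identities numerically over the stimulated frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crossover import model_fr

__all__ = ["PlantModel", "smith_loop_fr", "verify_equivalence"]


@dataclass(frozen=True)
class PlantModel:
    """Lumped loop description for the Smith-predictor diagram.

    ``k`` is the lumped controller-plant integrator gain (``C*P = k/s``);
    ``internal_k`` the gain of the brain's plant copy (``C*P_hat``),
    equal to ``k`` when matched and 0 when the predictor is absent;
    ``delay`` the shared visual delay ``T``; ``internal_delay`` the
    brain's delay copy ``T_hat``.
    """

    k: float = 2.7
    internal_k: float = 2.7
    delay: float = 0.141
    internal_delay: float = 0.141
    visual_gain: float = 0.39
    predictor: bool = True

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.delay < 0 or self.internal_delay < 0:
            raise ValueError("delays must be non-negative")


def smith_loop_fr(plant: PlantModel, frequencies: np.ndarray) -> np.ndarray:
    """Frequency response of the full Smith-predictor diagram.

    With ``CP = k/s`` and ``CP_hat = internal_k/s``:

        H = G e^{-sT} CP / (1 + CP_hat (1 - e^{-s T_hat}) + CP e^{-sT})

    The predictor term vanishes when the predictor is absent
    (``internal_k`` treated as 0).
    """
    f = np.asarray(frequencies, float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    s = 2j * np.pi * f
    cp = plant.k / s
    cp_hat = (plant.internal_k / s) if plant.predictor else 0.0
    num = plant.visual_gain * np.exp(-s * plant.delay) * cp
    den = (
        1.0
        + cp_hat * (1.0 - np.exp(-s * plant.internal_delay))
        + cp * np.exp(-s * plant.delay)
    )
    return num / den


def _reference_fr(plant: PlantModel, frequencies: np.ndarray) -> np.ndarray:
    """The simplified crossover structure the diagram should reduce to.

    Matched predictor -> control structure (visual delay T, feedback
    delay 0); no predictor -> patient structure (visual delay and
    feedback delay both T).
    """
    matched = (
        plant.predictor
        and plant.internal_k == plant.k
        and plant.internal_delay == plant.delay
    )
    tf = 0.0 if matched else plant.delay
    params = np.array(
        [
            plant.k, plant.k,
            plant.visual_gain, plant.visual_gain,
            plant.delay, plant.delay,
            tf, tf,
        ]
    )
    h_pat, _ = model_fr(params, frequencies)
    return h_pat


def verify_equivalence(
    plant: PlantModel,
    frequencies: np.ndarray,
    tolerance: float = 1e-9,
) -> tuple[float, bool]:
    """Maximum modulus difference between the full diagram and its
    simplified crossover structure, plus a pass flag.

    The identity is exact (to floating point) for a matched predictor or
    for no predictor; a mismatched internal model or delay copy breaks
    it, which is the diagnostic use of this check.
    """
    full = smith_loop_fr(plant, frequencies)
    simple = _reference_fr(plant, frequencies)
    diff = float(np.max(np.abs(full - simple)))
    return diff, diff < tolerance
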