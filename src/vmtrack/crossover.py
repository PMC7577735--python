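"""Crossover-model fitting, selection, and validation.

Both cohorts (cerebellar patients and age-matched controls) are modelled
as delayed, scaled integrators closing a visual feedback loop.  Per
cohort the elbow/target frequency response is

    H(jw) = G e^{-jw Tv} k/(jw) / (1 + g e^{-jw Tf} k/(jw))

with controller gain ``k`` (1/s), visual gain ``G``, visual (target)
delay ``Tv``, self-feedback delay ``Tf``, and applied cursor feedback
gain ``g`` (1 in the veridical condition).  A joint patient+control
model has up to eight free parameters; a *model structure* yokes subsets
of them together (gains with gains, delays with delays) and may pin
delay classes to zero.  Structures are compared by leave-one-out error
across subject pairs and by parameter consistency (the largest singular
value of the residual matrix of the per-fold parameter sets), with a
Pareto front over the two, and parameter uncertainty comes from
pair-level bootstrap resampling.

The public surface follows the Model/Results convention:
``CrossoverModel(patient_fr, control_fr, structure).fit()`` returns a
:class:`CrossoverResults` carrying the expanded parameter estimates,
the frequency-domain error, and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .phasor import FrequencyResponse
from .simulate import LoopConfig, SubjectParams, simulate_tracking
from .stimulus import TargetTrajectory

__all__ = [
    "PARAM_NAMES",
    "GAIN_NAMES",
    "DELAY_NAMES",
    "ModelStructure",
    "CrossoverModel",
    "CrossoverResults",
    "FitReport",
    "LooReport",
    "FULL_FREE",
    "BEST4_LOWEST_ERR",
    "BEST4_LOWEST_VAR",
    "BEST5_LOWEST_ERR",
    "BEST5_LOWEST_VAR",
    "DEGENERATE_STRUCTURES",
    "model_fr",
    "fd_error",
    "fit_structure",
    "loo_evaluate",
    "consistency",
    "enumerate_structures",
    "select_models",
    "bootstrap_ci",
    "average_fr",
    "simulate_model_td",
    "td_error",
    "simulate_phasor_cohort",
]

GAIN_NAMES = (
    "k_patient",
    "k_control",
    "visual_gain_patient",
    "visual_gain_control",
)
DELAY_NAMES = (
    "visual_delay_patient",
    "visual_delay_control",
    "feedback_delay_patient",
    "feedback_delay_control",
)
PARAM_NAMES = GAIN_NAMES + DELAY_NAMES
_INDEX = {n: i for i, n in enumerate(PARAM_NAMES)}

PARAM_UNITS = {
    "k_patient": "1/s",
    "k_control": "1/s",
    "visual_gain_patient": "-",
    "visual_gain_control": "-",
    "visual_delay_patient": "s",
    "visual_delay_control": "s",
    "feedback_delay_patient": "s",
    "feedback_delay_control": "s",
}

#: Parameters actually used by each model kind; the rest are fixed.
_USED = {
    "crossover": frozenset(PARAM_NAMES),
    "pure_gain": frozenset(("visual_gain_patient", "visual_gain_control")),
    "delayed_gain": frozenset(
        (
            "visual_gain_patient",
            "visual_gain_control",
            "visual_delay_patient",
            "visual_delay_control",
        )
    ),
    "open_loop": frozenset(
        ("k_patient", "k_control", "visual_delay_patient", "visual_delay_control")
    ),
}


def _canon_groups(groups: Iterable[Iterable[str]]) -> tuple[tuple[str, ...], ...]:
    tupled = [tuple(sorted(g, key=_INDEX.__getitem__)) for g in groups]
    return tuple(sorted(tupled, key=lambda g: _INDEX[g[0]]))


@dataclass(frozen=True)
class ModelStructure:
    """A yoking pattern over the eight crossover parameters.

    ``gain_groups`` partitions the four gain parameters, ``delay_groups``
    the four delays; ``zero_delays`` is the set of delays pinned to 0.
    ``kind`` selects the transfer-function family (the default closed
    loop, or one of the degenerate families: pure gain, delayed gain,
    open-loop integrator).
    """

    gain_groups: tuple[tuple[str, ...], ...]
    delay_groups: tuple[tuple[str, ...], ...] = ()
    zero_delays: frozenset = frozenset()
    kind: str = "crossover"
    name: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in _USED:
            raise ValueError(f"unknown model kind {self.kind!r}")
        gg = _canon_groups(self.gain_groups)
        zset = frozenset(self.zero_delays)
        # merge zero-fixed delays out of the free delay groups
        dg = []
        for g in _canon_groups(self.delay_groups):
            members = set(g)
            if members & zset:
                if not members <= zset:
                    raise ValueError(
                        "zero-fixed delays must cover whole yoking groups"
                    )
                continue
            dg.append(g)
        object.__setattr__(self, "gain_groups", gg)
        object.__setattr__(self, "delay_groups", tuple(dg))
        object.__setattr__(self, "zero_delays", zset)
        if sorted(n for g in gg for n in g) != sorted(GAIN_NAMES):
            raise ValueError("gain_groups must partition the four gains")
        covered = sorted(
            list(zset) + [n for g in self.delay_groups for n in g]
        )
        if covered != sorted(DELAY_NAMES):
            raise ValueError(
                "delay_groups plus zero_delays must partition the four delays"
            )

    @property
    def used(self) -> frozenset:
        return _USED[self.kind]

    @property
    def free_groups(self) -> tuple[tuple[str, ...], ...]:
        """Yoking groups that carry at least one used parameter, in
        canonical order (gains first, then non-zero delays)."""
        out = [g for g in self.gain_groups if set(g) & self.used]
        out += [g for g in self.delay_groups if set(g) & self.used]
        return tuple(out)

    @property
    def n_free(self) -> int:
        return len(self.free_groups)

    def expand(self, theta: np.ndarray) -> np.ndarray:
        """Expand a free-parameter vector to the full 8-vector.

        Positivity of gains and delays is enforced through an
        absolute-value reparameterisation.
        """
        theta = np.abs(np.asarray(theta, float))
        if theta.shape != (self.n_free,):
            raise ValueError(
                f"expected {self.n_free} free parameters, got {theta.shape}"
            )
        full = np.zeros(len(PARAM_NAMES))
        if self.kind == "open_loop":  # visual gain folds into k
            full[_INDEX["visual_gain_patient"]] = 1.0
            full[_INDEX["visual_gain_control"]] = 1.0
        for value, group in zip(theta, self.free_groups):
            for name in group:
                full[_INDEX[name]] = value
        for name in self.zero_delays:
            full[_INDEX[name]] = 0.0
        return full

    def key(self) -> tuple:
        """Canonical identity used for de-duplication."""
        return (self.kind, self.gain_groups, self.delay_groups, self.zero_delays)

    def describe(self) -> str:
        gg = " | ".join("{" + ",".join(g) + "}" for g in self.gain_groups)
        dg = " | ".join("{" + ",".join(g) + "}" for g in self.delay_groups)
        z = ",".join(sorted(self.zero_delays, key=_INDEX.__getitem__))
        label = self.name or self.kind
        return f"{label}: gains {gg}; delays {dg}; zero [{z}]"


def _submodel_fr(
    k: float, G: float, tv: float, tf: float, s: np.ndarray, g_app: float, kind: str
) -> np.ndarray:
    if kind == "pure_gain":
        return np.full(s.shape, G, complex)
    if kind == "delayed_gain":
        return G * np.exp(-s * tv)
    if kind == "open_loop":
        return G * k * np.exp(-s * tv) / s
    fwd = G * np.exp(-s * tv) * k / s
    return fwd / (1.0 + g_app * np.exp(-s * tf) * k / s)


def model_fr(
    params: np.ndarray | Sequence[float],
    frequencies: np.ndarray,
    applied_gain: float = 1.0,
    kind: str = "crossover",
) -> tuple[np.ndarray, np.ndarray]:
    """Patient and control phasor arrays for an expanded 8-parameter set."""
    p = np.asarray(params, float)
    f = np.asarray(frequencies, float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    s = 2j * np.pi * f
    h_pat = _submodel_fr(p[0], p[2], p[4], p[6], s, applied_gain, kind)
    h_con = _submodel_fr(p[1], p[3], p[5], p[7], s, applied_gain, kind)
    return h_pat, h_con


def fd_error(
    params: np.ndarray,
    fr_patient: FrequencyResponse,
    fr_control: FrequencyResponse,
    applied_gain: float = 1.0,
    kind: str = "crossover",
) -> float:
    """Frequency-domain fit error: the sum over frequencies of squared
    complex-difference moduli, patient plus control."""
    if not np.allclose(fr_patient.frequencies, fr_control.frequencies):
        raise ValueError("patient and control frequency grids differ")
    h_pat, h_con = model_fr(params, fr_patient.frequencies, applied_gain, kind)
    return float(
        np.sum(np.abs(fr_control.phasors - h_con) ** 2)
        + np.sum(np.abs(fr_patient.phasors - h_pat) ** 2)
    )


# ---------------------------------------------------------------------------
# Named structures

FULL_FREE = ModelStructure(
    gain_groups=[[n] for n in GAIN_NAMES],
    delay_groups=[[n] for n in DELAY_NAMES],
    name="Full 8",
)

_YOKED_GAINS = [["k_patient", "k_control"], ["visual_gain_patient", "visual_gain_control"]]

BEST4_LOWEST_ERR = ModelStructure(
    gain_groups=_YOKED_GAINS,
    delay_groups=[["visual_delay_patient"], ["visual_delay_control", "feedback_delay_patient"]],
    zero_delays=frozenset({"feedback_delay_control"}),
    name="Best 4 (Lowest Err)",
)
BEST4_LOWEST_VAR = ModelStructure(
    gain_groups=_YOKED_GAINS,
    delay_groups=[["visual_delay_patient", "feedback_delay_patient"], ["visual_delay_control"]],
    zero_delays=frozenset({"feedback_delay_control"}),
    name="Best 4 (Lowest Var)",
)
BEST5_LOWEST_ERR = ModelStructure(
    gain_groups=[["k_patient", "k_control"], ["visual_gain_patient"], ["visual_gain_control"]],
    delay_groups=[["visual_delay_patient"], ["visual_delay_control", "feedback_delay_patient"]],
    zero_delays=frozenset({"feedback_delay_control"}),
    name="Best 5 (Lowest Err)",
)
BEST5_LOWEST_VAR = ModelStructure(
    gain_groups=[["k_patient", "k_control"], ["visual_gain_patient"], ["visual_gain_control"]],
    delay_groups=[["visual_delay_patient", "feedback_delay_patient"], ["visual_delay_control"]],
    zero_delays=frozenset({"feedback_delay_control"}),
    name="Best 5 (Lowest Var)",
)

DEGENERATE_STRUCTURES = (
    ModelStructure(
        gain_groups=[[n] for n in GAIN_NAMES],
        zero_delays=frozenset(DELAY_NAMES),
        kind="pure_gain",
        name="Pure gain",
    ),
    ModelStructure(
        gain_groups=[[n] for n in GAIN_NAMES],
        delay_groups=[["visual_delay_patient"], ["visual_delay_control"]],
        zero_delays=frozenset({"feedback_delay_patient", "feedback_delay_control"}),
        kind="delayed_gain",
        name="Pure delayed gain",
    ),
    ModelStructure(
        gain_groups=[[n] for n in GAIN_NAMES],
        delay_groups=[["visual_delay_patient"], ["visual_delay_control"]],
        zero_delays=frozenset({"feedback_delay_patient", "feedback_delay_control"}),
        kind="open_loop",
        name="Open-loop integrator",
    ),
)


def _set_partitions(items: Sequence[str]):
    """All set partitions of a small sequence."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def enumerate_structures(
    include_degenerate: bool = True,
    allow_zero_fixing: bool = True,
) -> list[ModelStructure]:
    """Enumerate the crossover-model structure family.

    All gain partitions times all delay partitions (15 x 15 set
    partitions of four elements each), each delay class optionally
    pinned to zero; duplicates (structures identical after merging
    zero-fixed classes) are canonicalised away.  Named degenerate
    structures are appended when requested.
    """
    out: list[ModelStructure] = []
    seen = set()
    for gains in _set_partitions(list(GAIN_NAMES)):
        for delays in _set_partitions(list(DELAY_NAMES)):
            zero_choices = (
                range(2 ** len(delays)) if allow_zero_fixing else (0,)
            )
            for mask in zero_choices:
                zero = frozenset(
                    n
                    for i, grp in enumerate(delays)
                    if mask >> i & 1
                    for n in grp
                )
                st = ModelStructure(
                    gain_groups=gains, delay_groups=delays, zero_delays=zero
                )
                if st.key() not in seen:
                    seen.add(st.key())
                    out.append(st)
    if include_degenerate:
        for st in DEGENERATE_STRUCTURES:
            if st.key() not in seen:
                seen.add(st.key())
                out.append(st)
    return out


# ---------------------------------------------------------------------------
# Fitting


def _draw_start(structure: ModelStructure, rng: np.random.Generator) -> np.ndarray:
    theta = np.empty(structure.n_free)
    for i, group in enumerate(structure.free_groups):
        if group[0] in DELAY_NAMES:
            theta[i] = rng.uniform(0.0, 0.5)
        elif any(n.startswith("k_") for n in group):
            theta[i] = math.exp(rng.uniform(math.log(0.1), math.log(20.0)))
        else:
            theta[i] = rng.uniform(0.0, 1.5)
    return theta


class CrossoverModel:
    """Joint patient+control crossover model bound to averaged cohort
    frequency responses.

    Parameters
    ----------
    patient_fr, control_fr : FrequencyResponse
        Cohort-averaged phasors on a common frequency grid.
    structure : ModelStructure
        The yoking pattern to fit (default: the four-parameter structure
        with yoked gains, zero control feedback delay, and the patient
        feedback delay yoked to the control visual delay).
    applied_feedback_gain : float
        Cursor feedback gain of the fitted condition (1.0 = veridical).
    """

    def __init__(
        self,
        patient_fr: FrequencyResponse,
        control_fr: FrequencyResponse,
        structure: ModelStructure = BEST4_LOWEST_ERR,
        applied_feedback_gain: float = 1.0,
    ) -> None:
        if not np.allclose(patient_fr.frequencies, control_fr.frequencies):
            raise ValueError("patient and control frequency grids differ")
        self.patient_fr = patient_fr
        self.control_fr = control_fr
        self.structure = structure
        self.applied_feedback_gain = applied_feedback_gain
        self.frequencies = np.asarray(patient_fr.frequencies, float)

    @classmethod
    def from_cohort(
        cls,
        cohort: Sequence[tuple[FrequencyResponse, FrequencyResponse]],
        structure: ModelStructure = BEST4_LOWEST_ERR,
        applied_feedback_gain: float = 1.0,
    ) -> "CrossoverModel":
        """Build from per-pair (patient, control) frequency responses by
        averaging phasors across pairs."""
        pats, cons = zip(*cohort)
        return cls(
            average_fr(pats), average_fr(cons), structure, applied_feedback_gain
        )

    def objective(self, theta: np.ndarray) -> float:
        params = self.structure.expand(theta)
        return fd_error(
            params,
            self.patient_fr,
            self.control_fr,
            self.applied_feedback_gain,
            self.structure.kind,
        )

    def fit(
        self,
        n_restarts: int = 100,
        seed: int | None = None,
        xatol: float = 1e-8,
        fatol: float = 1e-8,
        maxiter: int | None = None,
    ) -> "CrossoverResults":
        """Multi-start Nelder-Mead minimisation of the FD-error.

        ``n_restarts`` simplex searches start from random draws
        (log-uniform k in [0.1, 20], uniform visual gain in [0, 1.5],
        uniform delays in [0, 0.5] s); the lowest-error solution is
        kept.  Deterministic given ``seed``.
        """
        rng = np.random.default_rng(seed)
        best = None
        n_ok = 0
        for _ in range(max(1, n_restarts)):
            theta0 = _draw_start(self.structure, rng)
            try:
                res = minimize(
                    self.objective,
                    theta0,
                    method="Nelder-Mead",
                    options={
                        "xatol": xatol,
                        "fatol": fatol,
                        "maxiter": maxiter or 400 * max(1, self.structure.n_free),
                        "maxfev": 10_000,
                    },
                )
            except (ValueError, FloatingPointError):
                continue
            if not np.isfinite(res.fun):
                continue
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError(
                f"all {n_restarts} restarts failed for structure "
                f"{self.structure.describe()}"
            )
        free = np.abs(best.x)
        return CrossoverResults(
            model=self,
            free_params=free,
            fd_error=float(best.fun),
            n_restarts=n_restarts,
            n_converged=n_ok,
        )


@dataclass
class CrossoverResults:
    """Fit results: expanded parameters, fit error, and diagnostics."""

    model: CrossoverModel
    free_params: np.ndarray
    fd_error: float
    n_restarts: int = 0
    n_converged: int = 0

    @property
    def structure(self) -> ModelStructure:
        return self.model.structure

    @property
    def params(self) -> pd.Series:
        """Expanded 8-parameter vector as a named series."""
        return pd.Series(
            self.structure.expand(self.free_params), index=list(PARAM_NAMES)
        )

    def predict(
        self, frequencies: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Model phasors (patient, control) at the given frequencies."""
        f = self.model.frequencies if frequencies is None else frequencies
        return model_fr(
            self.params.to_numpy(),
            f,
            self.model.applied_feedback_gain,
            self.structure.kind,
        )

    def summary(self) -> str:
        p = self.params
        lines = [
            "Crossover model fit",
            "=" * 66,
            f"structure:        {self.structure.describe()}",
            f"free parameters:  {self.structure.n_free}",
            f"applied gain:     {self.model.applied_feedback_gain}",
            f"FD-error:         {self.fd_error:.6g}",
            f"restarts:         {self.n_converged}/{self.n_restarts} converged",
            "-" * 66,
            f"{'parameter':<28}{'value':>12}  unit",
        ]
        for name in PARAM_NAMES:
            lines.append(f"{name:<28}{p[name]:>12.4g}  {PARAM_UNITS[name]}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # short, informative
        return (
            f"<CrossoverResults {self.structure.name or self.structure.kind}"
            f" n_free={self.structure.n_free} fd_error={self.fd_error:.4g}>"
        )


def fit_structure(
    structure: ModelStructure,
    avg_fr_patient: FrequencyResponse,
    avg_fr_control: FrequencyResponse,
    n_restarts: int = 100,
    seed: int | None = None,
    applied_gain: float = 1.0,
) -> CrossoverResults:
    """Functional wrapper: fit one structure to averaged cohort responses."""
    return CrossoverModel(
        avg_fr_patient, avg_fr_control, structure, applied_gain
    ).fit(n_restarts=n_restarts, seed=seed)


def average_fr(frs: Sequence[FrequencyResponse]) -> FrequencyResponse:
    """Complex mean of frequency responses on a shared grid."""
    f0 = frs[0].frequencies
    for fr in frs[1:]:
        if not np.allclose(fr.frequencies, f0):
            raise ValueError("frequency grids differ across subjects")
    stack = np.stack([fr.phasors for fr in frs])
    return FrequencyResponse(f0.copy(), stack.mean(axis=0), n_trials_used=len(frs))


# ---------------------------------------------------------------------------
# Model selection


@dataclass
class LooReport:
    """Leave-one-out evaluation of one structure on a paired cohort."""

    structure: ModelStructure
    loo_errors: np.ndarray
    param_sets: pd.DataFrame  # n_pairs x 8
    fold_fits: list[CrossoverResults] = field(default_factory=list)

    @property
    def mean_loo_error(self) -> float:
        return float(np.mean(self.loo_errors))

    @property
    def consistency(self) -> float:
        return consistency(self.param_sets.to_numpy())


def loo_evaluate(
    structure: ModelStructure,
    cohort: Sequence[tuple[FrequencyResponse, FrequencyResponse]],
    n_restarts: int = 100,
    seed: int | None = None,
    applied_gain: float = 1.0,
) -> LooReport:
    """Leave-one-pair-out evaluation.

    For each left-out pair the structure is fitted to the average of the
    remaining pairs' responses and scored on the left-out pair's
    phasors; the per-fold parameter sets feed the consistency gauge.
    """
    n = len(cohort)
    if n < 3:
        raise ValueError("need at least 3 pairs for leave-one-out")
    seeds = np.random.SeedSequence(seed).spawn(n)
    errors = np.empty(n)
    rows = []
    fits = []
    for i in range(n):
        rest = [cohort[j] for j in range(n) if j != i]
        res = CrossoverModel.from_cohort(rest, structure, applied_gain).fit(
            n_restarts=n_restarts, seed=seeds[i]
        )
        left_p, left_c = cohort[i]
        errors[i] = fd_error(
            res.params.to_numpy(), left_p, left_c, applied_gain, structure.kind
        )
        rows.append(res.params)
        fits.append(res)
    return LooReport(
        structure=structure,
        loo_errors=errors,
        param_sets=pd.DataFrame(rows).reset_index(drop=True),
        fold_fits=fits,
    )


def consistency(param_sets: np.ndarray) -> float:
    """Largest singular value of the residual parameter matrix.

    Rows are per-fold parameter sets; residuals are taken against the
    column means with no unit normalisation, so the gauge mixes 1/s and
    s exactly as the parameter vector does.
    """
    m = np.asarray(param_sets, float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    resid = m - m.mean(axis=0, keepdims=True)
    return float(np.linalg.svd(resid, compute_uv=False)[0])


@dataclass
class FitReport:
    """Selection-relevant summary of one structure."""

    structure: ModelStructure
    mean_loo_error: float
    consistency: float
    label: str | None = None

    @property
    def n_free(self) -> int:
        return self.structure.n_free


def select_models(reports: Sequence[FitReport | LooReport]) -> list[FitReport]:
    """Pareto front over (leave-one-out error, consistency).

    Dominated structures are dropped; survivors are sorted by error and
    labelled "lowest error" / "lowest variance" within each
    free-parameter count.  Ties on both axes break toward fewer free
    parameters.
    """
    items = [
        r
        if isinstance(r, FitReport)
        else FitReport(r.structure, r.mean_loo_error, r.consistency)
        for r in reports
    ]
    if not items:
        raise ValueError("no reports to select from")

    def dominated(a: FitReport) -> bool:
        for b in items:
            if b is a:
                continue
            better_eq = (
                b.mean_loo_error <= a.mean_loo_error
                and b.consistency <= a.consistency
            )
            strictly = (
                b.mean_loo_error < a.mean_loo_error
                or b.consistency < a.consistency
            )
            tie = (
                b.mean_loo_error == a.mean_loo_error
                and b.consistency == a.consistency
                and b.n_free < a.n_free
            )
            if (better_eq and strictly) or tie:
                return True
        return False

    front = [r for r in items if not dominated(r)]
    front.sort(key=lambda r: (r.mean_loo_error, r.consistency, r.n_free))
    for n_free in {r.n_free for r in front}:
        stratum = [r for r in front if r.n_free == n_free]
        min(stratum, key=lambda r: r.mean_loo_error).label = "lowest error"
        best_var = min(stratum, key=lambda r: r.consistency)
        best_var.label = (
            "lowest variance"
            if best_var.label is None
            else best_var.label + " / lowest variance"
        )
    return front


def bootstrap_ci(
    structure: ModelStructure,
    cohort: Sequence[tuple[FrequencyResponse, FrequencyResponse]],
    B: int = 1000,
    level: float = 0.95,
    n_restarts: int = 20,
    seed: int | None = None,
    applied_gain: float = 1.0,
) -> pd.DataFrame:
    """Pair-level bootstrap confidence intervals for the parameters.

    Subject pairs are resampled with replacement (patient and control
    move together), the structure refitted on each resampled cohort's
    average, and percentile intervals taken at the requested level.
    Returns a DataFrame with columns ``lo``, ``hi``, ``median`` and an
    ``n_failed`` attribute recording dropped fit failures.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 pairs")
    rng = np.random.default_rng(seed)
    seeds = np.random.SeedSequence(rng.integers(2**31)).spawn(B)
    draws = []
    n_failed = 0
    for b in range(B):
        idx = rng.integers(0, len(cohort), size=len(cohort))
        resampled = [cohort[i] for i in idx]
        try:
            res = CrossoverModel.from_cohort(
                resampled, structure, applied_gain
            ).fit(n_restarts=n_restarts, seed=seeds[b])
        except RuntimeError:
            n_failed += 1
            continue
        draws.append(res.params)
    if not draws:
        raise RuntimeError("every bootstrap fit failed")
    mat = pd.DataFrame(draws).reset_index(drop=True)
    alpha = (1.0 - level) / 2.0
    out = pd.DataFrame(
        {
            "lo": mat.quantile(alpha),
            "median": mat.quantile(0.5),
            "hi": mat.quantile(1.0 - alpha),
        }
    )
    out.attrs["n_failed"] = n_failed
    out.attrs["B"] = B
    return out


# ---------------------------------------------------------------------------
# Time-domain validation


def _subject_from_params(params: pd.Series | np.ndarray, group: str) -> SubjectParams:
    p = (
        params
        if isinstance(params, pd.Series)
        else pd.Series(np.asarray(params, float), index=list(PARAM_NAMES))
    )
    suffix = "patient" if group == "patient" else "control"
    return SubjectParams(
        k=float(p[f"k_{suffix}"]),
        visual_gain=float(p[f"visual_gain_{suffix}"]),
        visual_delay=float(p[f"visual_delay_{suffix}"]),
        feedback_delay=float(p[f"feedback_delay_{suffix}"]),
        group_label=group,
    )


def simulate_model_td(
    params: pd.Series | np.ndarray,
    trajectory: TargetTrajectory,
    applied_gain: float = 1.0,
    include_display_delay: bool = False,
    oversample: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the fitted loop in the time domain.

    Returns the predicted patient and control elbow series at the
    recording rate.  Fitted delays already absorb the display latency,
    so the default simulation applies no extra display delay (a config
    flag restores it for sensitivity checks).
    """
    disp = 0.0458 if include_display_delay else 0.0
    loop = LoopConfig(
        applied_feedback_gain=applied_gain,
        display_delay=disp,
        sample_rate=trajectory.sample_rate,
        oversample=oversample,
        n_trials=1,
        seed=0,
    )
    out = []
    for group in ("patient", "control"):
        subject = _subject_from_params(params, group)
        out.append(simulate_tracking(subject, trajectory, loop)[0].elbow)
    return out[0], out[1]


def td_error(
    pred_patient: np.ndarray,
    obs_patient: np.ndarray,
    pred_control: np.ndarray,
    obs_control: np.ndarray,
    sample_rate: float = 1000.0,
    window_s: float = 80.0,
) -> float:
    """Time-domain validation error.

    Mean squared difference (deg^2) between predicted and observed mean
    elbow series over the last ``window_s`` seconds, computed as a
    Riemann sum at the sampling interval and summed over both cohorts.
    """
    n = int(round(window_s * sample_rate))
    total = 0.0
    for pred, obs in (
        (pred_patient, obs_patient),
        (pred_control, obs_control),
    ):
        pred = np.asarray(pred, float)
        obs = np.asarray(obs, float)
        if len(pred) != len(obs):
            raise ValueError("prediction/observation length mismatch")
        if len(pred) < n:
            raise ValueError("series shorter than the validation window")
        d = pred[-n:] - obs[-n:]
        total += float(np.mean(d * d))
    return total


# ---------------------------------------------------------------------------
# Model-space synthetic cohorts


def simulate_phasor_cohort(
    truth: pd.Series | np.ndarray,
    frequencies: np.ndarray,
    n_pairs: int = 11,
    noise_sd: float = 0.05,
    seed: int | None = None,
    applied_gain: float = 1.0,
) -> list[tuple[FrequencyResponse, FrequencyResponse]]:
    """Paired per-subject phasors drawn around a ground-truth model.

    Each subject's phasors are the model response plus circular complex
    Gaussian noise with total standard deviation ``noise_sd`` per
    frequency (real and imaginary parts each ``noise_sd/sqrt(2)``).
    """
    rng = np.random.default_rng(seed)
    f = np.asarray(frequencies, float)
    truth_arr = (
        truth.to_numpy() if isinstance(truth, pd.Series) else np.asarray(truth, float)
    )
    h_pat, h_con = model_fr(truth_arr, f, applied_gain)
    cohort = []
    scale = noise_sd / np.sqrt(2.0)
    for _ in range(n_pairs):
        noise = lambda: scale * (
            rng.standard_normal(len(f)) + 1j * rng.standard_normal(len(f))
        )
        cohort.append(
            (
                FrequencyResponse(f.copy(), h_pat + noise()),
                FrequencyResponse(f.copy(), h_con + noise()),
            )
        )
    return cohort
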