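"""File formats, cohort manifests, and the pipeline driver.

Everything on disk is plain text: trial time series as CSV with a JSON
sidecar holding metadata, frequency responses as CSV, fit reports as
JSON.  Every artifact written by the pipeline carries provenance (a
configuration hash and the seeds used), so a rerun with the same
configuration is byte-identical apart from file timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import crossover
from .crossover import (
    BEST4_LOWEST_ERR,
    BEST4_LOWEST_VAR,
    BEST5_LOWEST_ERR,
    BEST5_LOWEST_VAR,
    FULL_FREE,
    CrossoverModel,
    CrossoverResults,
    FitReport,
    ModelStructure,
    loo_evaluate,
    select_models,
)
from .phasor import AnalysisConfig, FrequencyResponse, estimate_frequency_response
from .simulate import LoopConfig, TrialRecord, make_cohort, simulate_tracking
from .stimulus import StimulusSpec, build_spec, generate_sum_of_sines

__all__ = [
    "CohortManifest",
    "RunConfig",
    "write_trial",
    "read_trial",
    "read_trials",
    "write_frequency_response",
    "read_frequency_response",
    "write_fit_report",
    "read_fit_report",
    "read_manifest",
    "run_pipeline",
]

logger = logging.getLogger("vmtrack")

_TRIAL_COLUMNS = ("time_s", "target_deg", "elbow_deg", "cursor_deg")


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_trial(trial: TrialRecord, csv_path: str | Path) -> None:
    """Write a trial as CSV plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {
            "time_s": trial.time,
            "target_deg": trial.target,
            "elbow_deg": trial.elbow,
            "cursor_deg": trial.cursor,
            "mask": trial.mask.astype(int),
        }
    )
    df.to_csv(csv_path, index=False, float_format="%.6f")
    meta = dict(trial.metadata)
    meta["sample_rate_hz"] = float(round(trial.sample_rate))
    _sidecar_path(csv_path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_trial(csv_path: str | Path, expected_rate: float = 1000.0) -> TrialRecord:
    """Read and validate one trial (CSV + sidecar).

    Columns are header-keyed so order does not matter.  Raises on a
    missing sidecar, missing columns, non-uniform sampling, or a sample
    rate that does not match ``expected_rate``.
    """
    csv_path = Path(csv_path)
    sidecar = _sidecar_path(csv_path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar for {csv_path}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(csv_path)
    missing = [c for c in _TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{csv_path}: missing columns {missing}")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if len(dt) == 0 or np.max(np.abs(dt - dt[0])) > 1e-6:
        raise ValueError(f"{csv_path}: non-uniform sampling")
    rate = 1.0 / dt[0]
    if abs(rate - expected_rate) > 0.5:
        raise ValueError(
            f"{csv_path}: sample rate {rate:.1f} Hz does not match the "
            f"expected {expected_rate:.0f} Hz"
        )
    mask = (
        df["mask"].to_numpy().astype(bool)
        if "mask" in df.columns
        else np.ones(len(df), bool)
    )
    return TrialRecord(
        time=t,
        target=df["target_deg"].to_numpy(),
        elbow=df["elbow_deg"].to_numpy(),
        cursor=df["cursor_deg"].to_numpy(),
        metadata=meta,
        mask=mask,
    )


def read_trials(paths, expected_rate: float = 1000.0) -> list[TrialRecord]:
    """Read several trials (a list of paths or a glob-expanded iterable)."""
    return [read_trial(p, expected_rate) for p in paths]


def write_frequency_response(fr: FrequencyResponse, path: str | Path) -> None:
    pd.DataFrame(
        {
            "freq_hz": fr.frequencies,
            "re": fr.phasors.real,
            "im": fr.phasors.imag,
            "gain": fr.gain,
            "phase_lag_deg": fr.phase_lag_deg,
        }
    ).to_csv(path, index=False, float_format="%.9g")


def read_frequency_response(path: str | Path) -> FrequencyResponse:
    df = pd.read_csv(path)
    return FrequencyResponse(
        df["freq_hz"].to_numpy(), df["re"].to_numpy() + 1j * df["im"].to_numpy()
    )


def _structure_to_dict(st: ModelStructure) -> dict:
    return {
        "kind": st.kind,
        "name": st.name,
        "gain_groups": [list(g) for g in st.gain_groups],
        "delay_groups": [list(g) for g in st.delay_groups],
        "zero_delays": sorted(st.zero_delays),
    }


def _structure_from_dict(d: dict) -> ModelStructure:
    return ModelStructure(
        gain_groups=[tuple(g) for g in d["gain_groups"]],
        delay_groups=[tuple(g) for g in d["delay_groups"]],
        zero_delays=frozenset(d["zero_delays"]),
        kind=d.get("kind", "crossover"),
        name=d.get("name"),
    )


def write_fit_report(
    results: CrossoverResults, path: str | Path, extra: dict | None = None
) -> None:
    """Serialise a fit (structure, parameters with units, error) to JSON."""
    payload = {
        "structure": _structure_to_dict(results.structure),
        "params": {
            name: {"value": float(v), "unit": crossover.PARAM_UNITS[name]}
            for name, v in results.params.items()
        },
        "fd_error": results.fd_error,
        "applied_feedback_gain": results.model.applied_feedback_gain,
        "n_restarts": results.n_restarts,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_fit_report(path: str | Path) -> dict:
    d = json.loads(Path(path).read_text())
    d["structure"] = _structure_from_dict(d["structure"])
    return d


@dataclass
class CohortManifest:
    """Paired-subject manifest: each patient has exactly one control.

    ``subjects`` entries are dicts with keys ``id``, ``group``
    (``patient``/``control``), ``pair`` (the pairing key) and ``trials``
    (list of CSV paths).
    """

    subjects: list[dict]
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        pairs: dict[str, dict[str, dict]] = {}
        for s in self.subjects:
            if s["group"] not in ("patient", "control"):
                raise ValueError(f"unknown group {s['group']!r}")
            slot = pairs.setdefault(str(s["pair"]), {})
            if s["group"] in slot:
                raise ValueError(f"pair {s['pair']} has two {s['group']}s")
            slot[s["group"]] = s
        for key, slot in pairs.items():
            if set(slot) != {"patient", "control"}:
                raise ValueError(f"pair {key} is incomplete")
        self._pairs = pairs

    @property
    def pairs(self) -> list[tuple[dict, dict]]:
        return [
            (slot["patient"], slot["control"])
            for _, slot in sorted(self._pairs.items())
        ]

    def check_files(self) -> None:
        for s in self.subjects:
            for p in s.get("trials", []):
                if not (self.root / p).exists():
                    raise FileNotFoundError(f"subject {s['id']}: missing {p}")


def read_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    data = json.loads(path.read_text())
    return CohortManifest(subjects=data["subjects"], root=path.parent)


@dataclass
class RunConfig:
    """Pipeline configuration (the demo pipeline runs on a simulated
    cohort; point ``manifest`` at recorded data instead to analyse it)."""

    output_dir: str = "vmtrack_out"
    seed: int = 0
    n_pairs: int = 4
    n_trials: int = 2
    n_restarts: int = 10
    bootstrap_B: int = 0
    jitter: dict = field(default_factory=lambda: {"visual_delay": 0.01})
    motor_noise_sd: float = 0.5
    structures: tuple[str, ...] = ("Best 4 (Lowest Err)", "Best 4 (Lowest Var)", "Full 8")
    manifest: str | None = None

    def digest(self) -> str:
        """Hash of the analysis-relevant settings (the output location
        does not affect results and is excluded)."""
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        blob = json.dumps(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_NAMED_STRUCTURES = {
    s.name: s
    for s in (
        BEST4_LOWEST_ERR,
        BEST4_LOWEST_VAR,
        BEST5_LOWEST_ERR,
        BEST5_LOWEST_VAR,
        FULL_FREE,
    )
}


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis chain and write its artifacts.

    stimulus -> closed-loop simulation (or recorded trials from a
    manifest) -> per-subject frequency responses -> structure fitting
    and leave-one-out selection -> (optional) bootstrap.  Returns a
    result bundle dict; artifacts land in ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": config.digest(), "seed": config.seed}
    logger.info("pipeline start (hash %s)", provenance["config_hash"])

    spec = build_spec(phase_seed=config.seed)
    trajectory = generate_sum_of_sines(spec)

    if config.manifest is not None:
        manifest = read_manifest(config.manifest)
        manifest.check_files()
        cohort_fr = []
        for patient, control in manifest.pairs:
            frs = []
            for subj in (patient, control):
                trials = read_trials(manifest.root / p for p in subj["trials"])
                frs.append(
                    estimate_frequency_response(trials, spec.frequencies)
                )
            cohort_fr.append((frs[0], frs[1]))
    else:
        import dataclasses as _dc

        from .simulate import CONTROL_TEMPLATE, PATIENT_TEMPLATE

        pt = _dc.replace(PATIENT_TEMPLATE, motor_noise_sd=config.motor_noise_sd)
        ct = _dc.replace(CONTROL_TEMPLATE, motor_noise_sd=config.motor_noise_sd)
        cohort = make_cohort(
            config.n_pairs, pt, ct, jitter=config.jitter, seed=config.seed
        )
        cohort_fr = []
        for i, (patient, control) in enumerate(cohort):
            frs = []
            for j, subj in enumerate((patient, control)):
                loop = LoopConfig(
                    n_trials=config.n_trials, seed=config.seed * 1000 + i * 10 + j
                )
                trials = simulate_tracking(subj, trajectory, loop)
                frs.append(
                    estimate_frequency_response(trials, spec.frequencies)
                )
            cohort_fr.append((frs[0], frs[1]))

    for i, (fr_p, fr_c) in enumerate(cohort_fr):
        write_frequency_response(fr_p, out / f"fr_pair{i}_patient.csv")
        write_frequency_response(fr_c, out / f"fr_pair{i}_control.csv")

    structures = [_NAMED_STRUCTURES[name] for name in config.structures]
    reports = []
    fits = {}
    for st in structures:
        loo = loo_evaluate(
            st, cohort_fr, n_restarts=config.n_restarts, seed=config.seed
        )
        reports.append(FitReport(st, loo.mean_loo_error, loo.consistency))
        res = CrossoverModel.from_cohort(cohort_fr, st).fit(
            n_restarts=config.n_restarts, seed=config.seed
        )
        fits[st.name] = res
        write_fit_report(
            res,
            out / f"fit_{st.name.replace(' ', '_').replace('(', '').replace(')', '')}.json",
            extra={
                "provenance": provenance,
                "mean_loo_error": loo.mean_loo_error,
                "consistency": loo.consistency,
            },
        )

    front = select_models(reports)
    ranked = pd.DataFrame(
        {
            "structure": [r.structure.name or r.structure.describe() for r in front],
            "n_free": [r.n_free for r in front],
            "mean_loo_error": [r.mean_loo_error for r in front],
            "consistency": [r.consistency for r in front],
            "label": [r.label for r in front],
        }
    )
    ranked.to_csv(out / "model_selection.csv", index=False)

    bundle = {
        "provenance": provenance,
        "cohort_fr": cohort_fr,
        "fits": fits,
        "pareto_front": front,
    }
    if config.bootstrap_B > 0:
        ci = crossover.bootstrap_ci(
            structures[0],
            cohort_fr,
            B=config.bootstrap_B,
            n_restarts=max(2, config.n_restarts // 2),
            seed=config.seed,
        )
        ci.to_csv(out / "bootstrap_ci.csv")
        bundle["bootstrap_ci"] = ci
    logger.info("pipeline done: %d structures, front size %d", len(structures), len(front))
    return bundle
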