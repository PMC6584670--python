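"""Synthetic longitudinal-radiomics cohorts with survival outcomes.

Emulates the data structure of a serial-CT study of advanced NSCLC treated
with EGFR TKIs: each patient is scanned every ~2 months from baseline until
progressive disease, tumor volume follows one of six response patterns, a
panel of secondary radiomic features co-varies with volume, and overall
survival follows a proportional-hazards model whose linear predictor is a
function of the realized trajectory summaries.

Volume-trajectory templates
---------------------------
Templates are piecewise exponential in time.  Patterns 2-5 decay
exponentially from the baseline ratio 1 to a nadir (deep 0.30, shallow
0.85) reached at ``min(4 months, T/2)``, then regrow along a saturating
exponential toward a per-pattern ceiling — the ceiling stands in for the
tumor burden at which progressive disease ends follow-up.  Pattern 1 decays
toward a plateau below 1 and never rises; pattern 6 grows from baseline
toward its ceiling.  Because aggressive patterns reach progressive disease
sooner, the cohort generator couples the number of scans to the pattern
(fewer time points for rapidly progressing patterns).

Multiplicative lognormal noise with a stated coefficient of variation is
applied to every template value (baseline stays exactly 1 on the ratio
scale).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .longitudinal import FeatureTrajectory, summarize

__all__ = [
    "CohortSpec",
    "SyntheticPatient",
    "SurvivalRecord",
    "PATTERN_TEMPLATES",
    "volume_template",
    "generate_volume_trajectory",
    "generate_survival",
    "generate_cohort",
    "cohort_to_frames",
    "write_cohort",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """Observed follow-up of one patient: time in months, event = 1 for death."""

    patient_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event indicator must be 0 or 1")


# Template parameters, frozen at design time.  "slope0" is the post-nadir
# growth rate at the nadir (ratio units/month); growth saturates toward
# "cap".  See module docstring.
PATTERN_TEMPLATES: dict[int, dict] = {
    1: dict(kind="decay", plateau=0.5, rate=0.35),
    2: dict(kind="drop_rise", nadir=0.30, cap=0.8, slope0=0.015),
    3: dict(kind="drop_rise", nadir=0.30, cap=2.2, slope0=0.40),
    4: dict(kind="drop_rise", nadir=0.85, cap=1.4, slope0=0.035),
    5: dict(kind="drop_rise", nadir=0.85, cap=3.5, slope0=0.50),
    6: dict(kind="grow", cap=4.5, slope0=0.40),
}

# Scans until progressive disease: aggressive patterns progress sooner.
PATTERN_TIMEPOINT_RANGE: dict[int, tuple[int, int]] = {
    1: (6, 8),
    2: (5, 7),
    3: (4, 5),
    4: (6, 8),
    5: (4, 5),
    6: (3, 4),
}

#: Secondary features generated as a + b * volume_ratio + N(0, sd) per scan.
#: The noise floors make every secondary feature a decidedly noisier proxy
#: of the volume signal than volume itself (amplitude-to-noise ~2-3 vs ~10),
#: as texture features measured on serial CT are.
SECONDARY_FEATURES: dict[str, tuple[float, float, float]] = {
    "density": (35.0, 15.0, 5.0),
    "skewness_positive": (0.4, 0.6, 0.25),
    "kurtosis_positive": (2.5, 1.0, 0.50),
    "entropy": (3.5, 1.0, 0.35),
    "entropy_inner": (3.0, 1.2, 0.45),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults describe a plausible EGFR-TKI NSCLC cohort: ~2-month scan
    spacing, six response patterns in equal proportion, 10% measurement
    noise, survival tied to the signed trajectory area of volume
    (log-hazard 0.15 per unit of volume AUC2 on the ratio scale) around a
    baseline hazard of 0.02 events/month, and ~45-50% censoring from a
    60-month horizon with uniform dropout.
    """

    n_patients: int = 100
    n_timepoints_range: tuple[int, int] = (3, 8)
    timepoint_spacing: float = 2.0
    pattern_mix: tuple[float, ...] = (1 / 6,) * 6
    noise_cv: float = 0.10
    hazard_coefs: Mapping[str, float] = field(
        default_factory=lambda: {"volume_auc2": 0.15}
    )
    baseline_hazard: float = 0.02
    censor_horizon_months: float = 60.0
    baseline_volume_log_mean: float = np.log(4000.0)  # mm^3
    baseline_volume_log_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be nonnegative")
        lo, hi = self.n_timepoints_range
        if lo < 2 or hi < lo:
            raise ValueError("n_timepoints_range must satisfy 2 <= min <= max")
        if len(self.pattern_mix) != 6 or any(w < 0 for w in self.pattern_mix):
            raise ValueError("pattern_mix needs 6 nonnegative weights")
        if abs(sum(self.pattern_mix) - 1.0) > 1e-9:
            raise ValueError("pattern_mix must sum to 1 within 1e-9")
        for name, value in [
            ("timepoint_spacing", self.timepoint_spacing),
            ("baseline_hazard", self.baseline_hazard),
            ("censor_horizon_months", self.censor_horizon_months),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")


@dataclass(frozen=True)
class SyntheticPatient:
    patient_id: str
    pattern_label: int
    trajectories: dict[str, FeatureTrajectory]
    survival: SurvivalRecord
    true_linear_predictor: float
    baseline_volume: float  # mm^3


def volume_template(pattern: int, times: np.ndarray) -> np.ndarray:
    """Noise-free baseline-normalized volume ratio at ``times`` for a pattern."""
    if pattern not in PATTERN_TEMPLATES:
        raise ValueError(f"unknown pattern label {pattern!r}; expected 1-6")
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("times must be a 1-D grid with at least two points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if t[0] != 0:
        raise ValueError("times must start at the baseline, t = 0")
    p = PATTERN_TEMPLATES[pattern]
    horizon = t[-1]
    if p["kind"] == "decay":
        return p["plateau"] + (1 - p["plateau"]) * np.exp(-p["rate"] * t)
    if p["kind"] == "grow":
        g = p["slope0"] / (p["cap"] - 1.0)
        return p["cap"] - (p["cap"] - 1.0) * np.exp(-g * t)
    t_nadir = min(4.0, horizon / 2.0)
    k = -np.log(p["nadir"]) / t_nadir
    g = p["slope0"] / (p["cap"] - p["nadir"])
    rise = p["cap"] - (p["cap"] - p["nadir"]) * np.exp(
        -g * np.maximum(t - t_nadir, 0.0)
    )
    return np.where(t <= t_nadir, np.exp(-k * t), rise)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def generate_volume_trajectory(
    pattern: int,
    times: np.ndarray,
    noise_cv: float,
    rng: np.random.Generator,
    patient_id: str = "synthetic",
) -> FeatureTrajectory:
    """Baseline-normalized volume-ratio trajectory for one pattern.

    The deterministic template is multiplied by unit-mean lognormal noise
    with the stated coefficient of variation; the baseline ratio stays
    exactly 1.
    """
    v = volume_template(pattern, times)
    noise = _lognormal_noise(rng, noise_cv, len(v))
    noise[0] = 1.0
    return FeatureTrajectory(
        patient_id, "volume", np.asarray(times, float), v * noise, normalized=True
    )


def generate_survival(
    linear_predictor: float,
    baseline_hazard: float,
    censor_horizon: float,
    rng: np.random.Generator,
    patient_id: str = "synthetic",
) -> SurvivalRecord:
    """Draw one survival record from an exponential proportional-hazards model.

    Event times are exponential with rate ``baseline_hazard *
    exp(linear_predictor)``.  Censoring combines uniform dropout on
    ``(0, 2 * horizon)`` with administrative cut-off at ``horizon``; the
    observed time is the earlier of event and censoring.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if censor_horizon <= 0:
        raise ValueError("censor_horizon must be positive")
    rate = baseline_hazard * np.exp(linear_predictor)
    t_event = rng.exponential(1.0 / rate)
    t_censor = min(censor_horizon, rng.uniform(0.0, 2.0 * censor_horizon))
    time = min(t_event, t_censor)
    event = int(t_event <= t_censor)
    # guard against a zero observed time (probability-zero draw)
    return SurvivalRecord(patient_id, max(time, 1e-9), event)


def _clip_range(pattern: int, spec: CohortSpec) -> tuple[int, int]:
    lo, hi = PATTERN_TIMEPOINT_RANGE[pattern]
    slo, shi = spec.n_timepoints_range
    lo, hi = max(lo, slo), min(hi, shi)
    if lo > hi:  # spec range excludes the pattern's natural range
        return slo, shi
    return lo, hi


def generate_cohort(spec: CohortSpec) -> list[SyntheticPatient]:
    """Generate a full synthetic cohort, reproducible from ``spec.seed``.

    Per patient: a pattern label drawn from ``pattern_mix``; a shared time
    grid; a noisy volume-ratio trajectory; secondary feature trajectories
    that are linear transforms of the volume ratio plus independent noise
    (raw scale); a raw volume trajectory (ratio times a lognormal baseline
    volume); and a survival record whose log-hazard is
    ``sum(hazard_coefs[summary] * realized summary)`` computed from the
    generated (noisy) normalized trajectories.
    """
    rng = np.random.default_rng(spec.seed)
    patients: list[SyntheticPatient] = []
    width = max(3, len(str(max(spec.n_patients - 1, 0))))
    for i in range(spec.n_patients):
        pid = f"P{i:0{width}d}"
        pattern = int(rng.choice(6, p=np.asarray(spec.pattern_mix)) + 1)
        lo, hi = _clip_range(pattern, spec)
        n_tp = int(rng.integers(lo, hi + 1))
        times = np.arange(n_tp) * spec.timepoint_spacing

        ratio_traj = generate_volume_trajectory(
            pattern, times, spec.noise_cv, rng, patient_id=pid
        )
        ratio = ratio_traj.values
        baseline_volume = float(
            rng.lognormal(spec.baseline_volume_log_mean, spec.baseline_volume_log_sd)
        )

        trajectories: dict[str, FeatureTrajectory] = {
            "volume": FeatureTrajectory(
                pid, "volume", times, ratio * baseline_volume, normalized=False
            )
        }
        for name, (a, b, sd) in SECONDARY_FEATURES.items():
            vals = a + b * ratio + rng.normal(0.0, sd, size=len(ratio))
            trajectories[name] = FeatureTrajectory(
                pid, name, times, vals, normalized=False
            )
        # surface area scales as volume^(2/3) with its own measurement noise
        r_eq = (3.0 * baseline_volume / (4.0 * np.pi)) ** (1.0 / 3.0)
        s0 = 4.0 * np.pi * r_eq**2
        sa = s0 * ratio ** (2.0 / 3.0) * _lognormal_noise(rng, spec.noise_cv, len(ratio))
        trajectories["surface_area"] = FeatureTrajectory(
            pid, "surface_area", times, sa, normalized=False
        )

        lp = 0.0
        for key, coef in spec.hazard_coefs.items():
            feat, stat = key.rsplit("_", 1)
            if stat not in ("auc1", "beta", "auc2"):
                raise ValueError(f"hazard_coefs key {key!r} must end in a summary name")
            tri = summarize(trajectories[feat], normalize=True)
            lp += coef * getattr(tri, stat)

        survival = generate_survival(
            lp,
            spec.baseline_hazard,
            spec.censor_horizon_months,
            rng,
            patient_id=pid,
        )
        patients.append(
            SyntheticPatient(pid, pattern, trajectories, survival, lp, baseline_volume)
        )
    return patients


def cohort_to_frames(
    patients: list[SyntheticPatient],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Long trajectory table, outcome table and per-patient truth table."""
    traj_rows, outcome_rows, truth_rows = [], [], []
    for p in patients:
        for name, traj in p.trajectories.items():
            for t, v in zip(traj.times, traj.values):
                traj_rows.append(
                    dict(patient_id=p.patient_id, time_months=t, feature=name, value=v)
                )
        outcome_rows.append(
            dict(
                patient_id=p.patient_id,
                time_months=p.survival.time,
                event=p.survival.event,
            )
        )
        truth_rows.append(
            dict(
                patient_id=p.patient_id,
                pattern_label=p.pattern_label,
                true_linear_predictor=p.true_linear_predictor,
                baseline_volume_mm3=p.baseline_volume,
            )
        )
    cols = ["patient_id", "time_months", "feature", "value"]
    traj_df = pd.DataFrame(traj_rows, columns=cols)
    outcome_df = pd.DataFrame(
        outcome_rows, columns=["patient_id", "time_months", "event"]
    )
    truth_df = pd.DataFrame(truth_rows)
    return traj_df, outcome_df, truth_df


def write_cohort(patients: list[SyntheticPatient], outdir, spec: CohortSpec) -> dict:
    """Write trajectory/outcome/truth CSVs plus a key-value config file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj_df, outcome_df, truth_df = cohort_to_frames(patients)
    paths = {
        "trajectories": outdir / "trajectories.csv",
        "outcomes": outdir / "outcomes.csv",
        "truth": outdir / "truth.csv",
        "config": outdir / "cohort_config.txt",
    }
    traj_df.to_csv(paths["trajectories"], index=False)
    outcome_df.to_csv(paths["outcomes"], index=False)
    truth_df.to_csv(paths["truth"], index=False)
    with open(paths["config"], "w") as fh:
        fh.write(f"# deltarad synthetic cohort (seed={spec.seed})\n")
        for key, value in vars(spec).items():
            if isinstance(value, Mapping):
                value = json.dumps(dict(value))
            fh.write(f"{key} = {value}\n")
    return {k: str(v) for k, v in paths.items()}
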