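"""Longitudinal summaries of serial radiomic feature measurements.

Each patient contributes, per feature, a short irregular time series running
from the baseline scan (t = 0) to the scan at progressive disease.  Three
scalar summaries condense such a trajectory:

``auc1``
    unsigned trapezoid area under the piecewise-linear interpolant,
    in feature-units x months;
``beta``
    ordinary-least-squares slope of value on time, in feature-units per
    month;
``auc2``
    signed trapezoid area in which every segment whose value increases
    contributes positively and every other segment contributes negatively.

``auc2`` is the quantity of interest: it separates trajectories that spend
their follow-up shrinking from those that regrow, and it correlates strongly
with an ordinal six-pattern taxonomy of volume response
(:func:`classify_pattern`).

Trajectories are grid-native: patients may be scanned on different time
grids and no interpolation to a common grid is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureTrajectory",
    "SummaryTriple",
    "PatternThresholds",
    "segment_area",
    "auc1",
    "beta",
    "auc2",
    "summarize",
    "classify_pattern",
    "spearman_pattern_correlation",
    "summary_table",
    "baseline_table",
]

ZeroRule = Literal["subtract", "drop"]


@dataclass(frozen=True)
class FeatureTrajectory:
    """One patient's serial measurements of one feature.

    Parameters
    ----------
    patient_id : str
    feature_name : str
    times : array-like
        Months since baseline, strictly increasing, first element 0.
    values : array-like
        Feature values at ``times``; NaN marks a missing measurement.
    normalized : bool
        True when values are ratios to the baseline value (then
        ``values[0] == 1`` exactly).
    """

    patient_id: str
    feature_name: str
    times: np.ndarray
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.shape != times.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(times) < 2:
            raise ValueError("a trajectory needs at least two time points")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if times[0] != 0:
            raise ValueError("the first time point must be the baseline, t = 0")
        if self.normalized and values[0] != 1.0:
            raise ValueError("a normalized trajectory must have values[0] == 1")

    def normalize(self) -> "FeatureTrajectory":
        """Return the baseline-normalized version of this trajectory."""
        if self.normalized:
            return self
        v0 = self.values[0]
        if not np.isfinite(v0) or v0 == 0:
            raise ValueError(
                f"cannot normalize {self.feature_name!r}: baseline value is {v0}"
            )
        vals = self.values / v0
        vals[0] = 1.0
        return FeatureTrajectory(
            self.patient_id, self.feature_name, self.times, vals, normalized=True
        )

    def dropna(self) -> "FeatureTrajectory":
        """Drop time points with missing values (baseline must be present)."""
        keep = np.isfinite(self.values)
        if keep.all():
            return self
        if not keep[0]:
            raise ValueError("baseline value is missing; cannot summarize")
        if keep.sum() < 2:
            raise ValueError("fewer than two usable time points")
        return FeatureTrajectory(
            self.patient_id,
            self.feature_name,
            self.times[keep] - self.times[keep][0],
            self.values[keep],
            normalized=self.normalized,
        )


@dataclass(frozen=True)
class SummaryTriple:
    """The (AUC1, beta, AUC2) summary of one trajectory."""

    auc1: float
    beta: float
    auc2: float
    n_points: int = 0
    dropped_points: int = 0


@dataclass(frozen=True)
class PatternThresholds:
    """Decision thresholds of the six-pattern volume-trajectory taxonomy.

    ``deep_nadir`` separates a "rapid response" (fractional volume drop
    >= deep_nadir) from a "slight reduction"; ``fast_slope`` (ratio units
    per month) separates "rapid" from "slow" post-nadir progression.
    """

    deep_nadir: float = 0.30
    fast_slope: float = 0.10


def segment_area(t0: float, t1: float, v0: float, v1: float) -> float:
    """Trapezoid area of one segment: ``(v0 + v1) / 2 * (t1 - t0)``."""
    if t1 <= t0:
        raise ValueError("segment times must be strictly increasing")
    return 0.5 * (v0 + v1) * (t1 - t0)


def _areas_and_signs(
    traj: FeatureTrajectory, zero_increment: ZeroRule
) -> tuple[np.ndarray, np.ndarray]:
    t, v = traj.times, traj.values
    areas = 0.5 * (v[:-1] + v[1:]) * np.diff(t)
    dv = np.diff(v)
    # "positive, add; otherwise subtract" -- zero increments subtract under
    # the literal rule, contribute nothing under "drop".
    signs = np.where(dv > 0, 1.0, -1.0)
    if zero_increment == "drop":
        signs = np.where(dv == 0, 0.0, signs)
    return areas, signs


def auc1(traj: FeatureTrajectory) -> float:
    """Unsigned trapezoid area under the trajectory (feature-units x months)."""
    areas, _ = _areas_and_signs(traj, "subtract")
    return float(np.sum(areas))


def auc2(traj: FeatureTrajectory, zero_increment: ZeroRule = "subtract") -> float:
    """Signed trapezoid area: rising segments add, falling segments subtract."""
    areas, signs = _areas_and_signs(traj, zero_increment)
    return float(np.sum(signs * areas))


def beta(traj: FeatureTrajectory) -> float:
    """OLS slope of value on time (feature-units per month)."""
    t, v = traj.times, traj.values
    tc = t - t.mean()
    denom = np.sum(tc * tc)
    if denom == 0:
        raise ValueError("all time points are identical; slope undefined")
    return float(np.sum(tc * (v - v.mean())) / denom)


def summarize(
    traj: FeatureTrajectory,
    normalize: bool = False,
    zero_increment: ZeroRule = "subtract",
) -> SummaryTriple:
    """Compute the (AUC1, beta, AUC2) triple of one trajectory.

    Missing values drop only the affected time points (warning).  With fewer
    than two usable points the triple is returned as all-NaN with a warning,
    never an exception, so batch processing is not interrupted.
    """
    n_raw = len(traj.times)
    try:
        clean = traj.dropna()
        if normalize:
            clean = clean.normalize()
    except ValueError as exc:
        warnings.warn(
            f"{traj.patient_id}/{traj.feature_name}: {exc}; summaries set to NaN",
            stacklevel=2,
        )
        return SummaryTriple(np.nan, np.nan, np.nan, 0, n_raw)
    dropped = n_raw - len(clean.times)
    if dropped:
        warnings.warn(
            f"{traj.patient_id}/{traj.feature_name}: dropped {dropped} missing "
            "time point(s)",
            stacklevel=2,
        )
    return SummaryTriple(
        auc1(clean),
        beta(clean),
        auc2(clean, zero_increment),
        len(clean.times),
        dropped,
    )


def classify_pattern(
    traj: FeatureTrajectory, thresholds: PatternThresholds | None = None
) -> int:
    """Assign a normalized volume trajectory to one of six response patterns.

    The taxonomy, ordered by increasing aggressiveness:

    1. reduction only (progressive disease driven by non-target lesions);
    2. slow progression after rapid response;
    3. rapid progression after rapid response;
    4. slow progression after slight reduction;
    5. rapid progression after slight reduction;
    6. sequential progression (no reduction at all).

    The rules operate on the nadir depth ``d = 1 - min(v)`` and the OLS
    slope ``m`` of the post-nadir part of the trajectory: no post-nadir
    rise -> 1; ``d <= 0`` -> 6; otherwise deep/shallow nadir crossed with
    fast/slow ``m``.
    """
    if not traj.normalized:
        raise ValueError("classify_pattern requires a baseline-normalized trajectory")
    th = thresholds or PatternThresholds()
    clean = traj.dropna()
    t, v = clean.times, clean.values
    i_min = int(np.argmin(v))
    no_rise = i_min == len(v) - 1 or float(np.max(v[i_min:])) <= v[i_min]
    if no_rise:
        return 1
    d = 1.0 - float(v[i_min])
    if d <= 0:
        return 6
    m = float(np.polyfit(t[i_min:], v[i_min:], 1)[0])
    if d >= th.deep_nadir:
        return 2 if m < th.fast_slope else 3
    return 4 if m < th.fast_slope else 5


def spearman_pattern_correlation(
    labels: Sequence[int], summaries: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation between pattern labels and a summary.

    Average ranks on ties, two-sided p-value.  Constant input yields
    ``(nan, nan)`` with a warning rather than an exception.
    """
    labels = np.asarray(labels, dtype=float)
    summaries = np.asarray(summaries, dtype=float)
    if labels.shape != summaries.shape or labels.ndim != 1:
        raise ValueError("labels and summaries must be 1-D and equally long")
    if len(labels) < 3:
        raise ValueError("need at least three observations")
    if np.all(labels == labels[0]) or np.all(summaries == summaries[0]):
        warnings.warn("constant input; Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = stats.spearmanr(labels, summaries)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# table-level API (long trajectory CSV -> wide summary table)

REQUIRED_COLUMNS = ("patient_id", "time_months", "feature", "value")


def _iter_trajectories(long_df: pd.DataFrame):
    for (pid, feat), grp in long_df.groupby(["patient_id", "feature"], sort=True):
        grp = grp.sort_values("time_months")
        yield FeatureTrajectory(
            str(pid),
            str(feat),
            grp["time_months"].to_numpy(float),
            grp["value"].to_numpy(float),
        )


def summary_table(
    long_df: pd.DataFrame,
    normalize: bool = True,
    zero_increment: ZeroRule = "subtract",
) -> pd.DataFrame:
    """Wide per-patient summary table from a long-format trajectory table.

    Input columns: ``patient_id, time_months, feature, value``.  Output is
    indexed by patient_id with columns ``{feature}_{auc1|beta|auc2}``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in long_df.columns]
    if missing:
        raise ValueError(f"trajectory table lacks columns: {missing}")
    rows: dict[str, dict[str, float]] = {}
    for traj in _iter_trajectories(long_df):
        tri = summarize(traj, normalize=normalize, zero_increment=zero_increment)
        row = rows.setdefault(traj.patient_id, {})
        row[f"{traj.feature_name}_auc1"] = tri.auc1
        row[f"{traj.feature_name}_beta"] = tri.beta
        row[f"{traj.feature_name}_auc2"] = tri.auc2
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out = out[sorted(out.columns)]
    out.index.name = "patient_id"
    return out


def baseline_table(long_df: pd.DataFrame) -> pd.DataFrame:
    """Per-patient baseline (t = 0) feature values, columns ``{feature}_baseline``."""
    missing = [c for c in REQUIRED_COLUMNS if c not in long_df.columns]
    if missing:
        raise ValueError(f"trajectory table lacks columns: {missing}")
    base = long_df[long_df["time_months"] == 0]
    wide = base.pivot_table(
        index="patient_id", columns="feature", values="value", aggfunc="first"
    )
    wide.columns = [f"{c}_baseline" for c in wide.columns]
    wide.index = wide.index.astype(str)
    wide.index.name = "patient_id"
    return wide.sort_index()
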