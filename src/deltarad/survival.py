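"""Survival modeling for dichotomized radiomic biomarkers.

The analysis chain implemented here: dichotomize each continuous marker at
the cutoff with the most significant two-group log-rank p-value
(:func:`optimal_cutpoint`), screen the dichotomized markers with univariate
Cox fits, check collinearity with variance inflation factors, select a
multivariate Cox model by bidirectional stepwise AIC, form the linear
predictor as a risk score, and evaluate it with a censoring-weighted
time-dependent ROC.

The log-rank statistic, the Kaplan-Meier product-limit estimator and the
IPCW cumulative/dynamic AUC are implemented directly (the cutpoint scan
needs a vectorized log-rank over many candidate splits, and the AUC needs
left limits of the censoring-distribution KM).  Cox models are fitted with
lifelines (Efron tie handling); an independent Efron partial
log-likelihood evaluator is provided for diagnostics.

A caveat worth restating: choosing the cutoff that minimizes the log-rank
p-value inflates the type-I error of the subsequent test on the same data;
the selected p-value is descriptive, not a calibrated test.  An optional
permutation-adjusted p-value is available from :func:`optimal_cutpoint`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LogrankResult",
    "CutpointResult",
    "KaplanMeierEstimate",
    "CoxFit",
    "StepwiseResult",
    "TdROC",
    "logrank_test",
    "optimal_cutpoint",
    "km_estimate",
    "cox_fit",
    "cox_partial_loglik",
    "univariate_screen",
    "vif_screen",
    "stepwise_aic",
    "risk_score",
    "time_dependent_auroc",
]


def _check_survival(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.shape != event.shape or time.ndim != 1:
        raise ValueError("time and event must be 1-D arrays of equal length")
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    if not np.isin(event, [0, 1]).all():
        raise ValueError("event indicators must be 0 or 1")
    return time, event.astype(int)


# ---------------------------------------------------------------------------
# log-rank


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p: float
    observed_minus_expected: float
    variance: float


def _logrank_scan(
    group_matrix: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(O-E, V) of the two-group log-rank statistic for each column of a
    boolean group matrix, sharing one pass over the risk sets."""
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], group_matrix[order]
    n = len(t)
    # first index of each distinct time
    starts = np.flatnonzero(np.r_[True, np.diff(t) > 0])
    # at-risk counts just before each distinct time
    n_at_risk = n - starts
    n1_at_risk = (g[::-1].cumsum(axis=0)[::-1])[starts]  # per column
    d_at = np.add.reduceat(e, starts)
    d1_at = np.add.reduceat(e[:, None] * g, starts, axis=0)
    use = d_at > 0
    d, nn = d_at[use][:, None], n_at_risk[use][:, None]
    n1 = n1_at_risk[use]
    d1 = d1_at[use]
    o_minus_e = (d1 - d * n1 / nn).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = d * (n1 / nn) * (1 - n1 / nn) * (nn - d) / (nn - 1)
    var_terms = np.where(nn > 1, var_terms, 0.0)
    return o_minus_e, var_terms.sum(axis=0)


def logrank_test(groups, time, event) -> LogrankResult:
    """Two-group log-rank test.

    Sums observed-minus-expected events in the indicator group over the
    risk sets at each distinct event time (hypergeometric variance, tied
    events pooled), and refers ``(O-E)^2 / V`` to chi-square with 1 df.
    If neither group has any event the statistic is 0.
    """
    time, event = _check_survival(time, event)
    groups = np.asarray(groups).astype(bool)
    if groups.shape != time.shape:
        raise ValueError("groups must match time/event in length")
    if groups.all() or (~groups).all():
        raise ValueError("both groups must be nonempty")
    ome, var = _logrank_scan(groups[:, None], time, event)
    ome, var = float(ome[0]), float(var[0])
    if var == 0:
        return LogrankResult(0.0, 1.0, ome, 0.0)
    chi2 = ome**2 / var
    return LogrankResult(chi2, float(stats.chi2.sf(chi2, df=1)), ome, var)


# ---------------------------------------------------------------------------
# optimal cutpoint


@dataclass(frozen=True)
class CutpointResult:
    cutoff: float
    logrank_chi2: float
    p: float
    group_sizes: tuple[int, int]  # (n_low, n_high); high group is marker > cutoff
    n_candidates: int
    permutation_p: float | None = None


def optimal_cutpoint(
    marker,
    time,
    event,
    min_group_frac: float = 0.1,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> CutpointResult:
    """Most-significant log-rank dichotomization of a continuous marker.

    Candidate cutoffs are the midpoints between consecutive distinct sorted
    marker values whose resulting groups (low: marker <= cutoff, high:
    marker > cutoff) each contain at least ``min_group_frac`` of the
    sample.  The returned cutoff minimizes the log-rank p-value; exact ties
    resolve to the smaller cutoff.

    ``n_permutations > 0`` additionally estimates a selection-adjusted
    p-value by re-running the full scan on label-permuted survival data —
    the minimum-p selection makes the raw p anti-conservative.
    """
    time, event = _check_survival(time, event)
    marker = np.asarray(marker, dtype=float)
    if marker.shape != time.shape:
        raise ValueError("marker must match time/event in length")
    n = len(marker)
    if n < 10:
        raise ValueError("cutpoint search needs at least 10 patients")
    distinct = np.unique(marker)
    if len(distinct) < 2:
        raise ValueError("marker is constant; no cutpoint exists")
    mids = 0.5 * (distinct[:-1] + distinct[1:])
    n_high = (marker[:, None] > mids[None, :]).sum(axis=0)
    n_low = n - n_high
    floor = min_group_frac * n
    ok = (n_low >= floor) & (n_high >= floor)
    if not ok.any():
        raise ValueError(
            "no candidate cutoff satisfies the minimum group-size constraint"
        )
    mids, n_low, n_high = mids[ok], n_low[ok], n_high[ok]

    def scan(tt, ee):
        ome, var = _logrank_scan(marker[:, None] > mids[None, :], tt, ee)
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2 = np.where(var > 0, ome**2 / var, 0.0)
        return chi2, stats.chi2.sf(chi2, df=1)

    chi2, pvals = scan(time, event)
    best = int(np.lexsort((mids, pvals))[0])
    perm_p = None
    if n_permutations > 0:
        rng = rng or np.random.default_rng()
        p_min = pvals[best]
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            _, pp = scan(time[perm], event[perm])
            hits += pp.min() <= p_min
        perm_p = (hits + 1) / (n_permutations + 1)
    return CutpointResult(
        float(mids[best]),
        float(chi2[best]),
        float(pvals[best]),
        (int(n_low[best]), int(n_high[best])),
        len(mids),
        perm_p,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Product-limit estimator with Greenwood variance.

    ``times`` are the distinct event times; ``survival`` the estimate just
    after each; ``variance`` the Greenwood variance of the estimate.
    ``median`` is the first time at which the curve drops to 0.5 or below
    (NaN if it never does).
    """

    times: np.ndarray
    survival: np.ndarray
    variance: np.ndarray
    median: float
    n: int
    n_events: int

    def survival_at(self, t, left: bool = False) -> np.ndarray:
        """S(t) (right-continuous); ``left=True`` gives the left limit S(t-)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        side = "left" if left else "right"
        idx = np.searchsorted(self.times, t, side=side)
        s = np.r_[1.0, self.survival]
        return s[idx]


def km_estimate(time, event) -> KaplanMeierEstimate:
    """Kaplan-Meier product-limit estimate of the survival function."""
    time, event = _check_survival(time, event)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = len(t)
    starts = np.flatnonzero(np.r_[True, np.diff(t) > 0])
    at_risk = n - starts
    d = np.add.reduceat(e, starts)
    has_event = d > 0
    ut, nn, dd = t[starts][has_event], at_risk[has_event], d[has_event]
    surv = np.cumprod(1.0 - dd / nn)
    # Greenwood: var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(nn > dd, dd / (nn * (nn - dd)), np.inf))
        var = np.where(surv > 0, surv**2 * gw, 0.0)
    below = np.flatnonzero(surv <= 0.5)
    median = float(ut[below[0]]) if len(below) else float("nan")
    return KaplanMeierEstimate(ut, surv, var, median, n, int(e.sum()))


# ---------------------------------------------------------------------------
# Cox proportional hazards (lifelines-backed)


@dataclass(frozen=True)
class CoxFit:
    """A fitted Cox proportional-hazards model.

    ``summary`` has one row per covariate with columns ``coef, hr,
    ci_lower, ci_upper, p`` (hazard ratio = exp(coef), Wald 95% CI and
    p-value).  ``aic = -2 log PL + 2k`` on the partial likelihood.
    """

    summary: pd.DataFrame
    log_likelihood: float
    aic: float
    n: int
    n_events: int
    converged: bool
    flags: tuple[str, ...] = ()

    @property
    def covariates(self) -> list[str]:
        return list(self.summary.index)


def cox_partial_loglik(beta, design, time, event) -> float:
    """Efron partial log-likelihood at coefficient vector ``beta``.

    Independent of the lifelines fitting path; used to confirm fitted
    coefficients maximize the partial likelihood.
    """
    time, event = _check_survival(time, event)
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = X @ beta
    w = np.exp(eta)
    order = np.argsort(time, kind="stable")
    t, e, eta, w = time[order], event[order], eta[order], w[order]
    ll = 0.0
    # risk-set sum of w for each distinct time (sum over j: t_j >= t)
    starts = np.flatnonzero(np.r_[True, np.diff(t) > 0])
    rev_cumw = np.cumsum(w[::-1])[::-1]
    for s_idx, start in enumerate(starts):
        stop = starts[s_idx + 1] if s_idx + 1 < len(starts) else len(t)
        deaths = np.arange(start, stop)[e[start:stop] == 1]
        d = len(deaths)
        if d == 0:
            continue
        s_risk = rev_cumw[start]
        s_dead = w[deaths].sum()
        ll += eta[deaths].sum()
        for ell in range(d):
            ll -= np.log(s_risk - (ell / d) * s_dead)
    return float(ll)


def cox_fit(design: pd.DataFrame, time, event) -> CoxFit:
    """Maximum partial-likelihood Cox fit (Efron ties) via lifelines.

    Raises on constant columns and when the number of events is below the
    number of covariates; non-convergence and likely separation are
    surfaced as flags on the returned fit.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    time, event = _check_survival(time, event)
    design = pd.DataFrame(design).astype(float)
    if design.isna().any().any():
        raise ValueError("design matrix contains missing values")
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant columns in design: {constant}")
    n_events = int(event.sum())
    if design.shape[1] > 0 and n_events < design.shape[1]:
        raise ValueError(
            f"{n_events} events cannot support {design.shape[1]} covariates"
        )
    df = design.copy()
    df["_time"] = time
    df["_event"] = event
    cph = CoxPHFitter()
    flags: list[str] = []
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except ConvergenceError as exc:
            raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    for w in caught:
        msg = str(w.message)
        if "convergence" in msg.lower() or "complete separation" in msg.lower():
            flags.append(msg.splitlines()[0])
            converged = "complete separation" not in msg.lower()
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": np.exp(s["coef"]),
            "ci_lower": np.exp(s["coef lower 95%"]),
            "ci_upper": np.exp(s["coef upper 95%"]),
            "p": s["p"],
        }
    )
    summary.index.name = "feature"
    k = design.shape[1]
    ll = float(cph.log_likelihood_)
    return CoxFit(
        summary, ll, -2.0 * ll + 2.0 * k, len(time), n_events, converged, tuple(flags)
    )


def _null_fit(time, event) -> CoxFit:
    time, event = _check_survival(time, event)
    # partial likelihood with no covariates (eta = 0)
    ll = cox_partial_loglik(
        np.zeros(1), np.zeros((len(time), 1)), time, event
    )
    empty = pd.DataFrame(columns=["coef", "hr", "ci_lower", "ci_upper", "p"])
    empty.index.name = "feature"
    return CoxFit(empty, ll, -2.0 * ll, len(time), int(np.sum(event)), True)


# ---------------------------------------------------------------------------
# screening and selection


def univariate_screen(
    features: pd.DataFrame, time, event, alpha: float = 0.05
) -> tuple[pd.DataFrame, list[str]]:
    """One single-covariate Cox fit per feature; keep ``p < alpha``.

    Returns the per-feature report (coef, HR, CI, p) and the selected
    feature names.  Degenerate or non-converging features are reported
    with NaN p and never selected.
    """
    time, event = _check_survival(time, event)
    rows = []
    for col in features.columns:
        try:
            fit = cox_fit(features[[col]], time, event)
            row = fit.summary.loc[col].to_dict()
            if not fit.converged:
                row["p"] = np.nan
        except (ValueError, RuntimeError):
            row = dict(coef=np.nan, hr=np.nan, ci_lower=np.nan, ci_upper=np.nan, p=np.nan)
        row["feature"] = col
        rows.append(row)
    report = pd.DataFrame(
        rows, columns=["feature", "coef", "hr", "ci_lower", "ci_upper", "p"]
    ).set_index("feature")
    selected = list(report.index[report["p"] < alpha])
    return report, selected


def vif_screen(design: pd.DataFrame, threshold: float = 10.0) -> pd.DataFrame:
    """Variance inflation factors, ``VIF_j = 1 / (1 - R^2_j)``.

    Each feature is regressed (with intercept) on all the others; features
    with VIF above ``threshold`` are flagged, perfectly collinear columns
    get infinite VIF.
    """
    design = pd.DataFrame(design).astype(float)
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least two features")
    X = design.to_numpy()
    n = X.shape[0]
    vifs = []
    for j in range(X.shape[1]):
        y = X[:, j]
        others = np.c_[np.ones(n), np.delete(X, j, axis=1)]
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            vifs.append(np.inf)
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        vifs.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    out = pd.DataFrame({"vif": vifs}, index=design.columns)
    out.index.name = "feature"
    out["flagged"] = out["vif"] > threshold
    return out


@dataclass(frozen=True)
class StepwiseResult:
    fit: CoxFit
    selected: tuple[str, ...]
    path: tuple[tuple[str, str, float], ...]  # (action, feature, aic)


def stepwise_aic(
    candidates: pd.DataFrame, time, event, verbose: bool = False
) -> StepwiseResult:
    """Bidirectional stepwise Cox selection minimizing AIC.

    Starts from the full candidate set; at every step evaluates all single
    removals and additions and applies the move with the lowest AIC,
    stopping when no move improves it.  Deterministic given column order.
    Candidate models that fail to fit (too few events, separation) are
    skipped.
    """
    time, event = _check_survival(time, event)
    candidates = pd.DataFrame(candidates).astype(float)
    all_feats = list(candidates.columns)

    def fit_set(feats: list[str]) -> CoxFit | None:
        if not feats:
            return _null_fit(time, event)
        try:
            return cox_fit(candidates[feats], time, event)
        except (ValueError, RuntimeError):
            return None

    current = list(all_feats)
    fit = fit_set(current)
    while fit is None and current:  # full model unfittable: shrink from the back
        current = current[:-1]
        fit = fit_set(current)
    assert fit is not None
    path: list[tuple[str, str, float]] = [("start", "+".join(current) or "-", fit.aic)]
    while True:
        moves: list[tuple[float, str, str, CoxFit, list[str]]] = []
        for f in current:
            trial = [c for c in current if c != f]
            tf = fit_set(trial)
            if tf is not None:
                moves.append((tf.aic, "remove", f, tf, trial))
        for f in all_feats:
            if f in current:
                continue
            trial = current + [f]
            tf = fit_set(trial)
            if tf is not None:
                moves.append((tf.aic, "add", f, tf, trial))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        best_aic, action, feat, best_fit, best_set = moves[0]
        if best_aic >= fit.aic - 1e-12:
            break
        current, fit = best_set, best_fit
        path.append((action, feat, best_aic))
        if verbose:
            print(f"stepwise: {action} {feat} -> AIC {best_aic:.3f}")
    return StepwiseResult(fit, tuple(current), tuple(path))


def risk_score(fit: CoxFit, features: pd.DataFrame) -> pd.Series:
    """Linear predictor ``sum_j beta_j x_j`` of a fitted Cox model."""
    features = pd.DataFrame(features)
    missing = [c for c in fit.covariates if c not in features.columns]
    if missing:
        raise KeyError(f"features missing from input: {missing}")
    if not fit.covariates:
        return pd.Series(0.0, index=features.index, name="risk_score")
    X = features[fit.covariates].astype(float)
    score = X.to_numpy() @ fit.summary["coef"].to_numpy()
    return pd.Series(score, index=features.index, name="risk_score")


# ---------------------------------------------------------------------------
# time-dependent ROC


@dataclass(frozen=True)
class TdROC:
    horizons: np.ndarray
    auroc: np.ndarray
    n_cases: np.ndarray
    n_controls: np.ndarray
    flags: tuple[str, ...] = ()


def time_dependent_auroc(score, time, event, horizons: Sequence[float]) -> TdROC:
    """Cumulative-case / dynamic-control AUC with IPCW at each horizon.

    At horizon ``t``, cases are subjects with an observed event by ``t``
    and controls are subjects still under observation beyond ``t``.  Cases
    are weighted by the inverse of the Kaplan-Meier estimate of the
    censoring survival function at their event time (left limit), which
    corrects for informatively thinner case sets under censoring; tied
    scores count one half.  Horizons with no cases or no controls yield
    NaN and a flag.
    """
    time, event = _check_survival(time, event)
    score = np.asarray(score, dtype=float)
    if score.shape != time.shape:
        raise ValueError("score must match time/event in length")
    horizons = np.asarray(list(horizons), dtype=float)
    if np.any(horizons <= 0):
        raise ValueError("horizons must be positive")
    G = km_estimate(time, 1 - event)  # censoring distribution
    g_left = G.survival_at(time, left=True)
    aucs, ncase, nctrl, flags = [], [], [], []
    for h in horizons:
        case = (time <= h) & (event == 1)
        ctrl = time > h
        ncase.append(int(case.sum()))
        nctrl.append(int(ctrl.sum()))
        if not case.any() or not ctrl.any():
            flags.append(f"horizon {h}: no cases or no controls")
            aucs.append(np.nan)
            continue
        w = 1.0 / g_left[case]
        if not np.isfinite(w).all():
            # cases at times where censoring KM hit zero: drop with flag
            flags.append(f"horizon {h}: dropped cases with zero censoring weight")
            keep = np.isfinite(w)
            w = w[keep]
            case_scores = score[case][keep]
        else:
            case_scores = score[case]
        ctrl_scores = score[ctrl]
        diff = case_scores[:, None] - ctrl_scores[None, :]
        conc = (diff > 0).astype(float) + 0.5 * (diff == 0)
        num = float((w[:, None] * conc).sum())
        den = float(w.sum() * len(ctrl_scores))
        aucs.append(num / den)
    return TdROC(
        horizons,
        np.asarray(aucs),
        np.asarray(ncase),
        np.asarray(nctrl),
        tuple(flags),
    )
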