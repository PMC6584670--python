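"""End-to-end orchestration: cohort -> summaries -> cutpoints -> Cox -> ROC.

``run_pipeline`` executes the full analysis on either a freshly generated
synthetic cohort or user-supplied long-format feature/outcome tables,
writing every intermediate table as CSV into the run directory together
with the serialized configuration, a plain-text log and a summary report.
All randomness flows from the seed in the configuration, so a rerun with
the same config produces byte-identical numeric tables.

Stage order: generate/ingest, longitudinal summaries, per-marker optimal
log-rank cutpoints, univariate Cox screen, VIF collinearity check,
bidirectional stepwise-AIC Cox selection, linear-predictor risk score,
time-dependent AUROC at the requested horizons.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import longitudinal as lg
from . import survival as sv
from . import synthetic as syn

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "validate_inputs", "ValidationReport"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run; every field has a recorded default."""

    mode: str = "synthetic"  # "synthetic" | "feature-table" | "voxel"
    outdir: str = "deltarad_run"
    seed: int = 0
    # synthetic mode
    n_patients: int = 200
    # feature-table mode
    trajectories_csv: str | None = None
    outcomes_csv: str | None = None
    # voxel mode: NIfTI lesion manifest (patient_id, time_months, lesion_id,
    # image_path, mask_path) plus outcomes_csv
    manifest_csv: str | None = None
    inner_margin_mm: float = 2.0
    # analysis options
    normalize: bool = True
    zero_increment: str = "subtract"
    min_group_frac: float = 0.1
    alpha: float = 0.05
    vif_threshold: float = 10.0
    horizons: tuple[float, ...] = (12.0, 36.0)
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "feature-table", "voxel"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "feature-table" and (
            self.trajectories_csv is None or self.outcomes_csv is None
        ):
            raise ValueError("feature-table mode needs trajectories_csv and outcomes_csv")
        if self.mode == "voxel" and (
            self.manifest_csv is None or self.outcomes_csv is None
        ):
            raise ValueError("voxel mode needs manifest_csv and outcomes_csv")
        if any(h <= 0 for h in self.horizons):
            raise ValueError("horizons must be positive months")


@dataclass
class PipelineResult:
    outdir: Path
    summaries: pd.DataFrame
    cutpoints: pd.DataFrame
    univariate: pd.DataFrame
    selected_univariate: list[str]
    vif: pd.DataFrame | None
    stepwise: sv.StepwiseResult
    significant_fit: sv.CoxFit | None
    risk_scores: pd.Series
    tdroc: sv.TdROC


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[dict, ...]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_inputs(trajectories_csv, outcomes_csv) -> ValidationReport:
    """Schema and consistency checks on the two input tables.

    Violations are collected, never raised: missing columns, duplicated
    time points, non-baseline-anchored trajectories, nonpositive survival
    times, non-binary event indicators, and patients present in one table
    but not the other.
    """
    v: list[dict] = []
    traj = pd.read_csv(trajectories_csv)
    outc = pd.read_csv(outcomes_csv)
    for col in lg.REQUIRED_COLUMNS:
        if col not in traj.columns:
            v.append(dict(table="trajectories", check="column", detail=col))
    for col in ("patient_id", "time_months", "event"):
        if col not in outc.columns:
            v.append(dict(table="outcomes", check="column", detail=col))
    if v:
        return ValidationReport(tuple(v))
    for (pid, feat), grp in traj.groupby(["patient_id", "feature"]):
        t = grp["time_months"].to_numpy(float)
        if len(np.unique(t)) != len(t):
            v.append(dict(table="trajectories", check="duplicate_time", detail=f"{pid}/{feat}"))
        if t.min() != 0:
            v.append(dict(table="trajectories", check="missing_baseline", detail=f"{pid}/{feat}"))
        if len(t) < 2:
            v.append(dict(table="trajectories", check="too_few_points", detail=f"{pid}/{feat}"))
    if (outc["time_months"] <= 0).any():
        bad = outc.loc[outc["time_months"] <= 0, "patient_id"].tolist()
        v.append(dict(table="outcomes", check="nonpositive_time", detail=str(bad)))
    if not outc["event"].isin([0, 1]).all():
        v.append(dict(table="outcomes", check="event_not_binary", detail=""))
    tp, op = set(traj["patient_id"].astype(str)), set(outc["patient_id"].astype(str))
    for pid in sorted(tp - op):
        v.append(dict(table="outcomes", check="missing_patient", detail=pid))
    for pid in sorted(op - tp):
        v.append(dict(table="trajectories", check="missing_patient", detail=pid))
    return ValidationReport(tuple(v))


def _marker_table(
    traj_df: pd.DataFrame, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidate continuous markers: baseline value and AUC2 per feature."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        summaries = lg.summary_table(
            traj_df, normalize=config.normalize, zero_increment=config.zero_increment
        )
    baselines = lg.baseline_table(traj_df)
    markers = baselines.join(summaries[[c for c in summaries.columns if c.endswith("_auc2")]])
    return summaries, markers


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and write all outputs into ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, default=list)

    # --- stage: generate / ingest -----------------------------------------
    if config.mode == "synthetic":
        spec = syn.CohortSpec(n_patients=config.n_patients, seed=config.seed)
        cohort = syn.generate_cohort(spec)
        syn.write_cohort(cohort, outdir, spec)
        traj_df, outcome_df, _truth = syn.cohort_to_frames(cohort)
        log(f"generated synthetic cohort: {len(cohort)} patients (seed {config.seed})")
    elif config.mode == "voxel":
        from .features import feature_table_from_manifest

        per_lesion, traj_df = feature_table_from_manifest(
            config.manifest_csv, inner_margin_mm=config.inner_margin_mm
        )
        per_lesion.to_csv(outdir / "lesion_features.csv", index=False)
        traj_df.to_csv(outdir / "trajectories.csv", index=False)
        outcome_df = pd.read_csv(config.outcomes_csv)
        log(
            f"extracted features for {per_lesion['patient_id'].nunique()} patients "
            f"({len(per_lesion)} lesion-feature rows)"
        )
    else:
        traj_df = pd.read_csv(config.trajectories_csv)
        outcome_df = pd.read_csv(config.outcomes_csv)
        report = validate_inputs(config.trajectories_csv, config.outcomes_csv)
        if not report.ok:
            raise ValueError(f"input validation failed: {report.violations}")
        log(f"ingested feature tables: {outcome_df.shape[0]} patients")
    traj_df["patient_id"] = traj_df["patient_id"].astype(str)
    outcome_df["patient_id"] = outcome_df["patient_id"].astype(str)
    outcome_df = outcome_df.set_index("patient_id").sort_index()

    # --- stage: longitudinal summaries ------------------------------------
    summaries, markers = _marker_table(traj_df, config)
    order = summaries.index
    if not order.equals(outcome_df.index):
        raise ValueError("patient sets of trajectories and outcomes differ")
    time_arr = outcome_df["time_months"].to_numpy(float)
    event_arr = outcome_df["event"].to_numpy(int)
    summaries.to_csv(outdir / "summaries.csv")
    log(f"summaries: {summaries.shape[1]} columns for {summaries.shape[0]} patients")

    # --- stage: optimal cutpoints -----------------------------------------
    cut_rows, dichot = [], {}
    for col in markers.columns:
        m = markers[col].to_numpy(float)
        if np.isnan(m).any():
            log(f"cutpoint: skipped {col} (missing values)")
            continue
        try:
            cut = sv.optimal_cutpoint(m, time_arr, event_arr, config.min_group_frac)
        except ValueError as exc:
            log(f"cutpoint: skipped {col} ({exc})")
            continue
        cut_rows.append(
            dict(
                marker=col,
                cutoff=cut.cutoff,
                logrank_chi2=cut.logrank_chi2,
                p=cut.p,
                n_low=cut.group_sizes[0],
                n_high=cut.group_sizes[1],
            )
        )
        dichot[col] = (m > cut.cutoff).astype(float)
    cutpoints = pd.DataFrame(
        cut_rows, columns=["marker", "cutoff", "logrank_chi2", "p", "n_low", "n_high"]
    ).set_index("marker")
    cutpoints.to_csv(outdir / "cutpoints.csv")
    dichot_df = pd.DataFrame(dichot, index=order)
    dichot_df.to_csv(outdir / "dichotomized.csv")
    log(f"cutpoints: {len(cutpoints)} markers dichotomized")

    # --- stage: univariate screen ------------------------------------------
    univariate, selected = sv.univariate_screen(
        dichot_df, time_arr, event_arr, alpha=config.alpha
    )
    univariate.to_csv(outdir / "univariate.csv")
    log(f"univariate screen: {len(selected)}/{dichot_df.shape[1]} markers at p < {config.alpha}")

    # --- stage: VIF collinearity check -------------------------------------
    vif_report = None
    candidates = list(selected)
    if len(candidates) >= 2:
        while True:
            vif_report = sv.vif_screen(dichot_df[candidates], config.vif_threshold)
            flagged = vif_report[vif_report["flagged"]]
            if flagged.empty or len(candidates) <= 2:
                break
            worst = flagged["vif"].idxmax()
            candidates.remove(worst)
            log(f"vif: dropped {worst} (VIF {flagged.loc[worst, 'vif']:.1f})")
        vif_report.to_csv(outdir / "vif.csv")
    log(f"vif: {len(candidates)} candidates enter stepwise selection")

    # --- stage: stepwise AIC ------------------------------------------------
    stepwise = sv.stepwise_aic(dichot_df[candidates], time_arr, event_arr)
    pd.DataFrame(stepwise.path, columns=["action", "feature", "aic"]).to_csv(
        outdir / "stepwise_path.csv", index=False
    )
    stepwise.fit.summary.to_csv(outdir / "multivariate.csv")
    log(
        "stepwise: selected "
        + (", ".join(stepwise.selected) if stepwise.selected else "(null model)")
        + f"; AIC {stepwise.fit.aic:.3f}"
    )

    # refit on the significant subset of the stepwise model (reported both)
    significant_fit = None
    sig = list(stepwise.fit.summary.index[stepwise.fit.summary["p"] < config.alpha])
    if sig and set(sig) != set(stepwise.selected):
        try:
            significant_fit = sv.cox_fit(dichot_df[sig], time_arr, event_arr)
            significant_fit.summary.to_csv(outdir / "multivariate_significant.csv")
            log(f"significant-only refit: {', '.join(sig)}")
        except (ValueError, RuntimeError) as exc:
            log(f"significant-only refit failed: {exc}")

    # --- stage: risk score and time-dependent ROC ---------------------------
    scores = sv.risk_score(stepwise.fit, dichot_df)
    scores.to_csv(outdir / "risk_scores.csv")
    if scores.nunique() > 1:
        tdroc = sv.time_dependent_auroc(
            scores.to_numpy(), time_arr, event_arr, config.horizons
        )
    else:
        tdroc = sv.TdROC(
            np.asarray(config.horizons),
            np.full(len(config.horizons), np.nan),
            np.zeros(len(config.horizons), int),
            np.zeros(len(config.horizons), int),
            ("degenerate risk score",),
        )
    auroc_df = pd.DataFrame(
        dict(
            horizon_months=tdroc.horizons,
            auroc=tdroc.auroc,
            n_cases=tdroc.n_cases,
            n_controls=tdroc.n_controls,
        )
    )
    auroc_df.to_csv(outdir / "auroc.csv", index=False)
    for h, a in zip(tdroc.horizons, tdroc.auroc):
        log(f"time-dependent AUROC at {h:g} months: {a:.3f}")

    if config.make_plots:
        _write_plots(outdir, dichot_df, cutpoints, time_arr, event_arr, auroc_df)

    # --- report -------------------------------------------------------------
    log("done")
    (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    _write_report(outdir, config, cutpoints, univariate, selected, stepwise, tdroc)
    return PipelineResult(
        outdir,
        summaries,
        cutpoints,
        univariate,
        selected,
        vif_report,
        stepwise,
        significant_fit,
        scores,
        tdroc,
    )


def _write_plots(outdir, dichot_df, cutpoints, time_arr, event_arr, auroc_df) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    marker = "volume_auc2" if "volume_auc2" in dichot_df.columns else None
    if marker is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        for label, grp in [("low", 0.0), ("high", 1.0)]:
            sel = dichot_df[marker].to_numpy() == grp
            if sel.sum() == 0:
                continue
            km = sv.km_estimate(time_arr[sel], event_arr[sel])
            ax.step(
                np.r_[0, km.times],
                np.r_[1.0, km.survival],
                where="post",
                label=f"{marker} {label} (n={sel.sum()})",
            )
        ax.set_xlabel("months")
        ax.set_ylabel("overall survival")
        ax.set_ylim(0, 1.02)
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / "km_volume_auc2.png", dpi=120)
        plt.close(fig)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(auroc_df["horizon_months"], auroc_df["auroc"], "o-")
    ax.axhline(0.5, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("horizon (months)")
    ax.set_ylabel("AUROC")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(outdir / "auroc.png", dpi=120)
    plt.close(fig)


def _write_report(outdir, config, cutpoints, univariate, selected, stepwise, tdroc) -> None:
    lines = [
        "deltarad pipeline report",
        "========================",
        f"mode: {config.mode}   seed: {config.seed}",
        "",
        f"markers dichotomized: {len(cutpoints)}",
        f"univariate-selected (p < {config.alpha}): {len(selected)}",
        f"stepwise model: {', '.join(stepwise.selected) or '(null)'}",
        f"stepwise AIC: {stepwise.fit.aic:.3f}",
        "",
        "multivariate hazard ratios:",
    ]
    for feat, row in stepwise.fit.summary.iterrows():
        lines.append(
            f"  {feat}: HR {row['hr']:.3f} (95% CI {row['ci_lower']:.3f}-"
            f"{row['ci_upper']:.3f}), p = {row['p']:.4f}"
        )
    lines.append("")
    for h, a in zip(tdroc.horizons, tdroc.auroc):
        lines.append(f"AUROC at {h:g} months: {a:.3f}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
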