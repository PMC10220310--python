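"""End-to-end pipeline: simulate -> prep -> fit -> decode -> metrics ->
associate, with a YAML config, a reproducibility manifest, and a text
report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import metrics as met
from . import prep
from .hsmm import HSMMParams, decode_epoch_series, hsmm_fit, order_and_group
from .synthetic import SyntheticCohort, SyntheticConfig, generate_cohort

logger = logging.getLogger("actikid")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str = "actikid_run"
    # input: either simulate a synthetic cohort or point at existing data
    simulate: bool = True
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    traces_dir: str | None = None
    cohort_csv: str | None = None
    epoch_seconds: float = 1.0
    # preprocessing
    nonwear_minutes: float = 60.0
    movement_threshold: float | None = None
    min_day_hours: float = 5.0
    max_window_days: int = 7
    min_valid_days: int = 3
    # segmentation
    n_states: int = 6
    max_duration: int = 600
    n_restarts: int = 2
    tol: float = 1e-5
    max_iter: int = 50
    fit_max_epochs: int = 200_000
    log1p: bool = False
    # metrics
    cutpoint: float = 40.0
    cutpoint_epoch_seconds: float = 5.0
    guideline_minutes: float = 180.0
    guideline_rule: str = "mean"
    diurnal_bin_minutes: float = 10.0
    # association
    screen_alpha: float = 0.2
    seed: int = 0
    write_traces: bool = True

    def __post_init__(self):
        for name in (
            "nonwear_minutes",
            "min_day_hours",
            "max_window_days",
            "min_valid_days",
            "n_states",
            "max_duration",
            "cutpoint",
            "guideline_minutes",
            "epoch_seconds",
        ):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def select_predictors(table: pd.DataFrame, outcome: str, alpha: float, seed: int):
    """Screening stage for one activity outcome: Spearman rank correlation
    for child/family/environment factors, and for each parent-action item a
    two-predictor model adjusting for mobility; candidates with p <= alpha
    are carried into the multivariable model (mobility always retained)."""
    non_pa = [
        c
        for c in assoc.DEFAULT_CANDIDATES
        if c in table.columns and not c.startswith("parent_action_")
    ]
    screen = assoc.spearman_screen(table, outcome, candidates=non_pa, alpha=alpha, seed=seed)
    selected = [t for t in screen.index if screen.loc[t, "selected"]]
    pa_rows = []
    for item in assoc.PARENT_ACTION_COLUMNS:
        if item not in table.columns:
            continue
        try:
            res = assoc.parent_action_model(table, outcome, item)
        except assoc.AssociationError:
            continue
        p = float(res.table.loc[item, "p"])
        pa_rows.append({"term": item, "p": p, "selected": p <= alpha})
        if p <= alpha:
            selected.append(item)
    if "mobility" not in selected and "mobility" in table.columns:
        selected.insert(0, "mobility")
    return selected, screen, pd.DataFrame(pa_rows)


@dataclass
class PipelineResult:
    manifest: dict
    summary: pd.DataFrame
    cohort_table: pd.DataFrame
    models: dict  # outcome -> RegressionResult
    model_params: HSMMParams
    cohort: SyntheticCohort | None = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order, writing results and a manifest under
    ``config.out_dir``. Any stage failure raises a stage-labelled error."""
    out = str(config.out_dir)
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "schema": "actikid-run/1",
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
    }

    # ---- stage: input -----------------------------------------------------
    cohort = None
    if config.simulate:
        syn_kwargs = dict(config.synthetic)
        syn_kwargs.setdefault("epoch_seconds", config.epoch_seconds)
        syn_kwargs.setdefault("seed", config.seed)
        syn = SyntheticConfig(**syn_kwargs)
        cohort = generate_cohort(syn, out_dir=out if config.write_traces else None)
        traces = cohort.traces
        table = cohort.table.copy()
        manifest["stages"]["simulate"] = {
            "n_children": syn.n_children,
            "n_days": syn.n_days,
            "epoch_seconds": syn.epoch_seconds,
        }
    else:
        if not config.traces_dir or not config.cohort_csv:
            raise PipelineError("input stage: traces_dir and cohort_csv required when simulate=False")
        paths = sorted(
            os.path.join(config.traces_dir, f)
            for f in os.listdir(config.traces_dir)
            if f.endswith(".csv")
        )
        if not paths:
            raise PipelineError(f"input stage: no trace CSVs in {config.traces_dir}")
        traces = [prep.read_epoch_series(p, config.epoch_seconds) for p in paths]
        table = pd.read_csv(config.cohort_csv)

    # ---- stage: prep ------------------------------------------------------
    prepped = {}
    for series in traces:
        mask = prep.detect_non_wear(
            series, config.nonwear_minutes, config.movement_threshold
        )
        days = prep.summarize_days(series, mask, config.min_day_hours)
        selection = prep.select_recording(
            days, config.max_window_days, config.min_valid_days
        )
        prepped[series.child_id] = (series, mask, selection)
    eligible = {cid: v for cid, v in prepped.items() if v[2].eligible}
    manifest["stages"]["prep"] = {
        "n_traces": len(prepped),
        "n_eligible": len(eligible),
    }
    if not eligible:
        raise PipelineError("prep stage: no eligible recordings (check thresholds)")

    # ---- stage: fit -------------------------------------------------------
    segments = []
    for series, mask, _ in eligible.values():
        segments.extend(prep.wear_segments(series, mask))
    params, diag = hsmm_fit(
        segments,
        n_states=config.n_states,
        max_duration=config.max_duration,
        tol=config.tol,
        max_iter=config.max_iter,
        n_restarts=config.n_restarts,
        seed=config.seed,
        max_epochs=config.fit_max_epochs,
        log1p=config.log1p,
    )
    model_path = os.path.join(out, "model.json")
    params.save(model_path)
    manifest["stages"]["fit"] = {
        "n_epochs": diag.n_epochs,
        "loglik": diag.loglik_path[-1],
        "n_iter": diag.n_iter,
        "converged": diag.converged,
        "restart": diag.restart,
    }

    # ---- stage: decode + metrics -----------------------------------------
    rows = []
    sequences = []
    for cid, (series, mask, selection) in eligible.items():
        states = decode_epoch_series(series.magnitudes, mask.wear, params)
        cats = order_and_group(states)
        seq = met.IntensitySequence(
            child_id=cid,
            start_time=series.start_time,
            epoch_seconds=series.epoch_seconds,
            labels=cats,
        )
        sequences.append(seq)
        summary = met.summarize_activity(seq, selection)
        mean_mins, per_day = met.cutpoint_active_minutes(
            series,
            mask,
            selection,
            cutpoint=config.cutpoint,
            agg_seconds=config.cutpoint_epoch_seconds,
        )
        summary.cutpoint_active_mins_per_day = mean_mins
        summary.meets_guideline = met.meets_who_guideline(
            per_day, config.guideline_minutes, config.guideline_rule
        )
        rows.append(dataclasses.asdict(summary))
    summary_df = pd.DataFrame(rows)
    summary_df.to_csv(os.path.join(out, "summary.csv"), index=False)
    profile = met.diurnal_profile(sequences, config.diurnal_bin_minutes)
    profile.to_long().to_csv(os.path.join(out, "diurnal.csv"), index=False)
    manifest["stages"]["metrics"] = {
        "n_children": len(summary_df),
        "mean_wear_hours": float(summary_df.wear_hours_per_day.mean()),
        "mean_prop_active": float(summary_df.prop_active.mean()),
        "mean_prop_intense": float(summary_df.prop_intense.mean()),
        "guideline_compliance": float(summary_df.meets_guideline.mean()),
    }

    # ---- stage: associate -------------------------------------------------
    table = table.merge(
        summary_df[["child_id", "prop_active", "prop_intense"]], on="child_id"
    )
    item_cols = [c for c in table.columns if c.startswith("pedsql_item_")]
    if item_cols:
        # children whose whole questionnaire is absent get NaN silently;
        # partially answered ones go through the min-answered rule
        table["pedsql_total"] = [
            np.nan
            if np.all(~np.isfinite(row))
            else assoc.pedsql_total(row)
            for row in table[item_cols].to_numpy(dtype=float)
        ]
    models = {}
    screens = {}
    for outcome in ("prop_active", "prop_intense"):
        selected, screen, pa_screen = select_predictors(
            table, outcome, config.screen_alpha, config.seed
        )
        screens[outcome] = {
            "screen": screen,
            "parent_actions": pa_screen,
            "selected": selected,
        }
        models[outcome] = assoc.fit_multivariable(table, outcome, selected)
    if item_cols and table["pedsql_total"].notna().sum() >= 20:
        try:
            models["pedsql_total"] = assoc.hrqol_model(table)
        except assoc.AssociationError as exc:
            manifest["stages"]["hrqol_skipped"] = str(exc)
    tidy = pd.concat([m.to_tidy() for m in models.values()], ignore_index=True)
    tidy.to_csv(os.path.join(out, "model_terms.csv"), index=False)
    model_level = {
        name: {
            "n_used": m.n_used,
            "r_squared": m.r_squared,
            "adj_r_squared": m.adj_r_squared,
            "condition_number": m.condition_number,
            "predictors": list(m.table.index),
        }
        for name, m in models.items()
    }
    with open(os.path.join(out, "model_fit.json"), "w") as fh:
        json.dump(model_level, fh, indent=1)
    table.to_csv(os.path.join(out, "cohort_outcomes.csv"), index=False)
    manifest["stages"]["associate"] = model_level

    # ---- manifest ---------------------------------------------------------
    for name in sorted(os.listdir(out)):
        path = os.path.join(out, name)
        if os.path.isfile(path) and name != "run_manifest.json":
            manifest["outputs"][name] = _sha256(path)
    with open(os.path.join(out, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return PipelineResult(
        manifest=manifest,
        summary=summary_df,
        cohort_table=table,
        models=models,
        model_params=params,
        cohort=cohort,
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def report(result_or_dir) -> str:
    """Human-readable run summary: cohort means/SDs, guideline compliance,
    and one table per fitted model (term, beta, 95% CI, p, r_s^2)."""
    if isinstance(result_or_dir, PipelineResult):
        manifest = result_or_dir.manifest
        summary = result_or_dir.summary
        tidy = pd.concat(
            [m.to_tidy() for m in result_or_dir.models.values()], ignore_index=True
        )
        model_level = manifest["stages"]["associate"]
    else:
        out = str(result_or_dir)
        with open(os.path.join(out, "run_manifest.json")) as fh:
            manifest = json.load(fh)
        if "associate" not in manifest.get("stages", {}):
            raise PipelineError("incomplete manifest: associate stage missing")
        summary = pd.read_csv(os.path.join(out, "summary.csv"))
        tidy = pd.read_csv(os.path.join(out, "model_terms.csv"))
        model_level = manifest["stages"]["associate"]
    lines = []
    lines.append("activity analysis run report")
    lines.append("=" * 60)
    lines.append(f"children analysed: {len(summary)}")

    def ms(col):
        return f"{summary[col].mean():.2f} (SD {summary[col].std(ddof=1):.2f})"

    lines.append(f"wear time, h/day:          {ms('wear_hours_per_day')}")
    lines.append(f"active (states 2-5), h/day: {ms('active_hours_per_day')}")
    lines.append(f"intense (states 4-5), h/day: {ms('intense_hours_per_day')}")
    lines.append(
        f"proportion of wear active:  {summary.prop_active.mean():.3f}"
        f" (SD {summary.prop_active.std(ddof=1):.3f})"
    )
    lines.append(
        f"proportion of wear intense: {summary.prop_intense.mean():.3f}"
        f" (SD {summary.prop_intense.std(ddof=1):.3f})"
    )
    lines.append(
        f"meeting guideline:          {summary.meets_guideline.mean():.17g}"
    )
    for outcome, info in model_level.items():
        lines.append("")
        lines.append(
            f"model: {outcome}  (n = {info['n_used']}, R^2 = {info['r_squared']:.2f}, "
            f"adj = {info['adj_r_squared']:.2f}, condition number = "
            f"{info['condition_number']:.2f})"
        )
        lines.append(f"{'term':<22}{'beta':>8}{'ci_low':>9}{'ci_high':>9}{'p':>8}{'rs2':>7}")
        sub = tidy[tidy.outcome == outcome]
        for _, r in sub.iterrows():
            lines.append(
                f"{r.term:<22}{r.beta:>8.2f}{r.ci_low:>9.2f}{r.ci_high:>9.2f}"
                f"{r.p:>8.3f}{r.rs2:>7.2f}"
            )
    return "\n".join(lines) + "\n"
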