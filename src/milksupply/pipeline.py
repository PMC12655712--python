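"""End-to-end orchestration: simulate/ingest -> derive -> classify ->
thresholds -> risk models -> reports.

Every stochastic stage receives its own child seed spawned deterministically
from the master seed, so a stage can be rerun in isolation and a rerun of
the whole pipeline is byte-identical. The manifest collects every headline
number, a flow-accounting funnel (eligible -> excluded -> analysed), the
per-stage seeds, and a hash of the configuration.
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
import yaml

from . import measures, profiles, risk, roc, stats, synthetic
from .errors import MilkSupplyError
from .growth import GrowthReference

log = logging.getLogger(__name__)

LEGACY_MP_THRESHOLD = 600.0  # previously proposed mL/24 h cut-off


@dataclass
class PipelineConfig:
    """Everything a full run needs; YAML-loadable."""

    n_dyads: int = 460
    seed: int = 0
    k_range: tuple[int, int] = (1, 5)       # inclusive
    entropy_min: float = 0.8
    posterior_min: float = 0.5
    min_class_share: float = 0.05
    blrt_reps: int = 99
    n_restarts: int = 20
    n_restarts_boot: int = 2
    bootstrap_B: int = 200
    retention_threshold: float = 0.5
    roc_min_subgroup: int = 20
    composites: tuple = (
        ("ow", "advanced_age"),
        ("minimal_breast_growth", "advanced_age"),
    )
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        if "composites" in raw:
            raw["composites"] = tuple(tuple(c) for c in raw["composites"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: PipelineConfig | None = None, **overrides) -> dict:
    """Run the full analysis on a synthetic cohort; returns the bundle.

    The bundle maps stage names to their tabular results plus a ``manifest``
    dict of headline numbers. If ``config.outdir`` is set, all tables and
    the manifest are also written there.
    """
    config = config or PipelineConfig()
    if overrides:
        config = dataclasses.replace(config, **overrides)
    seeds = _stage_seeds(config.seed, ["cohort", "lpa", "risk"])
    manifest: dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": {},
        "funnel": {},
    }
    bundle: dict = {"manifest": manifest, "config": config}

    # --- simulate -----------------------------------------------------
    spec = synthetic.CohortSpec(n_dyads=config.n_dyads, seed=seeds["cohort"])
    cohort, diaries, truth = synthetic.generate_cohort(spec)
    ref = GrowthReference.bundled()
    manifest["funnel"]["eligible"] = len(cohort)
    manifest["stages"]["simulate"] = "ok"

    # --- derive -------------------------------------------------------
    derived = measures.derive_measures(cohort, diaries, ref)
    excluded = int(derived["mp_24h"].isna().sum())
    manifest["funnel"]["excluded_invalid_diary"] = excluded
    manifest["funnel"]["analysed"] = len(derived) - excluded
    bundle["cohort"] = derived
    bundle["ground_truth"] = truth
    desc = stats.descriptive_table(
        derived,
        ["maternal_age", "bmi", "bv_change", "mp_24h", "total_intake_24h",
         "breastmilk_intake_24h", "formula_intake_24h", "waz_current",
         "delta_waz", "avg_daily_gain", *measures.RISK_FACTOR_COLUMNS],
    )
    bundle["descriptives"] = desc
    manifest["stages"]["derive"] = "ok"
    manifest["mp_mean"] = float(derived["mp_24h"].mean())
    manifest["mp_sd"] = float(derived["mp_24h"].std())
    manifest["fully_breastfeeding_pct"] = stats.percent(
        int((derived["formula_intake_24h"] == 0).sum()), len(derived)
    )

    # --- classify -----------------------------------------------------
    im = profiles.prepare_indicators(derived)
    criteria = profiles.SelectionCriteria(
        entropy_min=config.entropy_min, posterior_min=config.posterior_min,
        min_class_share=config.min_class_share,
    )
    report = profiles.select_model(
        im, range(config.k_range[0], config.k_range[1] + 1), seed=seeds["lpa"],
        criteria=criteria, n_restarts=config.n_restarts,
        n_boot=config.blrt_reps, n_restarts_boot=config.n_restarts_boot,
    )
    bundle["model_selection"] = report
    manifest["selected_k"] = report.selected_k
    manifest["model_table"] = [
        {k: (v if not isinstance(v, (np.floating, np.bool_)) else v.item())
         for k, v in row.items()} for row in report.rows
    ]
    manifest["stages"]["classify"] = "ok"
    if report.selected_k is None or report.selected_k < 2:
        manifest["stages"]["thresholds"] = (
            "skipped: no multi-class solution, LMS grouping impossible"
        )
        manifest["stages"]["risks"] = "skipped: no LMS grouping"
        return _finalise(bundle, config)
    model = report.selected
    manifest["entropy"] = model.entropy
    manifest["bic"] = model.bic
    assignments = profiles.assign_and_group(model, im)
    bundle["assignments"] = assignments
    merged = derived.merge(assignments, on="dyad_id", how="inner")
    bundle["cohort_classified"] = merged
    if model.K == 4:
        counts = assignments["class_name"].value_counts().to_dict()
        manifest["class_counts"] = counts
        lms_n = int((assignments["group"] == "LMS").sum())
        manifest["lms_n"] = lms_n
        manifest["lms_share_pct"] = stats.percent(lms_n, len(assignments))
        manifest["nms_share_pct"] = stats.percent(
            len(assignments) - lms_n, len(assignments)
        )

    # --- thresholds ---------------------------------------------------
    if "group" in merged and merged["group"].notna().any():
        lms = merged["group"] == "LMS"
        curves = roc.predictor_panel(merged, lms, config.roc_min_subgroup)
        bundle["roc_panel"] = roc.panel_report(curves)
        for name, c in curves.items():
            manifest[f"auc_{name}"] = c.auc
            manifest[f"cutoff_{name}"] = c.optimal_threshold
        if "mp_24h" in curves:
            cmp_ = roc.compare_thresholds(
                merged["mp_24h"].to_numpy(float), lms.to_numpy(bool), roc.LOWER,
                LEGACY_MP_THRESHOLD, curves["mp_24h"].optimal_threshold,
                name="mp_24h",
            )
            bundle["threshold_comparison"] = cmp_
            manifest["mp_threshold_comparison"] = {
                "legacy_threshold": cmp_.threshold_a,
                "new_threshold": cmp_.threshold_b,
                "legacy_sens_spec_j": list(cmp_.metrics_a),
                "new_sens_spec_j": list(cmp_.metrics_b),
            }
        manifest["stages"]["thresholds"] = "ok"

        prev_tab, sig_tab = stats.class_prevalence_table(
            merged, "class_label", measures.RISK_FACTOR_COLUMNS
        )
        bundle["prevalence"] = prev_tab
        bundle["prevalence_significance"] = sig_tab

        # --- risks ------------------------------------------------------
        # the initial model: all ten candidate factors plus confounders
        try:
            initial = risk.fit_multinomial_df(
                merged, "class_label",
                measures.CONFOUNDER_COLUMNS + measures.RISK_FACTOR_COLUMNS,
                reference_level=1,
            )
            bundle["initial_odds_ratios"] = initial.report()
        except MilkSupplyError as exc:
            manifest["stages"]["initial_model"] = f"failed: {exc}"
        sel = risk.bootstrap_stability(
            merged, "class_label", measures.RISK_FACTOR_COLUMNS,
            measures.CONFOUNDER_COLUMNS, B=config.bootstrap_B,
            seed=seeds["risk"], reference_level=1,
            retention_threshold=config.retention_threshold,
        )
        bundle["stability"] = sel
        manifest["stability_frequencies"] = sel.frequencies
        manifest["retained_factors"] = sel.retained
        if sel.final_model is not None:
            or_tab = sel.final_model.report()
            bundle["odds_ratios"] = or_tab
            manifest["final_model_or"] = {
                f"class{r['outcome_level']}:{r['predictor']}": float(r["or"])
                for _, r in or_tab.iterrows() if r["predictor"] in sel.retained
            }
        composites = {}
        for a, b in config.composites:
            comp = risk.make_composite(merged[a], merged[b], name=f"{a}__{b}")
            try:
                m, info = risk.fit_composite_model(
                    merged, comp, sel.retained, measures.CONFOUNDER_COLUMNS,
                    source_flags=(a, b), outcome="class_label", reference_level=1,
                )
            except MilkSupplyError as exc:
                composites[comp.name] = {"error": str(exc)}
                continue
            composites[comp.name] = {
                "report": m.report().to_dict(orient="records"),
                **info,
            }
        manifest["composites"] = {
            name: {
                k: v for k, v in info.items() if k != "report"
            } for name, info in composites.items()
        }
        bundle["composite_models"] = composites
        manifest["stages"]["risks"] = "ok"

    return _finalise(bundle, config)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)


def _finalise(bundle: dict, config: PipelineConfig) -> dict:
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ["cohort", "descriptives", "assignments", "roc_panel",
                     "prevalence", "prevalence_significance", "odds_ratios",
                     "ground_truth"]:
            obj = bundle.get(name)
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(out / f"{name}.csv", index=False)
        if "model_selection" in bundle:
            bundle["model_selection"].to_frame().to_csv(
                out / "model_selection.csv", index=False
            )
        if "stability" in bundle:
            bundle["stability"].report().to_csv(out / "stability.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(bundle["manifest"], fh, indent=2, sort_keys=True,
                      default=_json_default)
    return bundle
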