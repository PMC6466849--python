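"""End-to-end pipeline: cohort -> imaging metrics -> deltas -> statistics.

``run_pipeline`` ties the stages together on a synthetic cohort: generate,
derive per-mouse-day metrics (ICG AUC, AUC C:P, FS/EF/SV/CO), form the
day-1 -> day-4 deltas, aggregate histology, summarise bioluminescence
flux, and run the group comparisons and biomarker correlations.  All
intermediate tables are written so any stage can be re-run or inspected,
and a manifest records seed, configuration hash and library versions so a
run is reproducible from the manifest alone.
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

from . import __version__
from .biodistribution import flux_change_table, merge_kidneys
from .cardiac import params_table
from .kinetics import RoiTrace, auc_cp_ratio, baseline_correct, compute_auc, session_delta
from .simulate import CohortBundle, CohortConfig, CohortNoise, SeverityModel, generate_cohort
from .stats import compare_groups, correlate, kidney_score_aggregate, liver_grade

log = logging.getLogger("multiorgan")

DELTA_METRICS = ("icg_auc", "auc_cp", "fs", "ef", "sv", "co")


@dataclass(frozen=True)
class RunConfig:
    """One reproducible pipeline run over a synthetic cohort."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    outdir: str = "results"
    baseline_window_s: float = 180.0
    volume_method: str = "teichholz"
    alpha: float = 0.05


def _trace(rec) -> RoiTrace:
    return RoiTrace(
        mouse_id=rec.mouse_id, day=rec.day, roi=rec.roi, times=rec.times, values=rec.values
    )


def compute_imaging_metrics(bundle: CohortBundle, baseline_window_s: float = 180.0) -> pd.DataFrame:
    """Per-mouse-day contrast-agent statistics from the cohort's ROI traces.

    The ICG AUC is the trapezoidal area under the baseline-corrected vessel
    trace from injection start to the end of the recording; AUC C:P is the
    cortex/pelvis AUC ratio over the same kind of window.
    """
    traces: dict[tuple[str, int, str], RoiTrace] = {
        (t.mouse_id, t.day, t.roi): _trace(t) for t in bundle.traces
    }
    t_inj = bundle.config.pk.injection_start_s
    rows = []
    for (mouse, day, roi), tr in traces.items():
        if roi != "vessel":
            continue
        corr = baseline_correct(tr, baseline_window_s)
        rows.append(
            {"mouse_id": mouse, "day": day, "metric": "icg_auc",
             "value": compute_auc(corr, start_s=t_inj)}
        )
        cortex = traces.get((mouse, day, "cortex"))
        pelvis = traces.get((mouse, day, "pelvis"))
        if cortex is not None and pelvis is not None:
            km = auc_cp_ratio(
                baseline_correct(cortex, baseline_window_s),
                baseline_correct(pelvis, baseline_window_s),
                start_s=t_inj,
            )
            if km.ratio_cp is None:
                raise ValueError(f"undefined AUC C:P for mouse {mouse} day {day} (pelvis AUC <= 0)")
            rows.append({"mouse_id": mouse, "day": day, "metric": "auc_cp", "value": km.ratio_cp})
    out = pd.DataFrame(rows).sort_values(["mouse_id", "day", "metric"]).reset_index(drop=True)
    return out


def compute_deltas(metrics: pd.DataFrame, groups: pd.DataFrame) -> pd.DataFrame:
    """Day-1 -> day-4 change of every metric per mouse (long format)."""
    wide = metrics.pivot_table(index=["mouse_id", "metric"], columns="day", values="value")
    rows = []
    for (mouse, metric), vals in wide.iterrows():
        if 1 not in vals.index or 4 not in vals.index or vals[[1, 4]].isna().any():
            raise ValueError(f"mouse {mouse!r} lacks both days for metric {metric!r}")
        d = session_delta(vals[1], vals[4], metric, mouse)
        rows.append(
            {"mouse_id": mouse, "metric": f"delta_{metric}", "day1": d.day1, "day4": d.day4,
             "delta": d.delta}
        )
    out = pd.DataFrame(rows)
    out = out.merge(groups[["mouse_id", "group"]], on="mouse_id", how="left")
    return out.sort_values(["metric", "mouse_id"]).reset_index(drop=True)


def aggregate_histology(histology: pd.DataFrame) -> pd.DataFrame:
    """Kidney mean field score and liver grade per mouse."""
    rows = []
    for _, row in histology.iterrows():
        fields = [row[f"field_{j}"] for j in range(1, 11)]
        rows.append(
            {
                "mouse_id": row["mouse_id"],
                "group": row["group"],
                "kidney_score": kidney_score_aggregate(fields),
                "liver_grade": liver_grade(row["liver_pct_area"]),
            }
        )
    return pd.DataFrame(rows)


def group_statistics(deltas: pd.DataFrame, biomarkers: pd.DataFrame,
                     histology_agg: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Group comparisons of every delta metric, biomarker and histology score."""
    rows = []

    def add(metric: str, by_group: dict) -> None:
        comp = compare_groups(by_group, metric=metric, alpha=alpha)
        base = {
            "metric": metric,
            "anova_f": comp.anova_f,
            "anova_p": comp.anova_p,
            "significant": comp.significant,
        }
        for g, m in comp.group_means.items():
            base[f"mean_{g}"] = m
        rows.append({**base, "pair": "", "p_adj": np.nan, "pair_significant": ""})
        for pw in comp.pairwise:
            rows.append(
                {**base, "pair": f"{pw.group_a} vs {pw.group_b}", "p_adj": pw.p_adj,
                 "pair_significant": bool(pw.significant)}
            )

    for metric, sub in deltas.groupby("metric", sort=True):
        add(metric, {g: s["delta"].to_numpy() for g, s in sub.groupby("group", sort=True)})
    for marker, sub in biomarkers.groupby("marker", sort=True):
        add(marker, {g: s["value"].to_numpy() for g, s in sub.groupby("group", sort=True)})
    for col in ("kidney_score", "liver_grade"):
        add(col, {g: s[col].to_numpy(dtype=float) for g, s in histology_agg.groupby("group", sort=True)})
    return pd.DataFrame(rows)


def correlation_statistics(metrics: pd.DataFrame, biomarkers: pd.DataFrame,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Day-4 imaging metric vs serum biomarker correlations (AUC C:P ~ BUN, ICG AUC ~ ALT)."""
    day4 = metrics[metrics["day"] == 4].pivot_table(index="mouse_id", columns="metric", values="value")
    bio = biomarkers.pivot_table(index="mouse_id", columns="marker", values="value")
    joined = day4.join(bio, how="inner")
    rows = []
    for x_m, y_m in (("auc_cp", "bun"), ("icg_auc", "alt")):
        sub = joined[[x_m, y_m]].dropna()
        res = correlate(sub[x_m], sub[y_m], x_metric=x_m, y_metric=y_m, alpha=alpha)
        rows.append(dataclasses.asdict(res))
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run generate -> metrics -> deltas -> stats; returns paths of the outputs.

    Deterministic under the cohort seed; any stage failure is re-raised
    with the stage name prepended.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    paths: dict[str, Path] = {}

    def stage(name, fn):
        log.info("stage %s: start", name)
        try:
            return fn()
        except Exception as exc:
            log.error("stage %s failed: %s", name, exc)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    try:
        bundle = stage("simulate", lambda: generate_cohort(config.cohort, outdir / "cohort"))
        metrics = stage(
            "kinetics", lambda: compute_imaging_metrics(bundle, config.baseline_window_s)
        )
        cparams = stage("cardiac", lambda: params_table(bundle.cardiac, method=config.volume_method))
        cardiac_long = cparams.melt(
            id_vars=[c for c in ("mouse_id", "day", "group") if c in cparams.columns],
            value_vars=["fs", "ef", "sv", "co"],
            var_name="metric",
            value_name="value",
        )[["mouse_id", "day", "metric", "value"]]
        all_metrics = pd.concat([metrics, cardiac_long], ignore_index=True)
        deltas = stage("deltas", lambda: compute_deltas(all_metrics, bundle.mice))
        hist = stage("histology", lambda: aggregate_histology(bundle.histology))
        flux = stage("biodistribution", lambda: flux_change_table(merge_kidneys(bundle.bli_flux)))
        comparisons = stage(
            "stats",
            lambda: group_statistics(deltas, bundle.biomarkers, hist, alpha=config.alpha),
        )
        correlations = stage(
            "stats", lambda: correlation_statistics(all_metrics, bundle.biomarkers, config.alpha)
        )

        cohort_table = all_metrics.merge(bundle.mice[["mouse_id", "group"]], on="mouse_id")
        cohort_table = cohort_table.sort_values(["metric", "mouse_id", "day"]).reset_index(drop=True)

        for name, df in (
            ("cohort_table", cohort_table),
            ("metrics", all_metrics.sort_values(["metric", "mouse_id", "day"])),
            ("deltas", deltas),
            ("histology_scores", hist),
            ("flux_summary", flux),
            ("comparisons", comparisons),
            ("correlations", correlations),
        ):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p

        cfg_json = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
        manifest = {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "seed": config.cohort.seed,
            "config": json.loads(cfg_json),
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        }
        mpath = outdir / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2))
        paths["manifest"] = mpath
        log.info("pipeline complete: %d outputs in %s", len(paths), outdir)
    finally:
        log.removeHandler(handler)
        handler.close()
    return paths


def null_config(seed: int, group_sizes: dict[str, int] | None = None) -> RunConfig:
    """A no-injury cohort (all severities 0) for null-calibration studies."""
    zero = SeverityModel((0.0, 0.0), 0.0)
    cohort = CohortConfig(
        seed=seed,
        severity={"control": zero, "adr": zero, "adr_bmdm": zero},
        **({"group_sizes": group_sizes} if group_sizes else {}),
    )
    return RunConfig(cohort=cohort)
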