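"""End-to-end pipeline: simulate → process → qc → analyze → report.

All computation lives in the sibling modules; this module wires them
into reproducible runs with a single seed, writes each stage's artifact
plus a manifest of input hashes and the effective configuration, and
provides the summary-table verification mode that recomputes every
derivable statistic from printed group descriptives alone.
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

from . import gaze_events, quality_control, reference, stats_engine, synthetic_gaze
from .gaze_events import visits_from_labels
from .scene_model import HitLabel, SceneSpec, classify_rays, load_scenes, save_scenes
from .stats_engine import GroupSummary

__all__ = [
    "PipelineConfig",
    "process_gaze_log",
    "simulate_cohort_metrics",
    "analyze_cohort",
    "run_pipeline",
    "verify_summary_tables",
]

log = logging.getLogger("vrgaze")


@dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline, with study defaults."""

    seed: int = 0
    collider_scale: float = 1.10
    visit_threshold_ms: float = 50.0
    merge_threshold_ms: float = 32.0
    sampling_hz: float = 90.0
    trial_duration_ms: float = 4000.0
    data_loss_cutoff: float = 0.05
    outlier_z: float = 3.0
    alpha: float = 0.05
    n_per_group: int | None = None
    attrition: dict = field(default_factory=dict)
    scenes_path: str | None = None
    gaze_path: str | None = None
    participants_path: str | None = None
    out_dir: str = "results/run"

    def __post_init__(self) -> None:
        for name in (
            "collider_scale",
            "visit_threshold_ms",
            "merge_threshold_ms",
            "sampling_hz",
            "trial_duration_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.data_loss_cutoff < 1:
            raise ValueError("data_loss_cutoff must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _trial_metrics_row(
    labels: np.ndarray,
    valid: np.ndarray,
    scene: SceneSpec,
    cfg: PipelineConfig,
) -> dict:
    visits = visits_from_labels(
        labels,
        dt_ms=1000.0 / cfg.sampling_hz,
        visit_threshold_ms=cfg.visit_threshold_ms,
        merge_threshold_ms=cfg.merge_threshold_ms,
    )
    dwell = {HitLabel.FO1: 0.0, HitLabel.FO2: 0.0, HitLabel.BACKGROUND: 0.0}
    for v in visits:
        dwell[v.label] += v.duration_ms
    expected = int(round(scene.trial_duration_ms * cfg.sampling_hz / 1000.0))
    return {
        "trial_id": scene.scene_id,
        "dwell_fo1_ms": dwell[HitLabel.FO1],
        "dwell_fo2_ms": dwell[HitLabel.FO2],
        "dwell_background_ms": dwell[HitLabel.BACKGROUND],
        "data_loss": (expected - int(valid.sum())) / expected,
    }


def process_gaze_log(
    gaze_log: pd.DataFrame,
    scenes: list[SceneSpec],
    cfg: PipelineConfig | None = None,
    groups: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gaze log → (trial metrics, participant metrics) tables."""
    cfg = cfg or PipelineConfig()
    by_id = {s.scene_id: s for s in scenes}
    rows = []
    for (pid, tid), sub in gaze_log.groupby(
        ["participant_id", "trial_id"], sort=False
    ):
        scene = by_id[str(tid)]
        dirs = sub[["dx", "dy", "dz"]].to_numpy(dtype=float)
        valid = sub["valid"].to_numpy(dtype=bool)
        labels = classify_rays(dirs, valid, scene)
        row = _trial_metrics_row(labels, valid, scene, cfg)
        row["participant_id"] = str(pid)
        rows.append(row)
    trial_metrics = pd.DataFrame(rows)
    participant_metrics = gaze_events.aggregate_participants_frame(
        trial_metrics, scenes, groups
    )
    return trial_metrics, participant_metrics


def simulate_cohort_metrics(
    profiles,
    scenes: list[SceneSpec],
    seed: int,
    cfg: PipelineConfig | None = None,
    attrition: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort and process it trial-by-trial in one pass.

    Streaming equivalent of :func:`synthetic_gaze.generate_cohort`
    followed by :func:`process_gaze_log` (identical RNG consumption,
    hence identical numbers) without materialising the full gaze log.
    Returns ``(participants, participant_metrics)``.
    """
    cfg = cfg or PipelineConfig(seed=seed)
    is_test = {s.scene_id: s.role.value == "TEST" for s in scenes}
    closer_idx = {s.scene_id: s.closer_index for s in scenes}
    meta_rows, metric_rows = [], []
    pidx = 0
    for profile in profiles:
        for _ in range(profile.n_participants):
            rng = synthetic_gaze.participant_rng(seed, pidx)
            pid = f"{profile.group_name}_{pidx:04d}"
            meta = synthetic_gaze.draw_participant_metadata(
                profile, pid, rng, attrition
            )
            meta_rows.append(meta)
            focal, closer, further, loss = [], [], [], []
            for scene, _ts, dirs, valid in synthetic_gaze.iter_participant_trials(
                profile, scenes, rng, meta["target_dwell_ms"]
            ):
                labels = classify_rays(dirs, valid, scene)
                row = _trial_metrics_row(labels, valid, scene, cfg)
                if not is_test[scene.scene_id]:
                    continue
                focal.append(row["dwell_fo1_ms"] + row["dwell_fo2_ms"])
                loss.append(row["data_loss"])
                ci = closer_idx[scene.scene_id]
                if ci is not None:
                    closer.append(row["dwell_fo1_ms"] if ci == 0 else row["dwell_fo2_ms"])
                    further.append(row["dwell_fo2_ms"] if ci == 0 else row["dwell_fo1_ms"])
            metric_rows.append(
                {
                    "participant_id": pid,
                    "group": profile.group_name,
                    "mean_focal_dwell_ms": float(np.mean(focal)),
                    "mean_closer_dwell_ms": float(np.mean(closer)) if closer else np.nan,
                    "mean_further_dwell_ms": float(np.mean(further)) if further else np.nan,
                    "mean_data_loss": float(np.mean(loss)),
                }
            )
            pidx += 1
    return pd.DataFrame(meta_rows), pd.DataFrame(metric_rows)


def analyze_cohort(
    participant_metrics: pd.DataFrame,
    outlier_z: float = 3.0,
) -> dict:
    """Full statistical analysis of a cleaned participant-metrics table.

    Returns a JSON-serialisable dict with descriptives, assumption
    checks, the Welch one-way ANOVA, pairwise post-hocs, the mixed
    closer/further ANOVA (after outlier screening), per-group simple
    main effects, and the power analysis context.
    """
    groups = {
        g: sub["mean_focal_dwell_ms"].to_numpy()
        for g, sub in participant_metrics.groupby("group", sort=False)
    }
    descriptives = stats_engine.summarize_groups(
        stats_engine.summaries_from_raw(participant_metrics, "mean_focal_dwell_ms")
    )
    lev_F, lev_p = stats_engine.levene_test(groups)
    all_vals = participant_metrics["mean_focal_dwell_ms"]
    resid = all_vals - participant_metrics.groupby("group")[
        "mean_focal_dwell_ms"
    ].transform("mean")
    sw_W, sw_p = stats_engine.shapiro_wilk(resid)
    welch = stats_engine.welch_anova(groups)
    posthoc = stats_engine.games_howell(
        stats_engine.summaries_from_raw(participant_metrics, "mean_focal_dwell_ms")
    )

    depth = participant_metrics.dropna(
        subset=["mean_closer_dwell_ms", "mean_further_dwell_ms"]
    )
    outliers = quality_control.detect_mixed_model_outliers(depth, outlier_z)
    depth_clean = depth[~depth["participant_id"].isin(outliers)]
    mixed = stats_engine.mixed_anova(depth_clean)
    simple = stats_engine.simple_main_effects(depth_clean)

    return {
        "descriptives": descriptives.to_dict(orient="records"),
        "levene": {"F": lev_F, "p": lev_p},
        "shapiro": {"W": sw_W, "p": sw_p},
        "welch_anova": dataclasses.asdict(welch),
        "games_howell": [dataclasses.asdict(r) for r in posthoc],
        "depth_outliers_removed": outliers,
        "mixed_anova": mixed.table.to_dict(orient="records"),
        "simple_main_effects": simple.to_dict(orient="records"),
    }


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the full pipeline into ``cfg.out_dir``; returns the run dir.

    Stages: simulate (unless a gaze log is supplied), process, quality
    control, analyze, report.  Each stage writes its artifact; the
    manifest records input hashes and the effective config so any stage
    can be re-run in isolation.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.scenes_path:
        scenes = load_scenes(cfg.scenes_path)
    else:
        scenes = reference.default_scene_set(cfg.collider_scale)
        save_scenes(scenes, out / "scenes.json")

    if cfg.gaze_path and cfg.participants_path:
        gaze_log = pd.read_csv(cfg.gaze_path)
        participants = pd.read_csv(cfg.participants_path)
        log.info("loaded %d participants", len(participants))
        groups = dict(
            zip(participants["participant_id"].astype(str), participants["group"])
        )
        _, metrics = process_gaze_log(gaze_log, scenes, cfg, groups)
    else:
        profiles = reference.default_profiles(cfg.n_per_group)
        log.info(
            "simulating cohort: %d groups, seed %d",
            len(profiles),
            cfg.seed,
        )
        participants, metrics = simulate_cohort_metrics(
            profiles, scenes, cfg.seed, cfg, cfg.attrition or None
        )
    participants.to_csv(out / "participants.csv", index=False)
    metrics.to_csv(out / "participant_metrics.csv", index=False)

    retained, report = quality_control.apply_exclusions(
        participants, metrics, cfg.data_loss_cutoff
    )
    for stage, count in report.counts.items():
        log.info("excluded at %s: %d", stage, count)
    log.info("retained %d of %d participants", report.retained_n, report.input_n)
    (out / "exclusion_report.json").write_text(json.dumps(report.to_dict(), indent=2))

    kept = metrics[metrics["participant_id"].isin(report.retained_ids)]
    if kept.empty or kept.groupby("group").size().lt(3).any() or kept["group"].nunique() < 2:
        log.warning("too few retained participants for the statistical analysis")
        results = {"note": "insufficient retained participants for analysis"}
    else:
        results = analyze_cohort(kept, cfg.outlier_z)
    results["exclusions"] = report.to_dict()
    (out / "statistics.json").write_text(json.dumps(results, indent=2, default=float))

    manifest = {
        "config": cfg.to_dict(),
        "inputs": {
            p.name: _hash_file(p)
            for p in sorted(out.glob("*.csv")) + sorted(out.glob("scenes.json"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if "welch_anova" in results:
        (out / "report.md").write_text(render_report(results))
    else:
        (out / "report.md").write_text(results.get("note", "") + "\n")
    return out


def render_report(results: dict) -> str:
    """Human-readable tables mirroring the published layout."""
    lines = ["# Dwell-time analysis", "", "## Focal object dwell descriptives (ms)", ""]
    lines.append("| group | n | mean (SD) | 95% CI |")
    lines.append("|---|---|---|---|")
    for r in results["descriptives"]:
        lines.append(
            f"| {r['group']} | {r['n']} | {r['mean']:.2f} ({r['sd']:.2f}) "
            f"| [{r['ci_low']:.2f}, {r['ci_high']:.2f}] |"
        )
    w = results["welch_anova"]
    lines += [
        "",
        f"Welch ANOVA: F({w['df1']}, {w['df2']:.2f}) = {w['F']:.2f}, "
        f"p = {w['p']:.3g}, omega^2 = {w['omega_sq']:.3f}",
        "",
        "## Pairwise post-hoc tests",
        "",
        "| pair | diff [95% CI] | p (GH) | Hedges g [95% CI] |",
        "|---|---|---|---|",
    ]
    for r in results["games_howell"]:
        lines.append(
            f"| {r['pair'][0]}—{r['pair'][1]} | {r['mean_diff']:.0f} "
            f"[{r['ci_low']:.0f}, {r['ci_high']:.0f}] | {r['p_adj']:.3f} "
            f"| {r['hedges_g']:.2f} [{r['g_ci_low']:.2f}, {r['g_ci_high']:.2f}] |"
        )
    lines += ["", "## Mixed ANOVA (group x object type)", ""]
    for r in results["mixed_anova"]:
        lines.append(
            f"- {r['effect']}: F({r['df1']}, {r['df2']}) = {r['F']:.2f}, "
            f"p_holm = {r['p_holm']:.3g}, omega^2 = {r['omega_sq']:.3f}"
        )
    lines += ["", "## Simple main effects (closer − further)", ""]
    for r in results["simple_main_effects"]:
        lines.append(
            f"- {r['group']} (N = {r['n']}): diff = {r['mean_diff']:.2f} "
            f"[{r['ci_low']:.2f}, {r['ci_high']:.2f}], F = {r['F']:.2f}, "
            f"p_holm = {r['p_holm']:.3f}, eta^2_g = {r['eta_sq_g']:.3f}"
        )
    return "\n".join(lines) + "\n"


def verify_summary_tables(
    focal_summary: pd.DataFrame | None = None,
    depth_summary: pd.DataFrame | None = None,
) -> dict:
    """Recompute every statistic derivable from printed group summaries.

    ``focal_summary`` needs columns group/n/mean/sd (defaults to the
    bundled five-country table); ``depth_summary`` needs
    group/n/closer_mean/closer_sd/further_mean/further_sd.  Returns the
    Welch ANOVA, pairwise differences with Tukey-style CIs, Hedges g,
    per-group CIs and pooled rows, and the closer-minus-further point
    contrasts.
    """
    focal = focal_summary if focal_summary is not None else reference.FOCAL_DWELL_SUMMARY
    for col in ("group", "n", "mean", "sd"):
        if col not in focal.columns:
            raise ValueError(f"summary table is missing column {col!r}")
    if (focal["n"] < 2).any():
        bad = focal.loc[focal["n"] < 2, "group"].tolist()
        raise ValueError(f"groups with n < 2: {bad}")
    summaries = [
        GroupSummary(str(r.group), int(r.n), float(r.mean), float(r.sd))
        for r in focal.itertuples()
    ]
    welch = stats_engine.welch_anova(summaries)
    posthoc = stats_engine.games_howell(summaries)
    table = stats_engine.summarize_groups(summaries)
    out = {
        "descriptives": table.to_dict(orient="records"),
        "welch_anova": dataclasses.asdict(welch),
        "pairwise": [dataclasses.asdict(r) for r in posthoc],
    }
    depth = depth_summary if depth_summary is not None else reference.DEPTH_DWELL_SUMMARY
    if depth is not None and len(depth):
        closer = [
            GroupSummary(str(r.group), int(r.n), float(r.closer_mean), float(r.closer_sd))
            for r in depth.itertuples()
        ]
        further = [
            GroupSummary(str(r.group), int(r.n), float(r.further_mean), float(r.further_sd))
            for r in depth.itertuples()
        ]
        out["depth"] = {
            "closer": stats_engine.summarize_groups(closer).to_dict(orient="records"),
            "further": stats_engine.summarize_groups(further).to_dict(orient="records"),
            "contrasts": [
                {
                    "group": c.group,
                    "mean_diff": c.mean - f.mean,
                }
                for c, f in zip(closer, further)
            ],
        }
    return out
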