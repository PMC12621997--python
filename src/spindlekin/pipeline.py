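"""End-to-end pipeline: simulate → (render → track) → analyze → plot → stats.

Units are fixed package-wide: micrometres, seconds, percent; frames are
0-based and time is rebased so anaphase onset is t = 0.  Every stage writes
new files under the run directory, never mutating inputs; a manifest JSON
lists each artifact with the parameters and seeds that produced it.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as skio
from .conditions import make_condition
from .imaging import render_stack
from .kinematics import compute_kinematics, group_average, summarize_cohort
from .simulate import simulate_cohort
from .stats import kruskal_wallis_dunn, mann_whitney
from .tracking import track_stack
from .viz import ColorGraphSpec, render_color_graph, render_composite_kymograph, save_png


@dataclass
class ConditionRun:
    preset: str
    n: int
    overrides: dict = field(default_factory=dict)


@dataclass
class PipelineConfig:
    """Run configuration; round-trips losslessly through YAML."""

    output_dir: str
    conditions: list[ConditionRun]
    seed: int = 0
    grid_dt: float = 10.0
    render: bool = False
    plots: bool = True
    stats_variable: str = "v_early_A"

    def __post_init__(self) -> None:
        self.conditions = [
            c if isinstance(c, ConditionRun) else ConditionRun(**c)
            for c in self.conditions
        ]
        if not self.conditions:
            raise ValueError("config lists no conditions")
        for c in self.conditions:
            if c.n < 1:
                raise ValueError(f"condition {c.preset}: n must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Deterministic given the config seeds.  Any stage failure aborts with
    the stage name and embryo id in the exception message.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "artifacts": [], "timing_s": {}}

    def log_artifact(path: Path, stage: str, **params):
        manifest["artifacts"].append(
            {"path": str(path.relative_to(out)), "stage": stage, **params}
        )

    all_series = {}
    summaries = []
    for ci, cond in enumerate(config.conditions):
        t_start = time.perf_counter()
        spec = make_condition(cond.preset, cond.overrides)
        cond_seed = int((config.seed + 7919 * ci) % (2**31))
        try:
            records = simulate_cohort(spec, cond.n, seed=cond_seed)
        except Exception as e:  # pragma: no cover - defensive
            raise RuntimeError(f"stage simulate, condition {cond.preset}: {e}") from e
        traj_path = out / f"trajectories_{cond.preset}.csv"
        skio.write_trajectories(records, traj_path)
        log_artifact(traj_path, "simulate", preset=cond.preset, n=cond.n,
                     seed=cond_seed)

        if config.render:
            stacks_dir = out / "stacks"
            stacks_dir.mkdir(exist_ok=True)
            for rec in records:
                try:
                    stack = render_stack(rec, z_planes=8, seed=cond_seed)
                    tiff = stacks_dir / f"{rec.embryo_id}.tif"
                    skio.write_stack(stack, tiff)
                    tracked, report = track_stack(
                        stack, embryo_id=rec.embryo_id, condition=rec.condition,
                        stage=rec.stage,
                    )
                    skio.write_report(report, stacks_dir / f"{rec.embryo_id}.track.json")
                except Exception as e:
                    raise RuntimeError(
                        f"stage render/track, embryo {rec.embryo_id}: {e}"
                    ) from e
                log_artifact(tiff, "render", embryo_id=rec.embryo_id)

        try:
            series = [compute_kinematics(r) for r in records]
        except Exception as e:
            raise RuntimeError(f"stage analyze, condition {cond.preset}: {e}") from e
        all_series[cond.preset] = series
        tidy = pd.concat([s.to_frame() for s in series], ignore_index=True)
        series_path = out / f"series_{cond.preset}.csv"
        tidy.to_csv(series_path, index=False)
        log_artifact(series_path, "analyze", preset=cond.preset)
        summary = summarize_cohort(series)
        summaries.append(summary)

        mean_path = out / f"group_mean_dcp_{cond.preset}.csv"
        ga = pd.concat(
            [
                group_average(series, "dcp_a", config.grid_dt).assign(side="A"),
                group_average(series, "dcp_p", config.grid_dt).assign(side="P"),
            ],
            ignore_index=True,
        )
        ga.to_csv(mean_path, index=False)
        log_artifact(mean_path, "analyze", preset=cond.preset,
                     variable="dcp", grid_dt=config.grid_dt)

        if config.plots:
            try:
                img, geo = render_color_graph(series[0], ColorGraphSpec())
                png = out / f"colorgraph_{cond.preset}.png"
                save_png(img, png)
                (out / f"colorgraph_{cond.preset}.json").write_text(
                    json.dumps(geo, indent=2)
                )
                kimg, kgeo = render_composite_kymograph(records[0])
                kpng = out / f"kymograph_{cond.preset}.png"
                save_png(kimg, kpng)
                (out / f"kymograph_{cond.preset}.json").write_text(
                    json.dumps(kgeo, indent=2)
                )
            except Exception as e:
                raise RuntimeError(f"stage plot, condition {cond.preset}: {e}") from e
            log_artifact(png, "plot", kind="color-graph", preset=cond.preset)
            log_artifact(kpng, "plot", kind="composite-kymograph", preset=cond.preset)
        manifest["timing_s"][cond.preset] = round(time.perf_counter() - t_start, 3)

    summary_all = pd.concat(summaries, ignore_index=True)
    summary_path = out / "summary.csv"
    summary_all.to_csv(summary_path, index=False)
    log_artifact(summary_path, "analyze")

    # group statistics on the configured summary variable
    stats_out: dict = {}
    presets = [c.preset for c in config.conditions]
    groups = [
        summary_all.loc[summary_all["condition"] == make_condition(p).name,
                        config.stats_variable].to_numpy()
        for p in presets
    ]
    if len(presets) == 2:
        gc = mann_whitney(groups[0], groups[1], labels=tuple(presets))
        stats_out = {"test": gc.test, "statistic": gc.statistic, "p": gc.p_value,
                     "stars": gc.stars, "groups": gc.groups, "n": gc.sizes}
    elif len(presets) >= 3:
        gc = kruskal_wallis_dunn(groups, labels=presets)
        stats_out = {
            "test": gc.test, "H": gc.statistic, "p": gc.p_value,
            "stars": gc.stars, "groups": gc.groups, "n": gc.sizes,
            "pairwise": gc.pairwise,
        }
    if stats_out:
        stats_path = out / "stats.json"
        stats_path.write_text(json.dumps(stats_out, indent=2, default=str))
        log_artifact(stats_path, "stats", variable=config.stats_variable)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
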