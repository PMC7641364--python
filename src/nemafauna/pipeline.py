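"""Full-analysis orchestration: load -> diversity -> faunal -> screening -> stats.

The pipeline is a pure function of (inputs, config): re-running with the
same inputs and configuration reproduces every output table bit for bit.
Canonical outputs are CSV tables plus a JSON run manifest carrying the
configuration hash and package version; plots are optional artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .community import (
    CORE,
    INTERFACE,
    DEFAULT_CALENDAR,
    SuccessionDataset,
    read_annotations,
    read_calendar,
    read_community_table,
    stage_for_day,
    validate_dataset,
)
from .diversity import HEATMAP_TROPHIC_GROUPS, alpha_table, heatmap_matrix
from .faunal import GuildWeights, faunal_trajectory
from .indicator import ScreenConfig, categorize_all, flags_table, screen_all, summary_table
from .stats import paired_t_by_day, rda, two_way_anova

__all__ = ["PipelineConfig", "PipelineError", "load_dataset", "run_pipeline"]

logger = logging.getLogger(__name__)

_ALPHA_METRICS = ("total_abundance", "richness", "shannon")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    annotations: str
    community: str
    calendar: str | None = None
    out_dir: str = "nemafauna_out"
    strata: tuple[str, ...] = (CORE, INTERFACE)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    weights: GuildWeights = field(default_factory=GuildWeights)
    shannon_base: float | None = None
    holm: bool = False
    seed: int | None = None  # recorded in the manifest (set by `simulate`)

    def config_hash(self) -> str:
        payload = {
            "annotations": str(self.annotations),
            "community": str(self.community),
            "calendar": str(self.calendar),
            "strata": list(self.strata),
            "screen": asdict(self.screen),
            "weights": {
                "enrichment": dict(self.weights.enrichment),
                "basal": dict(self.weights.basal),
                "structure": dict(self.weights.structure),
            },
            "shannon_base": self.shannon_base,
            "holm": self.holm,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_dataset(cfg: PipelineConfig) -> SuccessionDataset:
    registry = read_annotations(cfg.annotations)
    calendar = read_calendar(cfg.calendar) if cfg.calendar else DEFAULT_CALENDAR
    return read_community_table(cfg.community, registry, calendar)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_pipeline(cfg: PipelineConfig) -> dict[str, Path]:
    """Run the full analysis and write all output tables under ``out_dir``.

    Returns a mapping of artifact name -> path.  Strata are always analyzed
    separately.  Statistics are restricted to days where both treatments
    are present in a stratum (interface controls start later than interface
    impacted samples, so the early interface days carry no paired tests).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    ds = _stage("load")(load_dataset, cfg)

    report = _stage("validate")(validate_dataset, ds)
    artifacts["validation"] = out / "validation.csv"
    report.replicate_counts.to_csv(artifacts["validation"], index=False)
    if report.flags:
        raise PipelineError(f"stage 'validate' failed: {', '.join(report.flags)}")

    alpha = _stage("alpha")(alpha_table, ds, cfg.shannon_base)
    artifacts["alpha"] = out / "alpha.csv"
    alpha.to_csv(artifacts["alpha"], index=False)

    for stratum in cfg.strata:
        tag = "core" if stratum == CORE else "interface"
        if not ds.select(stratum=stratum):
            raise PipelineError(f"stage 'faunal' failed: stratum {stratum!r} absent")
        for treatment in ("impacted", "control"):
            if not ds.select(stratum=stratum, treatment=treatment):
                continue
            traj = _stage("faunal")(faunal_trajectory, ds, stratum, treatment, cfg.weights)
            key = f"faunal_{tag}_{treatment}"
            artifacts[key] = out / f"{key}.csv"
            traj.to_csv(artifacts[key], index=False)
        for trophic in HEATMAP_TROPHIC_GROUPS:
            mat = _stage("heatmap")(heatmap_matrix, ds, stratum, trophic)
            key = f"heatmap_{tag}_{trophic}"
            artifacts[key] = out / f"{key}.csv"
            mat.to_csv(artifacts[key])

        flags = _stage("screen")(screen_all, ds, stratum, cfg.screen)
        results = categorize_all(flags, cfg.screen)
        artifacts[f"flags_{tag}"] = out / f"flags_{tag}.csv"
        flags_table(flags).to_csv(artifacts[f"flags_{tag}"], index=False)
        artifacts[f"categories_{tag}"] = out / f"categories_{tag}.csv"
        summary_table(results).to_csv(artifacts[f"categories_{tag}"], index=False)

        sub = alpha[alpha["stratum"] == stratum]
        both = sorted(
            set(sub.loc[sub["treatment"] == "impacted", "study_day"])
            & set(sub.loc[sub["treatment"] == "control", "study_day"])
        )
        sub = sub[sub["study_day"].isin(both)]
        anova_rows = []
        ttest_frames = []
        for metric in _ALPHA_METRICS:
            table = _stage("anova")(
                two_way_anova, sub[metric], sub["treatment"], sub["study_day"]
            )
            t = table.table.copy()
            t.insert(0, "metric", metric)
            t.insert(1, "term", t.index)
            anova_rows.append(t.reset_index(drop=True))
            tt = _stage("ttests")(paired_t_by_day, sub, metric, cfg.holm)
            tt.insert(0, "metric", metric)
            ttest_frames.append(tt)
        artifacts[f"anova_{tag}"] = out / f"anova_{tag}.csv"
        pd.concat(anova_rows, ignore_index=True).to_csv(
            artifacts[f"anova_{tag}"], index=False
        )
        artifacts[f"ttests_{tag}"] = out / f"ttests_{tag}.csv"
        pd.concat(ttest_frames, ignore_index=True).to_csv(
            artifacts[f"ttests_{tag}"], index=False
        )

        imp = [s for s in ds.samples if s.stratum == stratum and s.treatment == "impacted"]
        wide = pd.DataFrame(
            [dict(s.abundances) for s in imp],
            index=[s.sample_id for s in imp],
        )
        stages = [stage_for_day(s.study_day, ds.calendar) for s in imp]
        res = _stage("rda")(rda, wide, stages)
        scores = res.site_scores.copy()
        scores.insert(0, "stage", stages)
        artifacts[f"rda_{tag}_scores"] = out / f"rda_{tag}_scores.csv"
        scores.to_csv(artifacts[f"rda_{tag}_scores"])
        ellipses = res.centroids.join(res.group_sd, lsuffix="_centroid", rsuffix="_sd")
        artifacts[f"rda_{tag}_ellipses"] = out / f"rda_{tag}_ellipses.csv"
        ellipses.to_csv(artifacts[f"rda_{tag}_ellipses"])

    # depth comparison: impacted communities of both strata, grouped by stratum
    if set(cfg.strata) == {CORE, INTERFACE}:
        imp = [s for s in ds.samples if s.treatment == "impacted"]
        if any(s.stratum == INTERFACE for s in imp):
            wide = pd.DataFrame(
                [dict(s.abundances) for s in imp], index=[s.sample_id for s in imp]
            )
            res = _stage("rda")(rda, wide, [s.stratum for s in imp])
            artifacts["rda_depth_scores"] = out / "rda_depth_scores.csv"
            scores = res.site_scores.copy()
            scores.insert(0, "stratum", [s.stratum for s in imp])
            scores.to_csv(artifacts["rda_depth_scores"])

    manifest = {
        "package": "nemafauna",
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "inputs": {
            "annotations": str(cfg.annotations),
            "community": str(cfg.community),
            "calendar": str(cfg.calendar) if cfg.calendar else "built-in",
        },
        "artifacts": {k: str(v) for k, v in sorted(artifacts.items())},
    }
    artifacts["manifest"] = out / "manifest.json"
    artifacts["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return artifacts
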