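"""Indicator-taxon screening: threshold flags and four-way categorization.

A taxon is flagged *enriched* at a sampling day when its impacted-soil mean
abundance is at least ``min_abundance`` AND exceeds the control mean times a
guild-specific scaling factor (10 for B1 enrichment opportunists, 2 for all
other taxa).  It is flagged *suppressed* when the control mean is at least
``min_abundance`` AND the impacted mean falls below the control mean divided
by the same factor.  Both clauses of a flag are evaluated at the same
sampling day; the minimum-abundance floors exclude rare taxa whose presence
cannot be observed consistently.  Strata (core vs interface) are always
screened separately, and days without a control mean (e.g. interface days
before interface controls were collected) are recorded as unevaluable
rather than treated as zero controls.

Flagged taxa are then classified into four indicator categories:
B1 enrichment, early suppression followed by late enrichment, suppression
only, and non-B1 enrichment.  The screening is deterministic thresholding;
no statistical significance is attached to flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .community import CommunityDataError, SuccessionDataset, TaxonAnnotation
from .diversity import group_means

__all__ = [
    "ScreenConfig",
    "IndicatorFlags",
    "IndicatorResult",
    "CATEGORIES",
    "screen_taxon",
    "screen_all",
    "categorize",
    "categorize_all",
    "flags_table",
    "summary_table",
]

CATEGORIES = (
    "b1_enrichment",
    "suppression_then_enrichment",
    "suppression_only",
    "non_b1_enrichment",
    "none",
)


@dataclass(frozen=True)
class ScreenConfig:
    """Screening thresholds and control-mean convention.

    ``control_mode='per_day'`` compares against the control mean at the same
    sampling day (the design is paired in time); ``'pooled'`` uses the
    study-wide control mean per taxon.  ``split_day`` is the first late-
    skeletonization day, the early/late boundary used when classifying
    suppression-then-enrichment.
    """

    min_abundance: float = 5.0
    scale_b1: float = 10.0
    scale_other: float = 2.0
    control_mode: str = "per_day"
    split_day: int = 153

    def __post_init__(self) -> None:
        if self.min_abundance <= 0:
            raise ValueError("min_abundance must be positive")
        if self.scale_b1 <= 1 or self.scale_other <= 1:
            raise ValueError("scaling factors must exceed 1")
        if self.control_mode not in ("per_day", "pooled"):
            raise ValueError("control_mode must be 'per_day' or 'pooled'")

    def scale_for(self, annotation: TaxonAnnotation) -> float:
        return self.scale_b1 if annotation.guild == "B1" else self.scale_other


@dataclass(frozen=True)
class IndicatorFlags:
    """Per-day enrichment/suppression flags for one taxon in one stratum."""

    taxon: str
    stratum: str
    guild: str
    enrichment_days: tuple[int, ...]
    suppression_days: tuple[int, ...]
    unevaluable_days: tuple[int, ...]
    table: pd.DataFrame = field(repr=False, compare=False, default=None)


@dataclass(frozen=True)
class IndicatorResult:
    """Final indicator category for one taxon in one stratum."""

    taxon: str
    stratum: str
    category: str
    enrichment_days: tuple[int, ...]
    suppression_days: tuple[int, ...]


def screen_taxon(
    annotation: TaxonAnnotation,
    impacted_means: Mapping[int, float],
    control_means: Mapping[int, float] | float,
    stratum: str,
    cfg: ScreenConfig | None = None,
) -> IndicatorFlags:
    """Apply the enrichment/suppression criteria day by day for one taxon.

    ``control_means`` is a per-day mapping, or a single pooled control mean.
    Days present in ``impacted_means`` but lacking a control mean are
    recorded as unevaluable and yield no flag.
    """
    if cfg is None:
        cfg = ScreenConfig()
    scale = cfg.scale_for(annotation)
    pooled = not isinstance(control_means, Mapping)
    rows = []
    enr, sup, unev = [], [], []
    for day in sorted(impacted_means):
        imp = float(impacted_means[day])
        if imp < 0:
            raise CommunityDataError(f"negative impacted mean for {annotation.label!r}")
        if pooled:
            ctl = float(control_means)
        elif day in control_means:
            ctl = float(control_means[day])
        else:
            unev.append(day)
            rows.append(
                {
                    "study_day": day,
                    "impacted_mean": imp,
                    "control_mean": float("nan"),
                    "enrichment_threshold": float("nan"),
                    "suppression_threshold": float("nan"),
                    "enriched": False,
                    "suppressed": False,
                    "evaluable": False,
                }
            )
            continue
        if ctl < 0:
            raise CommunityDataError(f"negative control mean for {annotation.label!r}")
        enr_threshold = ctl * scale
        sup_threshold = ctl / scale
        enriched = imp >= cfg.min_abundance and imp > enr_threshold
        suppressed = ctl >= cfg.min_abundance and imp < sup_threshold
        if enriched:
            enr.append(day)
        if suppressed:
            sup.append(day)
        rows.append(
            {
                "study_day": day,
                "impacted_mean": imp,
                "control_mean": ctl,
                "enrichment_threshold": enr_threshold,
                "suppression_threshold": sup_threshold,
                "enriched": enriched,
                "suppressed": suppressed,
                "evaluable": True,
            }
        )
    return IndicatorFlags(
        taxon=annotation.label,
        stratum=stratum,
        guild=annotation.guild,
        enrichment_days=tuple(enr),
        suppression_days=tuple(sup),
        unevaluable_days=tuple(unev),
        table=pd.DataFrame(rows),
    )


def screen_all(
    ds: SuccessionDataset, stratum: str, cfg: ScreenConfig | None = None
) -> dict[str, IndicatorFlags]:
    """Screen every registry taxon within one stratum (strata never pooled)."""
    if cfg is None:
        cfg = ScreenConfig()
    impacted = ds.select(stratum=stratum, treatment="impacted")
    controls = ds.select(stratum=stratum, treatment="control")
    if not impacted:
        raise CommunityDataError(f"no impacted samples in stratum {stratum!r}")
    if not controls:
        raise CommunityDataError(f"no control samples in stratum {stratum!r}")
    imp_means = group_means(ds, stratum=stratum, treatment="impacted")
    ctl_means = group_means(ds, stratum=stratum, treatment="control")
    out: dict[str, IndicatorFlags] = {}
    for annotation in ds.registry:
        taxon = annotation.label
        imp = dict(
            zip(
                imp_means.loc[imp_means["taxon"] == taxon, "study_day"],
                imp_means.loc[imp_means["taxon"] == taxon, "mean"],
            )
        )
        ctl_series = ctl_means.loc[ctl_means["taxon"] == taxon]
        if cfg.control_mode == "pooled":
            # pooled: mean of the per-day control means over evaluated days
            ctl: Mapping[int, float] | float = float(ctl_series["mean"].mean())
            out[taxon] = screen_taxon(annotation, imp, ctl, stratum, cfg)
        else:
            ctl = dict(zip(ctl_series["study_day"], ctl_series["mean"]))
            out[taxon] = screen_taxon(annotation, imp, ctl, stratum, cfg)
    return out


def categorize(flags: IndicatorFlags, cfg: ScreenConfig | None = None) -> IndicatorResult:
    """Assign the four-way indicator category from a taxon's flag days.

    Precedence: a B1 taxon with any enrichment flag is a B1 enrichment
    indicator; otherwise suppression before ``split_day`` followed by
    enrichment after the first suppressed day marks suppression-then-
    enrichment; suppression with no enrichment marks suppression-only; and
    enrichment alone in a non-B1 taxon marks non-B1 enrichment.
    """
    if cfg is None:
        cfg = ScreenConfig()
    enr = flags.enrichment_days
    sup = flags.suppression_days
    if flags.guild == "B1" and enr:
        category = "b1_enrichment"
    elif (
        sup
        and enr
        and any(d < cfg.split_day for d in sup)
        and any(d > min(sup) for d in enr)
    ):
        category = "suppression_then_enrichment"
    elif sup and not enr:
        category = "suppression_only"
    elif enr and not sup and flags.guild != "B1":
        category = "non_b1_enrichment"
    else:
        category = "none"
    return IndicatorResult(
        taxon=flags.taxon,
        stratum=flags.stratum,
        category=category,
        enrichment_days=enr,
        suppression_days=sup,
    )


def categorize_all(
    flags: Mapping[str, IndicatorFlags], cfg: ScreenConfig | None = None
) -> dict[str, IndicatorResult]:
    return {taxon: categorize(f, cfg) for taxon, f in flags.items()}


def flags_table(flags: Mapping[str, IndicatorFlags]) -> pd.DataFrame:
    """Concatenate per-taxon flag tables into one exportable frame."""
    frames = []
    for f in flags.values():
        t = f.table.copy()
        t.insert(0, "taxon", f.taxon)
        t.insert(1, "stratum", f.stratum)
        t.insert(2, "guild", f.guild)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def summary_table(results: Mapping[str, IndicatorResult]) -> pd.DataFrame:
    """One row per taxon: category and supporting flag days."""
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "stratum": r.stratum,
                "category": r.category,
                "enrichment_days": ";".join(map(str, r.enrichment_days)),
                "suppression_days": ";".join(map(str, r.suppression_days)),
            }
            for r in results.values()
        ]
    )
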