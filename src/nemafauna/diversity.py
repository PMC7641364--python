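"""Alpha diversity, replicate group means, and heatmap matrices.

Richness is the number of distinct taxa with positive abundance at their
recorded (mixed) taxonomic ranks.  Shannon diversity H' = -sum p_i ln p_i
uses the natural log by default; the base is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import (
    CommunityDataError,
    SampleRecord,
    SuccessionDataset,
)

__all__ = [
    "AlphaRecord",
    "alpha_diversity",
    "alpha_table",
    "group_means",
    "heatmap_matrix",
    "HEATMAP_TROPHIC_GROUPS",
]

#: Trophic groups shown in the abundance heatmaps (herbivores are not
#: displayed because they do not track microbial food sources).
HEATMAP_TROPHIC_GROUPS = ("bacterivore", "fungivore", "omnivore", "predator")


@dataclass(frozen=True)
class AlphaRecord:
    """Per-sample alpha diversity: total abundance, richness, Shannon H'."""

    sample_id: str
    total_abundance: float
    richness: int
    shannon: float
    degenerate: bool = False  # all-zero sample


def alpha_diversity(sample: SampleRecord, base: float | None = None) -> AlphaRecord:
    """Richness, Shannon diversity, and total abundance for one sample.

    ``base=None`` gives natural-log units; pass e.g. ``base=2`` for bits.
    An all-zero sample is flagged degenerate with richness 0 and H' = 0.
    """
    values = np.array([v for v in sample.abundances.values() if v > 0], dtype=float)
    total = float(values.sum())
    richness = int(values.size)
    if richness == 0:
        return AlphaRecord(sample.sample_id, 0.0, 0, 0.0, degenerate=True)
    p = values / total
    shannon = float(-(p * np.log(p)).sum())
    if base is not None:
        shannon /= math.log(base)
    return AlphaRecord(sample.sample_id, total, richness, shannon)


def alpha_table(ds: SuccessionDataset, base: float | None = None) -> pd.DataFrame:
    """Alpha diversity for every sample, with sample metadata columns."""
    rows = []
    for s in ds.samples:
        rec = alpha_diversity(s, base=base)
        rows.append(
            {
                "sample_id": s.sample_id,
                "site": s.site,
                "treatment": s.treatment,
                "stratum": s.stratum,
                "study_day": s.study_day,
                "total_abundance": rec.total_abundance,
                "richness": rec.richness,
                "shannon": rec.shannon,
                "degenerate": rec.degenerate,
            }
        )
    return pd.DataFrame(rows)


def group_means(
    ds: SuccessionDataset, stratum: str, treatment: str
) -> pd.DataFrame:
    """Per-day, per-taxon arithmetic mean abundance across replicate sites.

    Returns a tidy frame (study_day, taxon, mean, n).  Days with no samples
    in the requested cell are omitted entirely, never reported as zero.
    """
    samples = ds.select(stratum=stratum, treatment=treatment)
    if not samples:
        import warnings

        warnings.warn(
            f"no samples for stratum={stratum!r}, treatment={treatment!r}",
            stacklevel=2,
        )
        return pd.DataFrame(columns=["study_day", "taxon", "mean", "n"])
    rows = []
    by_day: dict[int, list[SampleRecord]] = {}
    for s in samples:
        by_day.setdefault(s.study_day, []).append(s)
    for day in sorted(by_day):
        reps = by_day[day]
        n = len(reps)
        for taxon in ds.registry.labels:
            mean = sum(s.abundances.get(taxon, 0.0) for s in reps) / n
            rows.append({"study_day": day, "taxon": taxon, "mean": mean, "n": n})
    return pd.DataFrame(rows)


def effect_summary(alpha: pd.DataFrame) -> pd.DataFrame:
    """Impacted-vs-control effect sizes per stratum and day.

    From a per-sample alpha table (see :func:`alpha_table`), computes for
    each (stratum, study_day) with both treatments present:

    * ``abundance_fold`` — impacted mean total abundance / control mean,
    * ``richness_change_pct`` / ``shannon_change_pct`` — percent change of
      the impacted mean relative to the control mean (negative = decrease).

    Days lacking either treatment arm are omitted.
    """
    rows = []
    for (stratum, day), grp in alpha.groupby(["stratum", "study_day"]):
        imp = grp[grp["treatment"] == "impacted"]
        ctl = grp[grp["treatment"] == "control"]
        if imp.empty or ctl.empty:
            continue
        row: dict[str, object] = {"stratum": stratum, "study_day": int(day)}
        ctl_abund = ctl["total_abundance"].mean()
        row["abundance_fold"] = (
            imp["total_abundance"].mean() / ctl_abund if ctl_abund > 0 else np.nan
        )
        for metric in ("richness", "shannon"):
            base = ctl[metric].mean()
            row[f"{metric}_change_pct"] = (
                100.0 * (imp[metric].mean() - base) / base if base > 0 else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def stratum_abundance_ratio(alpha: pd.DataFrame, day: int) -> float:
    """Interface / core ratio of impacted mean total abundance at one day."""
    imp = alpha[(alpha["treatment"] == "impacted") & (alpha["study_day"] == day)]
    core = imp.loc[imp["stratum"] == "core_0_30cm", "total_abundance"].mean()
    interface = imp.loc[imp["stratum"] == "interface_0_1cm", "total_abundance"].mean()
    return float(interface / core)


def heatmap_matrix(
    ds: SuccessionDataset,
    stratum: str,
    trophic: str,
    treatment: str = "impacted",
) -> pd.DataFrame:
    """Square-root-transformed mean abundances, taxa (rows) by days (columns).

    Rows cover every registry member of the requested trophic group
    regardless of abundance, ordered by ascending cp class (most r-selected
    first) and alphabetically within a class.  Cells are sqrt(mean
    abundance) for scaling.  Only the four microbial-feeding trophic groups
    are valid heatmap panels.
    """
    if trophic not in HEATMAP_TROPHIC_GROUPS:
        raise CommunityDataError(
            f"heatmap trophic group must be one of {HEATMAP_TROPHIC_GROUPS}, "
            f"got {trophic!r}"
        )
    members = sorted(
        (a for a in ds.registry if a.trophic == trophic),
        key=lambda a: (a.cp, a.label),
    )
    means = group_means(ds, stratum=stratum, treatment=treatment)
    days = sorted(means["study_day"].unique())
    wide = means.pivot(index="taxon", columns="study_day", values="mean")
    out = pd.DataFrame(
        index=pd.Index([a.label for a in members], name="taxon"),
        columns=pd.Index(days, name="study_day"),
        dtype=float,
    )
    for a in members:
        if a.label in wide.index:
            out.loc[a.label] = np.sqrt(wide.loc[a.label, days].astype(float).values)
    return out
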