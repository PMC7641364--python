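"""Faunal profile: weighted guild components and Enrichment/Structure Indices.

The soil food-web condition of a nematode community is summarized on the
(EI, SI) plane.  Guild abundances are weighted into three components:

* enrichment ``e`` — opportunist guilds (B1 weighted 3.2, F2 weighted 0.8),
* basal ``b`` — stress-tolerant cp-2 baseline (B2 and F2, weighted 0.8),
* structure ``s`` — cp 3-5 guilds (weights 1.8 / 3.2 / 5.0 by class) plus
  the cp-2 predators (P2, weighted 0.8).

EI = 100 e / (e + b) and SI = 100 s / (s + b).  Herbivorous taxa are plant
feeders not coupled to microbial food pulses and are excluded from all
components by convention (they do appear in descriptive composition
fractions).  F2 contributes to both e and b.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .community import SuccessionDataset, TaxonRegistry
from .diversity import group_means

__all__ = [
    "GuildWeights",
    "FaunalProfile",
    "CompositionRecord",
    "composition",
    "guild_components",
    "faunal_indices",
    "faunal_profile",
    "faunal_trajectory",
]

logger = logging.getLogger(__name__)


def _default_enrichment() -> dict[str, float]:
    return {"B1": 3.2, "F2": 0.8}


def _default_basal() -> dict[str, float]:
    return {"B2": 0.8, "F2": 0.8}


def _default_structure() -> dict[str, float]:
    weights = {"P2": 0.8}
    for initial in "BFOP":
        weights[f"{initial}3"] = 1.8
        weights[f"{initial}4"] = 3.2
        weights[f"{initial}5"] = 5.0
    return weights


@dataclass(frozen=True)
class GuildWeights:
    """Guild weighting scheme for the e/b/s components.

    Defaults follow the standard faunal-analysis weighting: cp-1 = 3.2,
    cp-2 = 0.8, cp-3 = 1.8, cp-4 = 3.2, cp-5 = 5.0, with F2 counted in both
    the enrichment and basal components and P2 in the structure component.
    Herbivore guilds never appear in any component.
    """

    enrichment: Mapping[str, float] = field(default_factory=_default_enrichment)
    basal: Mapping[str, float] = field(default_factory=_default_basal)
    structure: Mapping[str, float] = field(default_factory=_default_structure)

    def __post_init__(self) -> None:
        for component in (self.enrichment, self.basal, self.structure):
            for guild, w in component.items():
                if w < 0:
                    raise ValueError(f"negative weight for guild {guild}")
                if guild.startswith("H"):
                    raise ValueError("herbivore guilds are excluded from the faunal profile")


@dataclass(frozen=True)
class FaunalProfile:
    """Weighted components and indices for one community."""

    e: float
    b: float
    s: float
    ei: float  # NaN when e + b == 0
    si: float


@dataclass(frozen=True)
class CompositionRecord:
    """Descriptive relative abundances by trophic group and by cp class.

    Unlike EI/SI, composition includes herbivores.  For an empty community
    the fractions are undefined and ``defined`` is False.
    """

    trophic: dict[str, float]
    cp: dict[int, float]
    defined: bool


def composition(
    abundances: Mapping[str, float], registry: TaxonRegistry
) -> CompositionRecord:
    """Fractions of total abundance by trophic group and by cp class."""
    trophic_totals: dict[str, float] = {}
    cp_totals: dict[int, float] = {}
    total = 0.0
    for taxon, value in abundances.items():
        ann = registry[taxon]
        trophic_totals[ann.trophic] = trophic_totals.get(ann.trophic, 0.0) + value
        cp_totals[ann.cp] = cp_totals.get(ann.cp, 0.0) + value
        total += value
    if total <= 0:
        return CompositionRecord(
            trophic={k: float("nan") for k in trophic_totals},
            cp={k: float("nan") for k in cp_totals},
            defined=False,
        )
    return CompositionRecord(
        trophic={k: v / total for k, v in sorted(trophic_totals.items())},
        cp={k: v / total for k, v in sorted(cp_totals.items())},
        defined=True,
    )


def guild_components(
    abundances: Mapping[str, float],
    registry: TaxonRegistry,
    weights: GuildWeights | None = None,
) -> tuple[float, float, float]:
    """Weighted enrichment, basal, and structure components (e, b, s).

    Herbivorous taxa are silently excluded (logged at debug level).
    """
    if weights is None:
        weights = GuildWeights()
    e = b = s = 0.0
    for taxon, value in abundances.items():
        ann = registry[taxon]
        if ann.trophic == "herbivore":
            logger.debug("excluding herbivore %s from faunal components", taxon)
            continue
        guild = ann.guild
        e += weights.enrichment.get(guild, 0.0) * value
        b += weights.basal.get(guild, 0.0) * value
        s += weights.structure.get(guild, 0.0) * value
    return e, b, s


def faunal_indices(e: float, b: float, s: float) -> tuple[float, float]:
    """Enrichment and Structure Indices from weighted components.

    EI = 100 e / (e + b), undefined (NaN) when e + b = 0.
    SI = 100 s / (s + b); a community with no structure component has
    SI = 0 by convention, including the s = b = 0 case, so a pure cp-1
    bacterivore community sits at (EI, SI) = (100, 0).
    """
    if e < 0 or b < 0 or s < 0:
        raise ValueError("faunal components must be non-negative")
    ei = 100.0 * e / (e + b) if (e + b) > 0 else float("nan")
    si = 0.0 if s == 0 else 100.0 * s / (s + b)
    # the ratios are mathematically in [0, 100]; clamp float roundoff
    if not math.isnan(ei):
        ei = min(100.0, max(0.0, ei))
    return ei, min(100.0, max(0.0, si))


def faunal_profile(
    abundances: Mapping[str, float],
    registry: TaxonRegistry,
    weights: GuildWeights | None = None,
) -> FaunalProfile:
    """Components plus indices for a single community or group mean."""
    e, b, s = guild_components(abundances, registry, weights)
    ei, si = faunal_indices(e, b, s)
    return FaunalProfile(e=e, b=b, s=s, ei=ei, si=si)


def faunal_trajectory(
    ds: SuccessionDataset,
    stratum: str,
    treatment: str,
    weights: GuildWeights | None = None,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Per-day faunal profile series computed on per-day mean abundances.

    Returns (study_day, e, b, s, EI, SI, n); with ``per_sample=True`` each
    sample instead contributes its own row (for dispersion around the
    group-mean trajectory) with a ``sample_id`` column.
    """
    if per_sample:
        rows = []
        for s_rec in ds.select(stratum=stratum, treatment=treatment):
            prof = faunal_profile(s_rec.abundances, ds.registry, weights)
            rows.append(
                {
                    "sample_id": s_rec.sample_id,
                    "study_day": s_rec.study_day,
                    "e": prof.e,
                    "b": prof.b,
                    "s": prof.s,
                    "EI": prof.ei,
                    "SI": prof.si,
                }
            )
        return pd.DataFrame(rows).sort_values(
            ["study_day", "sample_id"], ignore_index=True
        )
    means = group_means(ds, stratum=stratum, treatment=treatment)
    rows = []
    for day, grp in means.groupby("study_day"):
        abundances = dict(zip(grp["taxon"], grp["mean"]))
        prof = faunal_profile(abundances, ds.registry, weights)
        rows.append(
            {
                "study_day": int(day),
                "e": prof.e,
                "b": prof.b,
                "s": prof.s,
                "EI": prof.ei,
                "SI": prof.si,
                "n": int(grp["n"].iloc[0]),
            }
        )
    return pd.DataFrame(rows)


def plot_faunal_profile(trajectory: pd.DataFrame, path=None):  # pragma: no cover
    """Quadrant plot of the (EI, SI) trajectory.  Requires matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(trajectory["SI"], trajectory["EI"], "o-", color="tab:blue")
    for _, row in trajectory.iterrows():
        ax.annotate(str(int(row["study_day"])), (row["SI"], row["EI"]), fontsize=7)
    ax.axhline(50, color="gray", lw=0.5)
    ax.axvline(50, color="gray", lw=0.5)
    ax.set_xlim(-2, 102)
    ax.set_ylim(-2, 102)
    ax.set_xlabel("Structure Index")
    ax.set_ylabel("Enrichment Index")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
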