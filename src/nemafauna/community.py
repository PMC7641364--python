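"""Community data model: taxon annotations, sample records, stage calendar.

The analysis operates on soil nematode community tables: per-sample taxon
abundances expressed as nematodes per 100 cm^3 soil, with sample metadata
(site, treatment, depth stratum, study day).  Taxa are identified at mixed
taxonomic ranks (genus, family, or order) and annotated with a trophic group
and a colonizer-persister (cp) class on the 1-5 r/K continuum; trophic
initial plus cp class gives the functional guild code (B1, F2, O4, ...).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping

import pandas as pd

__all__ = [
    "CommunityDataError",
    "TaxonAnnotation",
    "TaxonRegistry",
    "SampleRecord",
    "StageCalendar",
    "SuccessionDataset",
    "ValidationReport",
    "DEFAULT_CALENDAR",
    "CORE",
    "INTERFACE",
    "TROPHIC_GROUPS",
    "derive_guild",
    "read_annotations",
    "read_community_table",
    "read_calendar",
    "write_community_table",
    "validate_dataset",
    "stage_for_day",
]


class CommunityDataError(ValueError):
    """Raised for malformed or inconsistent community data."""


RANKS = ("genus", "family", "order")
TROPHIC_GROUPS = ("bacterivore", "fungivore", "herbivore", "omnivore", "predator")
_TROPHIC_INITIAL = {
    "bacterivore": "B",
    "fungivore": "F",
    "herbivore": "H",
    "omnivore": "O",
    "predator": "P",
}

CORE: str = "core_0_30cm"
INTERFACE: str = "interface_0_1cm"
STRATA = (CORE, INTERFACE)
TREATMENTS = ("impacted", "control")

Treatment = Literal["impacted", "control"]
Stratum = Literal["core_0_30cm", "interface_0_1cm"]


def derive_guild(trophic: str, cp: int) -> str:
    """Functional guild code: trophic-group initial + cp class (e.g. B1, F2)."""
    if trophic not in _TROPHIC_INITIAL:
        raise CommunityDataError(f"unknown trophic group {trophic!r}")
    return f"{_TROPHIC_INITIAL[trophic]}{cp}"


@dataclass(frozen=True)
class TaxonAnnotation:
    """A taxon label with rank, trophic group, and cp class.

    cp class 1 is an exclusively bacterial-feeding designation, so cp=1 is
    only valid together with trophic='bacterivore'.
    """

    label: str
    rank: str
    trophic: str
    cp: int

    def __post_init__(self) -> None:
        if not self.label:
            raise CommunityDataError("taxon label must be non-empty")
        if self.rank not in RANKS:
            raise CommunityDataError(
                f"taxon {self.label!r}: rank {self.rank!r} not one of {RANKS}"
            )
        if self.trophic not in TROPHIC_GROUPS:
            raise CommunityDataError(
                f"taxon {self.label!r}: trophic {self.trophic!r} not one of {TROPHIC_GROUPS}"
            )
        if not isinstance(self.cp, int) or not 1 <= self.cp <= 5:
            raise CommunityDataError(
                f"taxon {self.label!r}: cp class must be an integer in 1..5, got {self.cp!r}"
            )
        if self.cp == 1 and self.trophic != "bacterivore":
            raise CommunityDataError(
                f"taxon {self.label!r}: cp-1 is restricted to bacterivores "
                f"(got trophic {self.trophic!r})"
            )

    @property
    def guild(self) -> str:
        return derive_guild(self.trophic, self.cp)


class TaxonRegistry:
    """Ordered collection of taxon annotations with lookup by label."""

    def __init__(self, annotations: Iterable[TaxonAnnotation]):
        self._annotations: list[TaxonAnnotation] = []
        self._by_label: dict[str, TaxonAnnotation] = {}
        for ann in annotations:
            if ann.label in self._by_label:
                raise CommunityDataError(f"duplicate taxon label {ann.label!r}")
            self._annotations.append(ann)
            self._by_label[ann.label] = ann

    def __len__(self) -> int:
        return len(self._annotations)

    def __iter__(self) -> Iterator[TaxonAnnotation]:
        return iter(self._annotations)

    def __contains__(self, label: object) -> bool:
        return label in self._by_label

    def __getitem__(self, label: str) -> TaxonAnnotation:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"taxon {label!r} not in registry") from None

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(a.label for a in self._annotations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [a.label for a in self._annotations],
                "rank": [a.rank for a in self._annotations],
                "trophic": [a.trophic for a in self._annotations],
                "cp": [a.cp for a in self._annotations],
                "guild": [a.guild for a in self._annotations],
            }
        )


@dataclass(frozen=True)
class SampleRecord:
    """One composite soil sample: metadata plus taxon abundances per 100 cm^3."""

    sample_id: str
    site: int
    treatment: str
    stratum: str
    study_day: int
    abundances: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise CommunityDataError(
                f"sample {self.sample_id!r}: treatment {self.treatment!r} "
                f"not one of {TREATMENTS}"
            )
        if self.stratum not in STRATA:
            raise CommunityDataError(
                f"sample {self.sample_id!r}: stratum {self.stratum!r} not one of {STRATA}"
            )
        if self.study_day < 0:
            raise CommunityDataError(f"sample {self.sample_id!r}: negative study_day")
        for taxon, value in self.abundances.items():
            if value < 0:
                raise CommunityDataError(
                    f"sample {self.sample_id!r}: negative abundance for {taxon!r}"
                )

    @property
    def key(self) -> tuple[int, str, str, int]:
        return (self.site, self.treatment, self.stratum, self.study_day)

    @property
    def total_abundance(self) -> float:
        return float(sum(self.abundances.values()))


@dataclass(frozen=True)
class StageCalendar:
    """Ordered (study_day, decomposition stage) pairs.

    Stages spanning more than one sampling time point are numbered
    sequentially (e.g. "Advanced decay 1", "Advanced decay 2").
    """

    entries: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        days = [d for d, _ in self.entries]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise CommunityDataError("calendar days must be strictly increasing")

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(d for d, _ in self.entries)

    def stage(self, day: int) -> str:
        for d, s in self.entries:
            if d == day:
                return s
        raise KeyError(f"day {day} not in calendar")


#: Default sampling calendar: 12 time points spanning placement (day 0)
#: through late skeletonization (day 317).
DEFAULT_CALENDAR = StageCalendar(
    (
        (0, "Placement"),
        (2, "Fresh"),
        (6, "Bloat"),
        (15, "Active decay"),
        (21, "Advanced decay 1"),
        (40, "Advanced decay 2"),
        (78, "Early skeletonization 1"),
        (110, "Early skeletonization 2"),
        (153, "Late skeletonization 1"),
        (188, "Late skeletonization 2"),
        (250, "Late skeletonization 3"),
        (317, "Late skeletonization 4"),
    )
)


def stage_for_day(
    day: int, calendar: StageCalendar = DEFAULT_CALENDAR, mode: str = "exact"
) -> str:
    """Map a study day to its decomposition stage.

    In ``exact`` mode the day must be a sampling day listed in the calendar.
    In ``interval`` mode any day maps to the stage of the latest calendar
    day <= day (useful for sensor readings between sampling dates).
    """
    if mode == "exact":
        return calendar.stage(day)
    if mode == "interval":
        best = None
        for d, s in calendar.entries:
            if d <= day:
                best = s
        if best is None:
            raise KeyError(f"day {day} precedes the first calendar day")
        return best
    raise ValueError(f"mode must be 'exact' or 'interval', got {mode!r}")


@dataclass
class SuccessionDataset:
    """A succession study: taxon registry, samples, and stage calendar."""

    registry: TaxonRegistry
    samples: list[SampleRecord]
    calendar: StageCalendar = DEFAULT_CALENDAR

    def __post_init__(self) -> None:
        seen: set[tuple[int, str, str, int]] = set()
        cal_days = set(self.calendar.days)
        for s in self.samples:
            if s.key in seen:
                raise CommunityDataError(
                    f"duplicate sample for (site={s.site}, treatment={s.treatment}, "
                    f"stratum={s.stratum}, study_day={s.study_day})"
                )
            seen.add(s.key)
            if s.study_day not in cal_days:
                raise CommunityDataError(
                    f"sample {s.sample_id!r}: study_day {s.study_day} not in calendar"
                )
            unknown = set(s.abundances) - set(self.registry.labels)
            if unknown:
                raise CommunityDataError(
                    f"sample {s.sample_id!r}: taxa not in registry: {sorted(unknown)}"
                )

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(sorted({s.study_day for s in self.samples}))

    def select(
        self,
        stratum: str | None = None,
        treatment: str | None = None,
        study_day: int | None = None,
    ) -> list[SampleRecord]:
        out = []
        for s in self.samples:
            if stratum is not None and s.stratum != stratum:
                continue
            if treatment is not None and s.treatment != treatment:
                continue
            if study_day is not None and s.study_day != study_day:
                continue
            out.append(s)
        return out

    def to_wide(self) -> pd.DataFrame:
        """Wide table: one row per sample, metadata columns then taxon columns."""
        rows = []
        for s in self.samples:
            row: dict[str, object] = {
                "sample_id": s.sample_id,
                "site": s.site,
                "treatment": s.treatment,
                "stratum": s.stratum,
                "study_day": s.study_day,
            }
            for taxon in self.registry.labels:
                row[taxon] = float(s.abundances.get(taxon, 0.0))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_long(self) -> pd.DataFrame:
        """Long table: one row per (sample, taxon) including zeros."""
        wide = self.to_wide()
        return wide.melt(
            id_vars=["sample_id", "site", "treatment", "stratum", "study_day"],
            var_name="taxon",
            value_name="abundance",
        )


_META_COLS = ("sample_id", "site", "treatment", "stratum", "study_day")
_LONG_COLS = _META_COLS + ("taxon", "abundance")


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a CSV or TSV file, sniffing the delimiter from the header line."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    header = text.splitlines()[0] if text else ""
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(io.StringIO(text), sep=sep)


def read_annotations(path: str | Path) -> TaxonRegistry:
    """Read a taxon annotation table (columns: label, rank, trophic, cp).

    Guild codes are derived, not read; malformed rows (bad cp, cp-1
    non-bacterivores, duplicate labels) raise :class:`CommunityDataError`
    naming the offending taxon.
    """
    df = _read_delimited(path)
    required = {"label", "rank", "trophic", "cp"}
    missing = required - set(df.columns)
    if missing:
        raise CommunityDataError(f"annotation table missing columns: {sorted(missing)}")
    annotations = []
    for _, row in df.iterrows():
        cp_raw = row["cp"]
        try:
            cp = int(cp_raw)
        except (TypeError, ValueError):
            raise CommunityDataError(
                f"taxon {row['label']!r}: cp {cp_raw!r} is not an integer"
            ) from None
        if cp != float(cp_raw):
            raise CommunityDataError(f"taxon {row['label']!r}: cp {cp_raw!r} is not an integer")
        annotations.append(
            TaxonAnnotation(
                label=str(row["label"]).strip(),
                rank=str(row["rank"]).strip(),
                trophic=str(row["trophic"]).strip(),
                cp=cp,
            )
        )
    return TaxonRegistry(annotations)


def _records_from_long(df: pd.DataFrame, registry: TaxonRegistry) -> list[SampleRecord]:
    unknown = sorted(set(df["taxon"]) - set(registry.labels))
    if unknown:
        raise CommunityDataError(f"community table contains unknown taxa: {unknown}")
    if (df["abundance"] < 0).any():
        bad = df.loc[df["abundance"] < 0].iloc[0]
        raise CommunityDataError(
            f"negative abundance for taxon {bad['taxon']!r} in sample {bad['sample_id']!r}"
        )
    dup = df.duplicated(subset=["sample_id", "taxon"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise CommunityDataError(
            f"duplicate cell for sample {bad['sample_id']!r}, taxon {bad['taxon']!r}"
        )
    records = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        meta = grp.iloc[0]
        abundances = {label: 0.0 for label in registry.labels}
        abundances.update(
            {t: float(v) for t, v in zip(grp["taxon"], grp["abundance"])}
        )
        records.append(
            SampleRecord(
                sample_id=str(sample_id),
                site=int(meta["site"]),
                treatment=str(meta["treatment"]),
                stratum=str(meta["stratum"]),
                study_day=int(meta["study_day"]),
                abundances=abundances,
            )
        )
    return records


def _records_from_wide(df: pd.DataFrame, registry: TaxonRegistry) -> list[SampleRecord]:
    taxon_cols = [c for c in df.columns if c not in _META_COLS]
    unknown = sorted(set(taxon_cols) - set(registry.labels))
    if unknown:
        raise CommunityDataError(f"community table contains unknown taxa: {unknown}")
    records = []
    for _, row in df.iterrows():
        abundances = {label: 0.0 for label in registry.labels}
        for taxon in taxon_cols:
            value = float(row[taxon])
            if value < 0:
                raise CommunityDataError(
                    f"negative abundance for taxon {taxon!r} in sample {row['sample_id']!r}"
                )
            abundances[taxon] = value
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                site=int(row["site"]),
                treatment=str(row["treatment"]),
                stratum=str(row["stratum"]),
                study_day=int(row["study_day"]),
                abundances=abundances,
            )
        )
    return records


def read_community_table(
    path: str | Path,
    registry: TaxonRegistry,
    calendar: StageCalendar = DEFAULT_CALENDAR,
) -> SuccessionDataset:
    """Read a community-abundance table, long or wide (auto-detected).

    Long format has columns (sample_id, site, treatment, stratum, study_day,
    taxon, abundance); wide format has the metadata columns followed by one
    column per taxon.  Taxa absent from a sample are zero-filled against the
    registry, so both layouts load to the same dataset.
    """
    df = _read_delimited(path)
    missing = set(_META_COLS) - set(df.columns)
    if missing:
        raise CommunityDataError(f"community table missing columns: {sorted(missing)}")
    if {"taxon", "abundance"} <= set(df.columns):
        records = _records_from_long(df, registry)
    else:
        records = _records_from_wide(df, registry)
    return SuccessionDataset(registry=registry, samples=records, calendar=calendar)


def write_community_table(
    ds: SuccessionDataset, path: str | Path, layout: str = "long"
) -> None:
    """Write the dataset back out as CSV/TSV in ``long`` or ``wide`` layout."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    if layout == "long":
        ds.to_long().to_csv(path, sep=sep, index=False)
    elif layout == "wide":
        ds.to_wide().to_csv(path, sep=sep, index=False)
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")


def read_calendar(path: str | Path) -> StageCalendar:
    """Read a stage calendar CSV with columns study_day, stage."""
    df = _read_delimited(path)
    if not {"study_day", "stage"} <= set(df.columns):
        raise CommunityDataError("calendar file needs columns study_day, stage")
    return StageCalendar(
        tuple((int(d), str(s)) for d, s in zip(df["study_day"], df["stage"]))
    )


@dataclass
class ValidationReport:
    """Reporting-only summary of a dataset's replication structure."""

    n_samples: int
    replicate_counts: pd.DataFrame  # columns: treatment, stratum, study_day, n
    missing_cells: list[tuple[str, str, int]]  # (treatment, stratum, day) with no samples
    pairing_gaps: list[tuple[int, str, int]]  # (site, stratum, day) impacted without control
    flags: list[str] = field(default_factory=list)


def validate_dataset(ds: SuccessionDataset) -> ValidationReport:
    """Summarize replicate counts, missing cells, and impacted/control pairing.

    Missing strata cells are reported against the grid of (treatment,
    stratum) combinations observed anywhere in the dataset crossed with the
    sampling days present; absent cells are samples that were never taken
    (e.g. interface controls before they were added to the design), never
    zero-abundance samples.
    """
    if not ds.samples:
        return ValidationReport(
            n_samples=0,
            replicate_counts=pd.DataFrame(
                columns=["treatment", "stratum", "study_day", "n"]
            ),
            missing_cells=[],
            pairing_gaps=[],
            flags=["no samples"],
        )
    meta = pd.DataFrame(
        {
            "site": [s.site for s in ds.samples],
            "treatment": [s.treatment for s in ds.samples],
            "stratum": [s.stratum for s in ds.samples],
            "study_day": [s.study_day for s in ds.samples],
        }
    )
    counts = (
        meta.groupby(["treatment", "stratum", "study_day"])
        .size()
        .reset_index(name="n")
        .sort_values(["stratum", "treatment", "study_day"], ignore_index=True)
    )
    observed_pairs = {(t, st) for t, st in zip(meta["treatment"], meta["stratum"])}
    have = {
        (t, st, d)
        for t, st, d in zip(meta["treatment"], meta["stratum"], meta["study_day"])
    }
    missing = [
        (t, st, d)
        for (t, st) in sorted(observed_pairs)
        for d in ds.days
        if (t, st, d) not in have
    ]
    by_cell: dict[tuple[str, int, str], set[int]] = {}
    for s in ds.samples:
        by_cell.setdefault((s.treatment, s.study_day, s.stratum), set()).add(s.site)
    gaps = []
    for (treatment, day, stratum), sites in sorted(by_cell.items()):
        if treatment != "impacted":
            continue
        controls = by_cell.get(("control", day, stratum), set())
        for site in sorted(sites - controls):
            gaps.append((site, stratum, day))
    return ValidationReport(
        n_samples=len(ds.samples),
        replicate_counts=counts,
        missing_cells=missing,
        pairing_gaps=gaps,
    )
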