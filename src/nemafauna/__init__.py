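"""nemafauna: soil nematode succession analysis for decomposition hotspots.

Functional annotation of nematode taxa (trophic group x colonizer-persister
class -> guild), alpha and functional diversity (richness, Shannon,
Enrichment/Structure Indices), threshold-based indicator-taxon screening,
supporting statistics (two-way ANOVA, paired t-tests, RDA), and a synthetic
succession generator with planted ground truth for recovery testing.
"""

__version__ = "0.1.0"

from .community import (
    CORE,
    DEFAULT_CALENDAR,
    INTERFACE,
    CommunityDataError,
    SampleRecord,
    StageCalendar,
    SuccessionDataset,
    TaxonAnnotation,
    TaxonRegistry,
    read_annotations,
    read_community_table,
    stage_for_day,
    validate_dataset,
    write_community_table,
)
from .diversity import AlphaRecord, alpha_diversity, alpha_table, group_means, heatmap_matrix
from .faunal import (
    CompositionRecord,
    FaunalProfile,
    GuildWeights,
    composition,
    faunal_indices,
    faunal_profile,
    faunal_trajectory,
    guild_components,
)
from .indicator import (
    IndicatorFlags,
    IndicatorResult,
    ScreenConfig,
    categorize,
    categorize_all,
    screen_all,
    screen_taxon,
)
from .pipeline import PipelineConfig, run_pipeline
from .simulate import (
    GroundTruth,
    SimConfig,
    TaxonArchetype,
    default_archetypes,
    generate_succession,
)
from .stats import paired_t, rda, two_way_anova

__all__ = [
    "__version__",
    "CORE",
    "INTERFACE",
    "DEFAULT_CALENDAR",
    "CommunityDataError",
    "TaxonAnnotation",
    "TaxonRegistry",
    "SampleRecord",
    "StageCalendar",
    "SuccessionDataset",
    "read_annotations",
    "read_community_table",
    "write_community_table",
    "validate_dataset",
    "stage_for_day",
    "AlphaRecord",
    "alpha_diversity",
    "alpha_table",
    "group_means",
    "heatmap_matrix",
    "GuildWeights",
    "FaunalProfile",
    "CompositionRecord",
    "composition",
    "guild_components",
    "faunal_indices",
    "faunal_profile",
    "faunal_trajectory",
    "ScreenConfig",
    "IndicatorFlags",
    "IndicatorResult",
    "screen_taxon",
    "screen_all",
    "categorize",
    "categorize_all",
    "two_way_anova",
    "paired_t",
    "rda",
    "TaxonArchetype",
    "SimConfig",
    "GroundTruth",
    "default_archetypes",
    "generate_succession",
    "PipelineConfig",
    "run_pipeline",
]
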