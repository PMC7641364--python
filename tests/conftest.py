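import pytest

from nemafauna.community import TaxonAnnotation, TaxonRegistry
from nemafauna.simulate import generate_succession


@pytest.fixture(scope="session")
def tiny_registry() -> TaxonRegistry:
    """Small mixed-rank registry spanning the guilds the indices weight."""
    return TaxonRegistry(
        [
            TaxonAnnotation("Rhabditidae", "family", "bacterivore", 1),
            TaxonAnnotation("Diplogastridae", "family", "bacterivore", 1),
            TaxonAnnotation("Acrobeloides", "genus", "bacterivore", 2),
            TaxonAnnotation("Filenchus", "genus", "fungivore", 2),
            TaxonAnnotation("Seinura", "genus", "predator", 2),
            TaxonAnnotation("Helicotylenchus", "genus", "herbivore", 3),
            TaxonAnnotation("Dorylaimida", "order", "omnivore", 4),
            TaxonAnnotation("Nygolaimidae", "family", "predator", 5),
        ]
    )


@pytest.fixture(scope="session")
def sim():
    """Default synthetic study at the reference seed, with ground truth."""
    return generate_succession(seed=42)


@pytest.fixture(scope="session")
def sim_dataset(sim):
    return sim[0]


@pytest.fixture(scope="session")
def ground_truth(sim):
    return sim[1]
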