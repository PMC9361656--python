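import numpy as np
import pytest
from hypothesis import settings

import mockbench as mb

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

#: The three species reported absent from whole-cell shotgun profiles
#: (one lost to classification, two to extraction of hard-to-lyse cells).
ABSENT_SPECIES = (
    "ruminococcus gauvreauii",
    "clostridium butyricum",
    "alistipes finegoldii",
)


@pytest.fixture(scope="session")
def gut20():
    return mb.gut20()


@pytest.fixture(scope="session")
def species_truth_profile(gut20):
    return mb.expected_profile(gut20, basis="cells", rank="species")


@pytest.fixture
def fixture_16tp_2fp(species_truth_profile):
    """Truth profile minus the three absent species, plus two false taxa.

    The canonical 16-true-positive / 2-false-positive / 3-false-negative
    configuration: Sensitivity 16/19, Diversity 18.
    """
    entries = {
        name: value
        for name, value in species_truth_profile.entries.items()
        if name not in ABSENT_SPECIES
    }
    total = sum(entries.values())
    entries = {k: v / total * 0.95 for k, v in entries.items()}
    entries["kit reagent contaminant a"] = 0.03
    entries["kit reagent contaminant b"] = 0.02
    return mb.TaxonProfile.from_entries(
        sample_id="fixture_16tp_2fp", rank="species", entries=entries
    )


def random_profile(rng: np.random.Generator, taxa, min_taxa=1) -> mb.TaxonProfile:
    """A random normalized profile over a subset of a taxon pool."""
    k = int(rng.integers(min_taxa, len(taxa) + 1))
    chosen = rng.choice(list(taxa), size=k, replace=False)
    weights = rng.random(k) + 1e-6
    entries = dict(zip(chosen, weights / weights.sum()))
    return mb.TaxonProfile.from_entries(
        sample_id="random", rank="species", entries=entries
    )
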