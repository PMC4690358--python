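import numpy as np
import pytest
from hypothesis import settings

import cubkit as ck
from cubkit.codon_stats import CodonCountTable
from cubkit.genetic_code import CODONS, CODON_TO_AA, STOP

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")

_SENSE_MASK = np.array([CODON_TO_AA[c] != STOP for c in CODONS])


def random_count_table(rng: np.random.Generator, low: int = 1, high: int = 30) -> CodonCountTable:
    """A count table with every sense codon observed (all families usable)."""
    counts = np.where(_SENSE_MASK, rng.integers(low, high + 1, size=64), 0)
    return CodonCountTable(counts, scope="species-pooled")


@pytest.fixture(scope="session")
def uniform_table() -> CodonCountTable:
    """Equal counts for all 61 sense codons."""
    return CodonCountTable(np.where(_SENSE_MASK, 100, 0), scope="species-pooled")


@pytest.fixture(scope="session")
def small_cohort():
    """Six small species spanning a GC3 gradient; shared across tests."""
    params = [
        ck.SpeciesSimParams(
            species_id=f"sp{i}",
            n_genes=150,
            gc3_target=g,
            mean_length_codons=150,
        )
        for i, g in enumerate(np.linspace(0.30, 0.50, 6))
    ]
    return ck.generate_cohort(params, seed=2024)


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    small_cohort.write(out)
    return out
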