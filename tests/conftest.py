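import numpy as np
import pytest

from negset.core import LabeledSequence, SequenceSet
from negset.fixtures import SpeciesSpec, make_species_panel

BASES = np.array(list("ACGT"))


def random_sequence(rng, length=81, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(BASES[rng.choice(4, size=length, p=p)])


def make_set(seqs, label="non-promoter", origin="SRS", species="spX", stage=None):
    return SequenceSet(
        records=[
            LabeledSequence(f"{species}:{i}", species, s, label, origin)
            for i, s in enumerate(seqs)
        ],
        stage_tag=stage,
    )


@pytest.fixture(scope="session")
def small_panel():
    """Three species with distinct promoter GC, small enough for fast tests."""
    specs = [
        SpeciesSpec(species_id="spA", genome_length=150_000, background_gc=0.37,
                    promoter_gc=0.33, n_promoters=250, cds_gc_shift=0.03),
        SpeciesSpec(species_id="spB", genome_length=150_000, background_gc=0.52,
                    promoter_gc=0.50, n_promoters=250, cds_gc_shift=0.03),
        SpeciesSpec(species_id="spC", genome_length=150_000, background_gc=0.67,
                    promoter_gc=0.65, n_promoters=250, cds_gc_shift=0.03),
    ]
    return make_species_panel(specs, seed=101)


@pytest.fixture(scope="session")
def small_sets(small_panel):
    from negset.windows import extract_all

    P0, C0 = extract_all(small_panel.genomes, small_panel.tss_records,
                         small_panel.cds_records, seed=102)
    return P0, C0
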