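import pytest

from psmap.annotation import AnnotationIndex, AnnotationRecord
from psmap.mapping import OrfIndex, map_psms
from psmap.simulate import FixtureSpec, simulate_fixture


@pytest.fixture(scope="session")
def std_fixture():
    """The standard synthetic data set used across the suite."""
    return simulate_fixture(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def std_mapping(std_fixture):
    """(index, target PSMs, hits) for the standard fixture, mapped without
    any score filtering."""
    index = OrfIndex(std_fixture.orfs)
    targets = [p for p in std_fixture.psms if not p.is_decoy]
    hits = map_psms(targets, index)
    return index, targets, hits


@pytest.fixture(scope="session")
def truth_index(std_fixture):
    """Annotation index over *all* planted proteins (including the ones
    withheld from the emitted GFF), for realized-truth checks."""
    return AnnotationIndex(
        [
            AnnotationRecord(
                gene_id=t.gene_id,
                contig_id=t.contig_id,
                strand=t.strand,
                start=t.start,
                end=t.end,
            )
            for t in std_fixture.truth_proteins
        ]
    )
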