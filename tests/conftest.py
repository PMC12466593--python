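import pytest

from snptrait import GenotypeCountTable, Locus

# The four candidate-gene SNP loci with their published genotype counts
# (N = 176 birds). Reference allele here is the first-listed allele of each
# marker-table row, so hom_ref corresponds to the first printed genotype.
MARKER_TABLE = [
    (Locus("g.57337C>A", "A", "C", "exon 5"), (18, 47, 111)),
    (Locus("g.64757T>G", "T", "G", "exon 7"), (21, 50, 105)),
    (Locus("g.97213G>A", "G", "A", "exon 8"), (159, 17, 0)),
    (Locus("g.220985G>A", "G", "A", "exon 9"), (158, 18, 0)),
]


@pytest.fixture(scope="session")
def marker_counts() -> list[GenotypeCountTable]:
    return [GenotypeCountTable(locus, *counts) for locus, counts in MARKER_TABLE]
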