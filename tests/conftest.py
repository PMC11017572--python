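import numpy as np
import pytest

from pseudocheck.annotation_io import AssemblyAnnotation, CdsFeature
from pseudocheck.synthetic_data import GenomeSpec, make_genome


@pytest.fixture(scope="session")
def fixture_orf() -> str:
    """A deterministic 120-codon intact ORF (start + sense codons + stop)."""
    rng = np.random.default_rng(20240915)
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    while len(codons) < 118:
        codon = "".join(rng.choice(list("ACGT"), size=3))
        if codon not in stops:
            codons.append(codon)
    return "ATG" + "".join(codons) + "TAA"


@pytest.fixture(scope="session")
def small_genome() -> AssemblyAnnotation:
    """A 100-gene truth genome with 5 true pseudogenes."""
    return make_genome(GenomeSpec(n_genes=100, true_pseudo_fraction=0.05, seed=11))


def make_feature(
    feature_id: str = "f1",
    status: str = "gene",
    causes=frozenset(),
    seq: str | None = None,
    start: int = 1,
    end: int | None = None,
    contig: str = "c1",
    strand: str = "+",
) -> CdsFeature:
    if end is None:
        end = start + (len(seq) - 1 if seq else 99)
    return CdsFeature(
        feature_id=feature_id,
        contig_id=contig,
        start=start,
        end=end,
        strand=strand,
        status=status,
        causes=frozenset(causes),
        nt_sequence=seq,
    )
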