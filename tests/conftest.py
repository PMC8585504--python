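import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from prophagekit.aba import ABA_BTP1
from prophagekit.neighborhood import GeneFeature
from prophagekit.sequences import NucleotideSequence


@pytest.fixture
def aba_seq() -> NucleotideSequence:
    """The 63-bp BTP1 anti-BstA element."""
    return NucleotideSequence("aba_BTP1", ABA_BTP1)


def make_gene(
    feature_id: str,
    start: int,
    end: int,
    strand: str = "+",
    product: str = "hypothetical protein",
    contig: str = "contig1",
) -> GeneFeature:
    return GeneFeature(
        feature_id=feature_id,
        contig_id=contig,
        start=start,
        end=end,
        strand=strand,
        product=product,
    )


@pytest.fixture
def gene_factory():
    return make_gene
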