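import dataclasses

import pytest

from mutaccum import synthetic_data as synth
from mutaccum.io_formats import AnnotatedGenome, Gene


@pytest.fixture
def toy_genome():
    """30 bp genome with one plus-strand gene covering positions 1-30.

    Sense sequence is ten codons: ATG GAT GAT ... GAT TAA-like; built so
    codon identities are easy to reason about in tests.
    """
    seq = "ATG" + "GAT" * 8 + "TAA"
    return AnnotatedGenome(id="toy", sequence=seq, genes=[Gene("g1", 1, 30, "+")])


def make_genome(seq: str, genes: list[tuple[str, int, int, str]]) -> AnnotatedGenome:
    return AnnotatedGenome(
        id="t", sequence=seq, genes=[Gene(*g) for g in genes]
    )


@pytest.fixture(scope="session")
def small_genome():
    """Deterministic 30 kb annotated genome with homopolymer hotspots."""
    return synth.generate_genome(synth.GenomeSpec(
        length=30_000, coding_fraction_target=0.85, gc_target=0.5077,
        n_genes=20, homopolymer_spec=(("A", 6, 8), ("G", 5, 8)), seed=5,
    ))


@pytest.fixture(scope="session")
def inflated_rates():
    """Default per-group rates scaled so small genomes give usable counts."""
    scale = 200.0
    return {
        name: dataclasses.replace(
            spec,
            six_type={c: r * scale for c, r in spec.six_type.items()},
            indel={c: r * scale for c, r in spec.indel.items()},
        )
        for name, spec in synth.default_rate_specs().items()
    }
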