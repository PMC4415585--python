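import pytest

from mcminer import composition as C
from mcminer import synthetic as S


@pytest.fixture(scope="session")
def trio_genomes():
    """Three well-separated synthetic genomes, each large enough to yield
    >=30 binnable 10-20 kb sections (the planted-recovery setting)."""
    specs = [
        S.GenomeSpec(
            genome_id=f"G{i}",
            length_bp=620_000,
            gc_target=gc,
            composition_divergence=1.0,
            taxon_label=f"Genus{i}",
            seed=100 + i,
        )
        for i, gc in enumerate([0.45, 0.55, 0.65])
    ]
    return {s.genome_id: S.generate_genome(s) for s in specs}


@pytest.fixture(scope="session")
def trio_fragments(trio_genomes):
    """(fragments, truth) from sectioning the trio's genomes directly."""
    frags, truth = [], {}
    for g in trio_genomes.values():
        rec = C.SequenceRecord(g.genome_id, g.sequence)
        for fr in C.fragment_sections(rec):
            frags.append(fr)
            truth[fr.id] = g.genome_id
    return frags, truth


@pytest.fixture(scope="session")
def small_pair():
    """Two small divergent genomes for read-recruitment tests."""
    specs = [
        S.GenomeSpec(
            genome_id=f"P{i}",
            length_bp=50_000,
            gc_target=0.45 + 0.1 * i,
            composition_divergence=1.0,
            seed=7 + i,
        )
        for i in range(2)
    ]
    return {s.genome_id: S.generate_genome(s) for s in specs}
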