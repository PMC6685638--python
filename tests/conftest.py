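"""Shared fixtures: small genomes, constructed alignments, simulated runs."""

from __future__ import annotations

import numpy as np
import pytest

from refbias import (
    Mapper,
    ReadAlignment,
    ReferenceGenome,
    SNPPanel,
    SNPRecord,
    filter_short,
    remove_duplicates,
)
from refbias.simulate import SimulationConfig, simulate_dataset


def make_alignment(
    sequence: str,
    chrom: str = "chr1",
    start: int = 0,
    read_id: str = "r1",
    mapq: int = 37,
    baseq: int = 40,
    strand: str = "+",
    cigar: str | None = None,
    **kwargs,
) -> ReadAlignment:
    """Hand-built alignment with uniform base qualities."""
    return ReadAlignment(
        read_id=read_id,
        sequence=sequence,
        base_quals=np.full(len(sequence), baseq, dtype=np.int64),
        chrom=chrom,
        start=start,
        strand=strand,
        mapq=mapq,
        edit_distance=kwargs.pop("edit_distance", 0),
        has_indel=kwargs.pop("has_indel", False),
        cigar=cigar or f"{len(sequence)}M",
        **kwargs,
    )


@pytest.fixture(scope="session")
def small_reference() -> ReferenceGenome:
    """5 kb random repeat-free reference for fast mapping tests."""
    cfg = SimulationConfig(genome_length=5000, coverage=1.0, seed=42)
    from refbias.simulate import simulate_reference

    return simulate_reference(cfg)


@pytest.fixture(scope="session")
def small_mapper(small_reference) -> Mapper:
    return Mapper(small_reference)


@pytest.fixture(scope="session")
def unbiased_run():
    """Small clean end-to-end run: repeat-free genome, error-free reads.

    20 kb / 100 het SNPs / 20x, enough to exercise the whole pipeline in
    a few seconds.
    """
    cfg = SimulationConfig(
        genome_length=20_000,
        snp_density=5.0,
        het_fraction=1.0,
        coverage=20.0,
        length_mode=50,
        seed=3,
    )
    reference, genotypes, panel, reads = simulate_dataset(cfg)
    mapper = Mapper(reference)
    alignments = remove_duplicates(filter_short(mapper.map_reads(reads), 35))
    return reference, genotypes, panel, alignments


@pytest.fixture(scope="session")
def biased_run():
    """Seed-fixed biased simulation: duplicated segment, short fragments,
    terminal deamination and sequencing error.

    The deamination load is roughly constant per read while the mapper's
    mismatch budget grows with length, so short fragments lose
    alternative-allele reads disproportionately.
    """
    cfg = SimulationConfig(
        genome_length=40_000,
        repeat_spec=((800, 3),),
        snp_density=6.0,
        het_fraction=1.0,
        coverage=60.0,
        length_mode=40,
        length_sigma=0.4,
        deamination=(0.5, 0.25),
        error_rate=0.01,
        seed=11,
    )
    reference, genotypes, panel, reads = simulate_dataset(cfg)
    mapper = Mapper(reference)
    alignments = remove_duplicates(filter_short(mapper.map_reads(reads), 35))
    return reference, genotypes, panel, alignments


def build_paralog_fixture(alt_matches_paralog: bool):
    """Genome where a paralog collides with one haplotype at a SNP.

    A 400 bp source region around the SNP is copied elsewhere; the copy
    carries the SNP's *other* allele plus ``budget`` extra differences
    clustered beside the SNP.  Reads carrying the allele matching the
    paralog then see a second placement within the edit budget (ambiguous
    MAPQ), while reads carrying the opposite allele see none.

    With ``alt_matches_paralog`` the alternative allele is the one
    captured (classic reference bias); otherwise the mirror case.
    Returns (reference, panel, haplotype sequences (h_ref, h_alt),
    snp position0).
    """
    rng = np.random.default_rng(99)
    bases = "ACGT"
    seq = list(rng.choice(list(bases), size=3000))
    snp_pos = 700
    seq[snp_pos] = "A"
    ref_allele, alt_allele = "A", "T"
    # paralog: copy of [500, 900) carrying the captured allele at the SNP
    # plus exactly budget (= maxdiff(40) = 3) extra differences clustered
    # beside it, so allele-matching 40-mers sit at the edit budget while
    # opposite-allele 40-mers exceed it by one
    src = seq[500:900]
    copy = list(src)
    copy[snp_pos - 500] = alt_allele if alt_matches_paralog else ref_allele
    for off in (3, 6, 9):
        orig = copy[snp_pos - 500 + off]
        copy[snp_pos - 500 + off] = bases[(bases.index(orig) + 1) % 4]
    seq[2200:2600] = copy
    reference = ReferenceGenome({"chr1": "".join(seq)})
    panel = SNPPanel([SNPRecord("chr1", snp_pos + 1, ref_allele, alt_allele)])
    h_ref = "".join(seq)
    h_alt = h_ref[:snp_pos] + alt_allele + h_ref[snp_pos + 1 :]
    return reference, panel, (h_ref, h_alt), snp_pos
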