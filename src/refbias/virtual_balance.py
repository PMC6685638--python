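"""The virtual opposite-allele read-set diagnostic.

Every read that mapped over a panel SNP (with sufficient mapping and
base quality) is doubled: the original is kept and a copy with the
allele at every overlapping SNP swapped to its counterpart (ref <-> alt)
is added.  The joint set therefore carries the two alleles of every SNP
in exactly equal numbers — a perfectly balanced input.  After remapping
the doubled set, any deviation of a SNP's alternative-allele fraction
from 1/2 isolates mapping-induced bias at that site: fractions below 1/2
are reference bias, above 1/2 alternative bias, and 0 or 1 mean only one
allele ever maps back.

Fractions are held as exact rationals so the singleton histogram bins
{0}, {1/2}, {1} are decided without floating-point ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import ReferenceGenome
from .mapper import Mapper, MapperParams, ReadAlignment, remap_reference_forward
from .snp_panel import SNPPanel

BALANCE_BINS = ("0", "(0,0.4)", "[0.4,0.5)", "0.5", "(0.5,0.6]", "(0.6,1)", "1")


@dataclass(frozen=True)
class BalancedRead:
    """One member of the doubled read set, pinned to its original locus."""

    read_id: str
    sequence: str  # reference-forward, as stored in the source alignment
    base_quals: np.ndarray
    chrom: str
    start: int
    strand: str
    is_swapped: bool


@dataclass
class SiteBalance:
    chrom: str
    pos: int  # 1-based
    n_ref: int
    n_alt: int

    @property
    def fraction(self) -> Optional[Fraction]:
        total = self.n_ref + self.n_alt
        if total == 0:
            return None
        return Fraction(self.n_alt, total)


@dataclass
class BalanceHistogram:
    """Counts of SNPs per allelic-balance bin.

    Bins partition [0, 1]: {0}, (0,0.4), [0.4,0.5), {0.5}, (0.5,0.6],
    (0.6,1), {1}.  ``n_uncovered`` counts SNPs with no ref/alt read after
    remapping (excluded from the bins).
    """

    counts: dict[str, int]
    n_snps: int
    n_uncovered: int = 0
    filtered_flag: bool = True

    def to_frame(self) -> pd.DataFrame:
        total = max(self.n_snps, 1)
        return pd.DataFrame(
            {
                "bin": list(BALANCE_BINS),
                "n_snps": [self.counts[b] for b in BALANCE_BINS],
                "percentage": [
                    100.0 * self.counts[b] / total for b in BALANCE_BINS
                ],
            }
        )


def build_balanced_readset(
    alignments: Sequence[ReadAlignment],
    panel: SNPPanel,
    min_mapq: int = 30,
    min_baseq: int = 30,
) -> tuple[list[BalancedRead], int]:
    """Double every qualifying SNP-overlapping read with its allele-swap.

    A read qualifies if MAPQ >= ``min_mapq`` and it carries ref or alt
    with base quality >= ``min_baseq`` at >= 1 panel SNP.  The swapped
    copy flips the allele at every overlapping SNP where the read carries
    ref or alt (ref -> alt and vice versa), so each SNP ends up with
    exactly equal ref and alt representation.  Returns (doubled set,
    number of reads excluded for carrying only third alleles at their
    SNPs).
    """
    doubled: list[BalancedRead] = []
    n_excluded_other = 0
    for a in alignments:
        if a.is_duplicate or a.mapq < min_mapq:
            continue
        snps = panel.overlapping(a.chrom, a.start, a.ref_end)
        if not snps:
            continue
        qualifying = False
        swap_positions: list[tuple[int, str]] = []
        for snp in snps:
            off = a.read_offset_at(snp.pos0)
            if off is None:
                continue
            base = a.sequence[off]
            if base == snp.ref_allele:
                swap_positions.append((off, snp.alt_allele))
            elif base == snp.alt_allele:
                swap_positions.append((off, snp.ref_allele))
            else:
                continue
            if a.base_quals[off] >= min_baseq:
                qualifying = True
        if not qualifying:
            if any(a.read_offset_at(s.pos0) is not None for s in snps):
                n_excluded_other += 1
            continue
        doubled.append(
            BalancedRead(
                read_id=a.read_id,
                sequence=a.sequence,
                base_quals=a.base_quals,
                chrom=a.chrom,
                start=a.start,
                strand=a.strand,
                is_swapped=False,
            )
        )
        chars = list(a.sequence)
        for off, base in swap_positions:
            chars[off] = base
        doubled.append(
            BalancedRead(
                read_id=a.read_id + "/swap",
                sequence="".join(chars),
                base_quals=a.base_quals,
                chrom=a.chrom,
                start=a.start,
                strand=a.strand,
                is_swapped=True,
            )
        )
    return doubled, n_excluded_other


def remap_and_classify(
    doubled: Sequence[BalancedRead],
    reference: ReferenceGenome,
    params: MapperParams | None,
    panel: SNPPanel,
    min_remap_mapq: int = 30,
    require_original_locus: bool = True,
) -> list[SiteBalance]:
    """Remap the doubled set and count alleles returning to each SNP.

    Each remapped read with MAPQ >= ``min_remap_mapq`` contributes to
    every panel SNP it covers; with ``require_original_locus`` (the
    default) only reads returning to their original (chrom, start,
    strand) count, mirroring the headline diagnostic.  SNPs covered by no
    qualifying read are omitted.
    """
    mapper = Mapper(reference, params)
    counts: dict[tuple[str, int], list[int]] = {}
    for read in doubled:
        aln = remap_reference_forward(
            mapper, read.sequence, read.base_quals, read.strand, read_id=read.read_id
        )
        if aln is None or aln.mapq < min_remap_mapq:
            continue
        if require_original_locus and (
            (aln.chrom, aln.start, aln.strand)
            != (read.chrom, read.start, read.strand)
        ):
            continue
        for snp in panel.overlapping(aln.chrom, aln.start, aln.ref_end):
            off = aln.read_offset_at(snp.pos0)
            if off is None:
                continue
            base = aln.sequence[off]
            entry = counts.setdefault((snp.chrom, snp.pos), [0, 0])
            if base == snp.ref_allele:
                entry[0] += 1
            elif base == snp.alt_allele:
                entry[1] += 1
    return [
        SiteBalance(chrom, pos, n_ref, n_alt)
        for (chrom, pos), (n_ref, n_alt) in sorted(counts.items())
    ]


def _classify_fraction(frac: Fraction) -> str:
    if frac == 0:
        return "0"
    if frac < Fraction(2, 5):
        return "(0,0.4)"
    if frac < Fraction(1, 2):
        return "[0.4,0.5)"
    if frac == Fraction(1, 2):
        return "0.5"
    if frac <= Fraction(3, 5):
        return "(0.5,0.6]"
    if frac < 1:
        return "(0.6,1)"
    return "1"


def balance_histogram(
    sites: Sequence[SiteBalance], filtered_flag: bool = True
) -> BalanceHistogram:
    """Assign each SNP's exact alt fraction to its balance bin."""
    counts = {b: 0 for b in BALANCE_BINS}
    n_uncovered = 0
    n_snps = 0
    for site in sites:
        frac = site.fraction
        if frac is None:
            n_uncovered += 1
            continue
        counts[_classify_fraction(frac)] += 1
        n_snps += 1
    return BalanceHistogram(
        counts=counts,
        n_snps=n_snps,
        n_uncovered=n_uncovered,
        filtered_flag=filtered_flag,
    )


def write_site_balance_tsv(sites: Sequence[SiteBalance], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tn_ref_back\tn_alt_back\tfraction\tbin\n")
        for s in sites:
            frac = s.fraction
            if frac is None:
                frac_s, bin_s = "NA", "NA"
            else:
                frac_s, bin_s = f"{float(frac):.6g}", _classify_fraction(frac)
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.n_ref}\t{s.n_alt}\t{frac_s}\t{bin_s}\n"
            )
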