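"""Post-mapping filters that mitigate reference bias by remapping.

Two complementary strategies operate on reads that already mapped over a
panel SNP:

* **modified-read filter** — every read carrying the reference allele at
  one or more panel SNPs is copied, the reference alleles are flipped to
  the alternative alleles, and the copy is remapped.  The original read
  passes only if its flipped twin still maps to the identical position
  with no indels and sufficient MAPQ.  This removes exactly the reads
  whose alternative-allele counterparts would have been lost in mapping.

* **modified-reference filter** — the reference is rewritten to carry a
  random third allele (neither ref nor alt) at every panel SNP, and every
  SNP-overlapping read is remapped against it.  Both alleles are then
  equally distant from the modified reference, so survival is symmetric
  by construction.

Reads overlapping no panel SNP are never touched.  Both filters are
per-read predicates, hence idempotent, and their combination is the
intersection of the two pass sets.  Neither filter can restore a 50/50
allele ratio if alternative reads were already lost before or during the
first mapping; they only stop the reference-carrying survivors from
outnumbering them further.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import ReferenceGenome
from .mapper import Mapper, MapperParams, ReadAlignment, remap_reference_forward
from .snp_panel import BASES, SNPPanel

DEFAULT_MIN_REMAP_MAPQ = 30

_FAIL_POSITION = "position"
_FAIL_INDEL = "indel"
_FAIL_MAPQ = "mapq"


@dataclass
class FilterReport:
    """Bookkeeping for one filter run.

    ``n_flipped_or_remapped`` counts the reads actually re-evaluated (the
    rest passed untouched); ``n_passed`` plus the three failure counts
    partition it.  ``fraction_removed`` is removed / re-evaluated.
    """

    n_input_reads: int = 0
    n_flipped_or_remapped: int = 0
    n_failed_position: int = 0
    n_failed_indel: int = 0
    n_failed_mapq: int = 0
    n_passed: int = 0

    def _record(self, failure: Optional[str]) -> bool:
        self.n_flipped_or_remapped += 1
        if failure is None:
            self.n_passed += 1
            return True
        if failure == _FAIL_POSITION:
            self.n_failed_position += 1
        elif failure == _FAIL_INDEL:
            self.n_failed_indel += 1
        else:
            self.n_failed_mapq += 1
        return False

    @property
    def n_removed(self) -> int:
        return self.n_failed_position + self.n_failed_indel + self.n_failed_mapq

    @property
    def fraction_removed(self) -> float:
        if self.n_flipped_or_remapped == 0:
            return 0.0
        return self.n_removed / self.n_flipped_or_remapped

    def to_frame(self) -> pd.DataFrame:
        metrics = [
            "n_input_reads",
            "n_flipped_or_remapped",
            "n_failed_position",
            "n_failed_indel",
            "n_failed_mapq",
            "n_passed",
            "fraction_removed",
        ]
        return pd.DataFrame(
            {"metric": metrics, "value": [getattr(self, m) for m in metrics]}
        )


@dataclass(frozen=True)
class FlipResult:
    sequence: str
    flipped_positions: tuple[int, ...]  # 0-based reference positions

    @property
    def changed(self) -> bool:
        return bool(self.flipped_positions)


@dataclass
class ModifiedReference:
    """Third-allele reference plus the substitution table that built it."""

    genome: ReferenceGenome
    substitutions: pd.DataFrame  # columns chrom, pos (1-based), ref, alt, third

    def write_table(self, path) -> None:
        self.substitutions.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_files(cls, fasta_path, table_path) -> "ModifiedReference":
        return cls(
            genome=ReferenceGenome.from_fasta(fasta_path),
            substitutions=pd.read_csv(table_path, sep="\t"),
        )


def _check_panel_matches_reference(
    panel: SNPPanel, reference: ReferenceGenome
) -> None:
    bad = []
    for r in panel:
        if r.chrom not in reference:
            bad.append(f"{r.chrom}:{r.pos} (unknown chromosome)")
            continue
        base = reference[r.chrom][r.pos0]
        if base != r.ref_allele:
            bad.append(f"{r.chrom}:{r.pos} (panel ref {r.ref_allele}, genome {base})")
    if bad:
        head = ", ".join(bad[:5])
        raise ValueError(
            f"{len(bad)} panel SNPs disagree with the reference: {head}"
            + (", ..." if len(bad) > 5 else "")
        )


def flip_ref_to_alt(read: ReadAlignment, panel: SNPPanel) -> FlipResult:
    """Copy of the read sequence with every reference allele at an
    overlapping panel SNP replaced by the alternative allele.

    Bases at non-SNP positions and base qualities are untouched; SNPs at
    which the read already carries alt (or a third base) are left alone.
    All ref-carrying SNPs on the read are flipped simultaneously: one
    remap decides the whole read.
    """
    snps = panel.overlapping(read.chrom, read.start, read.ref_end)
    if not snps:
        raise ValueError(
            f"read {read.read_id} overlaps no panel SNP; nothing to flip"
        )
    chars = list(read.sequence)
    flipped = []
    for snp in snps:
        off = read.read_offset_at(snp.pos0)
        if off is None:
            continue
        if chars[off] == snp.ref_allele:
            chars[off] = snp.alt_allele
            flipped.append(snp.pos0)
    return FlipResult("".join(chars), tuple(flipped))


def _remap_failure(
    aln: ReadAlignment,
    remapped: Optional[ReadAlignment],
    min_remap_mapq: int,
) -> Optional[str]:
    """Same-position / no-indel / MAPQ rule; None means the read passes."""
    if (
        remapped is None
        or (remapped.chrom, remapped.start, remapped.strand)
        != (aln.chrom, aln.start, aln.strand)
    ):
        return _FAIL_POSITION
    if remapped.has_indel:
        return _FAIL_INDEL
    if remapped.mapq < min_remap_mapq:
        return _FAIL_MAPQ
    return None


def _eval_modified_read(
    a: ReadAlignment,
    panel: SNPPanel,
    mapper: Mapper,
    min_remap_mapq: int,
) -> tuple[bool, Optional[str]]:
    """(was re-evaluated, failure category or None) for the read filter."""
    snps = panel.overlapping(a.chrom, a.start, a.ref_end)
    if not snps:
        return False, None
    flip = flip_ref_to_alt(a, panel)
    if not flip.changed:  # alt/other only: nothing to test
        return False, None
    remapped = remap_reference_forward(
        mapper, flip.sequence, a.base_quals, a.strand, read_id=a.read_id
    )
    return True, _remap_failure(a, remapped, min_remap_mapq)


def _eval_modified_reference(
    a: ReadAlignment,
    panel: SNPPanel,
    mapper: Mapper,
    min_remap_mapq: int,
) -> tuple[bool, Optional[str]]:
    """(was re-evaluated, failure category or None) for the reference filter."""
    if not panel.overlapping(a.chrom, a.start, a.ref_end):
        return False, None
    remapped = remap_reference_forward(
        mapper, a.sequence, a.base_quals, a.strand, read_id=a.read_id
    )
    return True, _remap_failure(a, remapped, min_remap_mapq)


def modified_read_filter(
    alignments: Sequence[ReadAlignment],
    panel: SNPPanel,
    reference: ReferenceGenome,
    params: MapperParams | None = None,
    min_remap_mapq: int = DEFAULT_MIN_REMAP_MAPQ,
) -> tuple[list[ReadAlignment], FilterReport]:
    """Remap allele-flipped copies of reference-carrying reads.

    Reads overlapping no panel SNP, or carrying only alt/other alleles at
    their SNPs, pass untouched.  A read carrying the reference allele at
    >= 1 SNP passes iff its flipped copy maps back to the identical
    (chrom, start, strand) with no indels and MAPQ >= ``min_remap_mapq``.
    The ORIGINAL read is emitted for passers.
    """
    _check_panel_matches_reference(panel, reference)
    mapper = Mapper(reference, params)
    report = FilterReport(n_input_reads=len(alignments))
    passed = []
    for a in alignments:
        evaluated, failure = _eval_modified_read(a, panel, mapper, min_remap_mapq)
        if not evaluated:
            passed.append(a)
        elif report._record(failure):
            passed.append(a)
    return passed, report


def build_modified_reference(
    reference: ReferenceGenome, panel: SNPPanel, seed: int
) -> ModifiedReference:
    """Reference with a random third allele at every panel SNP.

    At each site one of the two bases outside {ref, alt} is chosen
    uniformly with the given seed; the substitution table records every
    choice so the modified genome is reproducible bit-for-bit.
    """
    _check_panel_matches_reference(panel, reference)
    rng = np.random.default_rng(seed)
    rows = []
    subs = []
    for r in panel:
        choices = sorted(BASES - {r.ref_allele, r.alt_allele})
        third = choices[rng.integers(len(choices))]
        subs.append((r.chrom, r.pos0, third))
        rows.append((r.chrom, r.pos, r.ref_allele, r.alt_allele, third))
    genome = reference.with_substitutions(subs)
    table = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "third"])
    return ModifiedReference(genome=genome, substitutions=table)


def _check_modified_reference(panel: SNPPanel, modified: ModifiedReference) -> None:
    table = modified.substitutions
    keys = set(zip(table["chrom"], table["pos"]))
    panel_keys = {(r.chrom, r.pos) for r in panel}
    if keys != panel_keys:
        raise ValueError(
            "modified reference was not built from this panel "
            f"({len(panel_keys - keys)} panel sites missing from the "
            f"substitution table, {len(keys - panel_keys)} extraneous)"
        )


def modified_reference_filter(
    alignments: Sequence[ReadAlignment],
    panel: SNPPanel,
    modified: ModifiedReference,
    params: MapperParams | None = None,
    min_remap_mapq: int = DEFAULT_MIN_REMAP_MAPQ,
) -> tuple[list[ReadAlignment], FilterReport]:
    """Remap every SNP-overlapping read against the third-allele reference.

    ``alignments`` must come from mapping against the ORIGINAL reference.
    Acceptance is the same-position / no-indel / MAPQ rule; reads not
    overlapping any panel SNP pass untouched.
    """
    _check_modified_reference(panel, modified)
    mapper = Mapper(modified.genome, params)
    report = FilterReport(n_input_reads=len(alignments))
    passed = []
    for a in alignments:
        evaluated, failure = _eval_modified_reference(
            a, panel, mapper, min_remap_mapq
        )
        if not evaluated:
            passed.append(a)
        elif report._record(failure):
            passed.append(a)
    return passed, report


def combined_filter(
    alignments: Sequence[ReadAlignment],
    panel: SNPPanel,
    reference: ReferenceGenome,
    modified: ModifiedReference,
    params: MapperParams | None = None,
    min_remap_mapq: int = DEFAULT_MIN_REMAP_MAPQ,
) -> tuple[list[ReadAlignment], FilterReport]:
    """Intersection of the modified-read and modified-reference filters.

    Equivalent to running both filters and keeping reads (identified by
    read_id and coordinates) passing both.  In the report, a read failing
    both filters is counted once, under the modified-read filter's
    failure category.
    """
    _check_panel_matches_reference(panel, reference)
    _check_modified_reference(panel, modified)
    read_mapper = Mapper(reference, params)
    ref_mapper = Mapper(modified.genome, params)
    report = FilterReport(n_input_reads=len(alignments))
    passed = []
    for a in alignments:
        eval_a, fail_a = _eval_modified_read(a, panel, read_mapper, min_remap_mapq)
        if fail_a is not None:  # already rejected; second remap unnecessary
            report._record(fail_a)
            continue
        eval_b, fail_b = _eval_modified_reference(
            a, panel, ref_mapper, min_remap_mapq
        )
        if not (eval_a or eval_b):
            passed.append(a)
            continue
        if report._record(fail_b):
            passed.append(a)
    return passed, report
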