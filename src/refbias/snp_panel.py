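"""Panels of known biallelic SNPs.

All analyses in this package are restricted to a panel of known biallelic
variants — in practice transversions, so that post-mortem deamination
(C→T / G→A) cannot masquerade as polymorphism.  The panel is the analogue
of the large genotyping-array / sequencing-project SNP sets used in human
palaeogenomics.

On-disk positions (EIGENSTRAT ``.snp``, VCF, the ``alleles_tsv`` dialect)
are 1-based; BED masks and ancestry segments are 0-based half-open.
``SNPRecord.pos`` keeps the familiar 1-based convention, and ``pos0``
exposes the 0-based coordinate used against alignments.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Optional, Sequence

BASES = frozenset("ACGT")
ANCESTRY_LABELS = frozenset({"African", "European", "EastAsian", "Uncertain"})

_TRANSITIONS = (frozenset("AG"), frozenset("CT"))


def is_transversion(a: str, b: str) -> bool:
    """True iff the substitution a<->b crosses the purine/pyrimidine divide."""
    pair = frozenset((a, b))
    return pair not in _TRANSITIONS


class PanelParseError(ValueError):
    """Malformed panel input; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class SNPRecord:
    """A known biallelic SNP, alleles on the reference forward strand."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    id: Optional[str] = None
    maf: Optional[float] = None
    ancestry: Optional[str] = None

    def __post_init__(self):
        if self.ref_allele not in BASES or self.alt_allele not in BASES:
            raise ValueError(
                f"{self.chrom}:{self.pos}: alleles must be canonical bases, "
                f"got {self.ref_allele}/{self.alt_allele}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.chrom}:{self.pos}: ref equals alt")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.maf is not None and not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"maf must be in [0, 0.5], got {self.maf}")
        if self.ancestry is not None and self.ancestry not in ANCESTRY_LABELS:
            raise ValueError(f"unknown ancestry label {self.ancestry!r}")

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1

    @property
    def is_transversion(self) -> bool:
        return is_transversion(self.ref_allele, self.alt_allele)


class SNPPanel:
    """An ordered, duplicate-free collection of SNPRecords.

    Records are sorted by (chrom, pos); a duplicated (chrom, pos) is an
    error.  Fast per-chromosome position lookup supports pileups and
    read-overlap queries.
    """

    def __init__(self, records: Iterable[SNPRecord]):
        recs = sorted(records, key=lambda r: (r.chrom, r.pos))
        seen = None
        for r in recs:
            key = (r.chrom, r.pos)
            if key == seen:
                raise ValueError(f"duplicate panel site {r.chrom}:{r.pos}")
            seen = key
        self._records = recs
        self._by_chrom: dict[str, tuple[list[int], list[SNPRecord]]] = {}
        for r in recs:
            pos_list, rec_list = self._by_chrom.setdefault(r.chrom, ([], []))
            pos_list.append(r.pos0)
            rec_list.append(r)

    @property
    def records(self) -> Sequence[SNPRecord]:
        return tuple(self._records)

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SNPRecord]:
        return iter(self._records)

    def get(self, chrom: str, pos: int) -> Optional[SNPRecord]:
        """Record at 1-based (chrom, pos), or None."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        pos_list, rec_list = entry
        i = bisect_left(pos_list, pos - 1)
        if i < len(pos_list) and pos_list[i] == pos - 1:
            return rec_list[i]
        return None

    def overlapping(self, chrom: str, start0: int, end0: int) -> list[SNPRecord]:
        """Records with 0-based position in [start0, end0)."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        pos_list, rec_list = entry
        lo = bisect_left(pos_list, start0)
        hi = bisect_left(pos_list, end0)
        return rec_list[lo:hi]

    def __eq__(self, other) -> bool:
        return isinstance(other, SNPPanel) and self._records == other._records


# ---------------------------------------------------------------------------
# Readers

def _read_alleles_tsv(path) -> list[SNPRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PanelParseError(
                    f"expected >= 4 tab-separated fields, got {len(fields)}",
                    lineno,
                )
            chrom, pos_s, ref, alt = fields[:4]
            maf = None
            if len(fields) >= 5 and fields[4] not in ("", "."):
                try:
                    maf = float(fields[4])
                except ValueError:
                    raise PanelParseError(f"bad maf {fields[4]!r}", lineno)
            try:
                pos = int(pos_s)
            except ValueError:
                raise PanelParseError(f"bad position {pos_s!r}", lineno)
            try:
                records.append(SNPRecord(chrom, pos, ref, alt, maf=maf))
            except ValueError as e:
                raise PanelParseError(str(e), lineno)
    return records


def _read_eigenstrat_snp(path) -> list[SNPRecord]:
    """6-column EIGENSTRAT .snp: id chrom genetic_pos pos allele1 allele2.

    allele1 is taken as the reference allele, allele2 as the alternative.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6:
                raise PanelParseError(
                    f"expected 6 whitespace-separated fields, got {len(fields)}",
                    lineno,
                )
            snp_id, chrom, _gpos, pos_s, ref, alt = fields
            try:
                pos = int(pos_s)
            except ValueError:
                raise PanelParseError(f"bad position {pos_s!r}", lineno)
            try:
                records.append(SNPRecord(chrom, pos, ref, alt, id=snp_id))
            except ValueError as e:
                raise PanelParseError(str(e), lineno)
    return records


def _read_vcf(path) -> list[SNPRecord]:
    from cyvcf2 import VCF

    records = []
    vcf = VCF(str(path))
    try:
        for v in vcf:
            if len(v.ALT) != 1:
                raise PanelParseError(
                    f"{v.CHROM}:{v.POS}: multi-allelic record (ALT={v.ALT}); "
                    "only biallelic SNVs are accepted"
                )
            ref, alt = v.REF, v.ALT[0]
            if len(ref) != 1 or len(alt) != 1:
                raise PanelParseError(
                    f"{v.CHROM}:{v.POS}: not a SNV ({ref}->{alt})"
                )
            records.append(
                SNPRecord(v.CHROM, v.POS, ref, alt, id=v.ID or None)
            )
    finally:
        vcf.close()
    return records


_READERS = {
    "alleles_tsv": _read_alleles_tsv,
    "eigenstrat_snp": _read_eigenstrat_snp,
    "vcf": _read_vcf,
}


def read_panel(path, format: str) -> SNPPanel:
    """Read a SNP panel from disk.

    Parameters
    ----------
    path : path to the panel file
    format : one of ``eigenstrat_snp``, ``vcf``, ``alleles_tsv``

    The returned panel is sorted by (chrom, pos); duplicated positions and
    multi-allelic VCF records are rejected.
    """
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(
            f"unknown panel format {format!r}; expected one of {sorted(_READERS)}"
        )
    return SNPPanel(reader(path))


def write_panel_tsv(panel: SNPPanel, path) -> None:
    """Write a panel in the alleles_tsv dialect (with maf/ancestry columns)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\tmaf\tancestry\n")
        for r in panel:
            maf = "" if r.maf is None else f"{r.maf:g}"
            anc = r.ancestry or ""
            fh.write(f"{r.chrom}\t{r.pos}\t{r.ref_allele}\t{r.alt_allele}\t{maf}\t{anc}\n")


# ---------------------------------------------------------------------------
# Interval sets (BED; 0-based half-open)

def read_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Read a 3+-column BED file into {chrom: [(start, end), ...]}, sorted."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PanelParseError("BED line with < 3 fields", lineno)
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            intervals.setdefault(chrom, []).append((start, end))
    for chrom in intervals:
        intervals[chrom].sort()
    return intervals


def read_labeled_bed(path) -> list[tuple[str, int, int, str]]:
    """Read a 4-column BED of labeled segments: (chrom, start, end, label)."""
    segments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PanelParseError("labeled BED line with < 4 fields", lineno)
            segments.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
    return segments


def _in_intervals(sorted_ivals: list[tuple[int, int]], pos0: int) -> bool:
    i = bisect_right(sorted_ivals, (pos0, float("inf")))
    if i == 0:
        return False
    start, end = sorted_ivals[i - 1]
    return start <= pos0 < end


# ---------------------------------------------------------------------------
# Filters

def filter_transversions(panel: SNPPanel) -> SNPPanel:
    """Retain only transversion sites ({ref, alt} not {A,G} and not {C,T})."""
    return SNPPanel(r for r in panel if r.is_transversion)


def filter_by_frequency(panel: SNPPanel, min_maf: float) -> SNPPanel:
    """Retain records with minor-allele frequency >= min_maf (inclusive)."""
    missing = [f"{r.chrom}:{r.pos}" for r in panel if r.maf is None]
    if missing:
        raise ValueError(
            f"{len(missing)} records lack a maf (first: {missing[0]}); "
            "frequency filtering requires maf on every record"
        )
    return SNPPanel(r for r in panel if r.maf >= min_maf)


def apply_mappability_mask(
    panel: SNPPanel, mask: dict[str, list[tuple[int, int]]]
) -> SNPPanel:
    """Retain records whose position lies inside a mask interval.

    Mask intervals are 0-based half-open (BED convention).  Intervals on
    chromosomes absent from the panel are ignored with a warning.
    """
    panel_chroms = set(panel.chroms)
    unknown = sorted(set(mask) - panel_chroms)
    if unknown:
        warnings.warn(
            f"mask intervals on chromosomes absent from the panel ignored: {unknown}"
        )
    kept = []
    for r in panel:
        ivals = mask.get(r.chrom)
        if ivals and _in_intervals(ivals, r.pos0):
            kept.append(r)
    return SNPPanel(kept)


def annotate_ancestry(
    panel: SNPPanel, segments: Iterable[tuple[str, int, int, str]]
) -> SNPPanel:
    """Label each SNP with the ancestry of its containing reference segment.

    ``segments`` are (chrom, start0, end0, label) with labels from
    {African, European, EastAsian, Uncertain}; sites contained in no
    segment are labeled Uncertain.  Overlapping segments with conflicting
    labels are an error.
    """
    segs = sorted(segments, key=lambda s: (s[0], s[1], s[2]))
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, label in segs:
        if label not in ANCESTRY_LABELS:
            raise ValueError(f"unknown ancestry label {label!r}")
        prev = by_chrom.setdefault(chrom, [])
        if prev:
            p_start, p_end, p_label = prev[-1]
            if start < p_end and label != p_label:
                raise ValueError(
                    f"conflicting ancestry labels on {chrom}: "
                    f"[{p_start},{p_end})={p_label} overlaps [{start},{end})={label}"
                )
        prev.append((start, end, label))
    out = []
    for r in panel:
        label = "Uncertain"
        for start, end, seg_label in by_chrom.get(r.chrom, ()):
            if start <= r.pos0 < end:
                label = seg_label
                break
            if start > r.pos0:
                break
        out.append(replace(r, ancestry=label))
    return SNPPanel(out)
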