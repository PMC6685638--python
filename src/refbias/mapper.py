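"""Deterministic internal short-read mapper and alignment pre-filters.

The mapper emulates the behaviour that matters for reference bias in
ancient-DNA pipelines: a length-dependent edit-distance budget, a cap on
gap opens, and a mapping quality that reflects placement uniqueness.  It
is a seed-and-extend design — exact k-mer seeds on both strands followed
by banded edit-distance verification (edlib) — and is fully deterministic,
so every remapping-based diagnostic and filter in this package can be
tested in a closed loop without external aligner binaries.

The edit budget follows a Poisson model: ``maxdiff(L)`` is the smallest k
such that the upper tail P(X > k) of X ~ Poisson(L * err_rate) falls below
``miss_frac``.  This mirrors the way short-read aligners scale the number
of accepted differences with read length; no bit-for-bit agreement with
any particular external aligner build is promised.

MAPQ model (documented so that thresholds are meaningful): 37 for a unique
best hit with no other hit inside the budget, 25 for a unique best hit
with suboptimal hits inside the budget, 0 for two or more co-optimal hits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
from scipy.stats import poisson

from .genome import ReferenceGenome, revcomp

MAPQ_UNIQUE = 37
MAPQ_SUBOPTIMAL = 25

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class MapperParams:
    """Mapping stringency parameters.

    err_rate
        Per-base rate of the Poisson error model behind the edit budget.
    miss_frac
        Accepted probability mass of reads whose true error count exceeds
        the budget (smaller = more permissive budget).
    max_gap_opens
        Maximum number of gap openings (contiguous indel runs) accepted.
    seed_disabled
        Kept for interface parity with aligners whose seeding can be
        switched off; the internal mapper's pigeonhole seeding is exact,
        so this flag has no effect on results.
    """

    err_rate: float = 0.02
    miss_frac: float = 0.01
    max_gap_opens: int = 2
    seed_disabled: bool = True

    def __post_init__(self):
        if not 0.0 < self.miss_frac < 1.0:
            raise ValueError("miss_frac must be in (0, 1)")
        if self.err_rate <= 0.0:
            raise ValueError("err_rate must be > 0")
        if self.max_gap_opens < 0:
            raise ValueError("max_gap_opens must be >= 0")


@dataclass(eq=False)
class ReadAlignment:
    """A mapped fragment, sequence stored in reference-forward orientation.

    ``cigar`` uses extended operations (=, X, I, D) with the read as query
    and the reference as target; for minus-strand alignments both sequence
    and qualities are stored reverse-complemented/reversed so allele
    lookup at SNPs needs no strand logic.
    """

    read_id: str
    sequence: str
    base_quals: np.ndarray
    chrom: str
    start: int  # 0-based
    strand: str  # '+' or '-'
    mapq: int
    edit_distance: int
    has_indel: bool
    cigar: str
    read_group: Optional[str] = None
    is_duplicate: bool = False

    def __post_init__(self):
        self.base_quals = np.asarray(self.base_quals, dtype=np.int64)
        if len(self.sequence) != len(self.base_quals):
            raise ValueError("sequence and base_quals lengths differ")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.mapq < 0 or self.edit_distance < 0:
            raise ValueError("mapq and edit_distance must be >= 0")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def ref_end(self) -> int:
        """0-based exclusive end on the reference (start + reference span)."""
        span = 0
        for n, op in _CIGAR_RE.findall(self.cigar):
            if op in "=XMD":
                span += int(n)
        return self.start + span

    def read_offset_at(self, ref_pos0: int) -> Optional[int]:
        """Read index aligned to reference position ``ref_pos0``.

        Returns None if the position is outside the alignment or removed
        by a deletion in the read.
        """
        if not self.start <= ref_pos0 < self.ref_end:
            return None
        ref = self.start
        read = 0
        for n, op in _CIGAR_RE.findall(self.cigar):
            n = int(n)
            if op in "=XM":
                if ref <= ref_pos0 < ref + n:
                    return read + (ref_pos0 - ref)
                ref += n
                read += n
            elif op == "D":
                if ref <= ref_pos0 < ref + n:
                    return None
                ref += n
            elif op == "I":
                read += n
        return None


@lru_cache(maxsize=4096)
def _maxdiff_cached(length: int, err_rate: float, miss_frac: float) -> int:
    mu = length * err_rate
    k = 0
    while poisson.sf(k, mu) >= miss_frac:
        k += 1
    return k


def maxdiff(length: int, err_rate: float = 0.02, miss_frac: float = 0.01) -> int:
    """Edit-distance budget for a read of the given length.

    Smallest k with P(X > k) < miss_frac for X ~ Poisson(length * err_rate).
    Non-decreasing in length, non-increasing in miss_frac.
    """
    if length < 0:
        raise ValueError("length must be >= 0")
    return _maxdiff_cached(length, err_rate, miss_frac)


def _parse_cigar_stats(cigar: str) -> tuple[int, bool]:
    """(number of gap opens, any indel present) from an extended CIGAR."""
    gap_opens = 0
    has_indel = False
    for _n, op in _CIGAR_RE.findall(cigar):
        if op in "ID":
            gap_opens += 1
            has_indel = True
    return gap_opens, has_indel


class Mapper:
    """Seed-and-extend mapper over an in-memory reference.

    Builds exact k-mer indexes lazily per seed length.  For a read of
    length L with budget e = maxdiff(L), e + 1 non-overlapping seeds are
    queried on both strands; by the pigeonhole principle every placement
    within the edit budget shares at least one exact seed, so hit
    enumeration (and hence MAPQ) is exhaustive within the budget.
    """

    def __init__(self, reference: ReferenceGenome, params: MapperParams | None = None):
        if len(reference) == 0 or reference.total_length() == 0:
            raise ValueError("reference is empty")
        self.reference = reference
        self.params = params or MapperParams()
        self._chrom_names = sorted(reference.names)
        self._seqs = {name: reference[name] for name in self._chrom_names}
        self._indexes: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _seed_index(self, k: int) -> dict[str, list[tuple[str, int]]]:
        idx = self._indexes.get(k)
        if idx is None:
            idx = {}
            for name in self._chrom_names:
                seq = self._seqs[name]
                for i in range(len(seq) - k + 1):
                    idx.setdefault(seq[i : i + k], []).append((name, i))
            self._indexes[k] = idx
        return idx

    def map_read(
        self,
        sequence: str,
        base_quals: Optional[Sequence[int]] = None,
        read_id: str = "read",
        read_group: Optional[str] = None,
    ) -> Optional[ReadAlignment]:
        """Map one read; returns None if no placement fits the budget."""
        sequence = sequence.upper()
        L = len(sequence)
        if L == 0:
            raise ValueError("empty read sequence")
        if base_quals is None:
            base_quals = np.full(L, 40, dtype=np.int64)
        base_quals = np.asarray(base_quals, dtype=np.int64)
        p = self.params
        budget = maxdiff(L, p.err_rate, p.miss_frac)

        n_seeds = budget + 1
        seed_len = max(4, L // n_seeds)
        # quantize so only a handful of k-mer indexes are ever built
        for canonical in (16, 14, 12, 10, 8, 6, 4):
            if canonical <= seed_len:
                seed_len = canonical
                break
        seed_len = min(seed_len, L)
        index = self._seed_index(seed_len)
        offsets = [i * seed_len for i in range(n_seeds)]
        offsets = sorted({min(off, L - seed_len) for off in offsets})

        queries = {"+": sequence, "-": revcomp(sequence)}
        candidates: set[tuple[str, str, int]] = set()
        for strand, query in queries.items():
            for off in offsets:
                for name, hit in index.get(query[off : off + seed_len], ()):
                    candidates.add((strand, name, hit - off))

        # raw hits: placement -> (distance, gap_opens, cigar)
        hits: dict[tuple[str, str, int], tuple[int, int, str]] = {}

        def record(name, strand, start, dist, gap_opens, cigar):
            key = (name, strand, start)
            prev = hits.get(key)
            if prev is None or (dist, gap_opens) < (prev[0], prev[1]):
                hits[key] = (dist, gap_opens, cigar)

        pad = budget + 1
        for strand, name, cand_start in candidates:
            chrom_seq = self._seqs[name]
            query = queries[strand]
            # substitution-only placement at the seed-implied start: checked
            # exactly so that, at equal edit distance, a mismatch alignment
            # is preferred over a gapped re-representation of it
            if 0 <= cand_start and cand_start + L <= len(chrom_seq):
                seg = chrom_seq[cand_start : cand_start + L]
                d_h = 0
                for qc, sc in zip(query, seg):
                    if qc != sc:
                        d_h += 1
                        if d_h > budget:
                            break
                if d_h <= budget:
                    record(name, strand, cand_start, d_h, 0, f"{L}M")
            # gapped placements via banded edit distance around the seed
            ws = max(0, cand_start - pad)
            we = min(len(chrom_seq), cand_start + L + pad)
            if we - ws < seed_len:
                continue
            res = edlib.align(query, chrom_seq[ws:we], mode="HW", task="path", k=budget)
            if res["editDistance"] == -1:
                continue
            gap_opens, _indel = _parse_cigar_stats(res["cigar"])
            if gap_opens > p.max_gap_opens:
                continue
            record(
                name,
                strand,
                ws + res["locations"][0][0],
                res["editDistance"],
                gap_opens,
                res["cigar"],
            )

        if not hits:
            return None

        # cluster placements whose starts differ by <= budget on the same
        # chromosome and strand: those are alternative representations of
        # one physical locus, not independent hits
        loci: list[tuple[int, int, str, str, int, str]] = []
        for (name, strand, start), (dist, gaps, cigar) in sorted(hits.items()):
            if (
                loci
                and loci[-1][3] == name
                and loci[-1][2] == strand
                and start - loci[-1][4] <= budget
            ):
                prev = loci[-1]
                if (dist, gaps, start) < (prev[0], prev[1], prev[4]):
                    loci[-1] = (dist, gaps, strand, name, start, cigar)
                else:
                    loci[-1] = prev
            else:
                loci.append((dist, gaps, strand, name, start, cigar))

        best_dist = min(l[0] for l in loci)
        co_optimal = [l for l in loci if l[0] == best_dist]
        # deterministic tie-break: lowest chrom name, lowest start, '+' first
        co_optimal.sort(key=lambda l: (l[3], l[4], l[2] != "+"))
        best_dist_, gaps, strand, name, start, cigar = co_optimal[0]
        dist = best_dist_
        if len(co_optimal) >= 2:
            mapq = 0
        elif len(loci) > 1:
            mapq = MAPQ_SUBOPTIMAL
        else:
            mapq = MAPQ_UNIQUE
        _gap_opens, has_indel = _parse_cigar_stats(cigar)
        if strand == "-":
            stored_quals = base_quals[::-1].copy()
        else:
            stored_quals = base_quals
        return ReadAlignment(
            read_id=read_id,
            sequence=queries[strand],
            base_quals=stored_quals,
            chrom=name,
            start=start,
            strand=strand,
            mapq=mapq,
            edit_distance=dist,
            has_indel=has_indel,
            cigar=cigar,
            read_group=read_group,
        )

    def map_reads(self, reads: Iterable) -> list[ReadAlignment]:
        """Map an iterable of objects with .read_id/.sequence/.base_quals.

        Unmapped reads are dropped; output is coordinate-sorted.
        """
        out = []
        for read in reads:
            aln = self.map_read(
                read.sequence,
                getattr(read, "base_quals", None),
                read_id=read.read_id,
                read_group=getattr(read, "read_group", None),
            )
            if aln is not None:
                out.append(aln)
        out.sort(key=lambda a: (a.chrom, a.start, a.read_id))
        return out


def remap_reference_forward(
    mapper: Mapper,
    sequence: str,
    base_quals,
    original_strand: str,
    read_id: str = "read",
) -> Optional[ReadAlignment]:
    """Remap a reference-forward stored sequence in sequencing orientation.

    Alignments keep sequences reference-forward; to re-evaluate a read the
    way it was sequenced (so strand round-trips), minus-strand reads are
    reverse-complemented back first.
    """
    if original_strand == "-":
        sequence = revcomp(sequence)
        base_quals = np.asarray(base_quals)[::-1]
    return mapper.map_read(sequence, base_quals, read_id=read_id)


def map_read(
    sequence: str,
    base_quals,
    reference: ReferenceGenome,
    params: MapperParams | None = None,
    read_id: str = "read",
) -> Optional[ReadAlignment]:
    """One-shot convenience wrapper; use :class:`Mapper` for many reads."""
    return Mapper(reference, params).map_read(sequence, base_quals, read_id=read_id)


def compute_mappability(
    reference: ReferenceGenome, k: int = 35
) -> dict[str, list[tuple[int, int]]]:
    """Positions whose k-mer occurs exactly once genome-wide (both strands).

    Returns merged half-open intervals of unique k-mer start positions per
    chromosome.  A k-mer and its reverse complement are one sequence
    observed from two strands, so occurrences of both orientations count.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: dict[str, int] = {}
    for _name, seq in reference.items():
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    intervals: dict[str, list[tuple[int, int]]] = {}
    for name, seq in reference.items():
        runs = []
        run_start = None
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            total = counts.get(kmer, 0) + counts.get(revcomp(kmer), 0)
            if kmer == revcomp(kmer):  # palindrome counted once per strand
                total = counts[kmer] * 2
            if total == 1:
                if run_start is None:
                    run_start = i
            else:
                if run_start is not None:
                    runs.append((run_start, i))
                    run_start = None
        if run_start is not None:
            runs.append((run_start, len(seq) - k + 1))
        intervals[name] = runs
    return intervals


def remove_duplicates(alignments: Sequence[ReadAlignment]) -> list[ReadAlignment]:
    """Collapse PCR duplicates: reads sharing (chrom, start, end, strand).

    Input must be coordinate-sorted.  The survivor is the read with the
    highest base-quality sum (ties broken by read_id order); the others
    are marked ``is_duplicate`` and dropped from the returned list.
    """
    last = None
    for a in alignments:
        key = (a.chrom, a.start)
        if last is not None and key < last:
            raise ValueError("alignments must be coordinate-sorted")
        last = key
    groups: dict[tuple, list[ReadAlignment]] = {}
    order: list[tuple] = []
    for a in alignments:
        key = (a.chrom, a.start, a.ref_end, a.strand)
        if key not in groups:
            order.append(key)
        groups.setdefault(key, []).append(a)
    survivors = []
    for key in order:
        group = groups[key]
        best = min(group, key=lambda a: (-int(a.base_quals.sum()), a.read_id))
        for a in group:
            if a is not best:
                a.is_duplicate = True
        survivors.append(best)
    survivors.sort(key=lambda a: (a.chrom, a.start, a.read_id))
    return survivors


def filter_short(
    alignments: Iterable[ReadAlignment], min_length: int = 35
) -> list[ReadAlignment]:
    """Drop fragments shorter than ``min_length`` (35 bp boundary kept)."""
    return [a for a in alignments if a.length >= min_length]
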