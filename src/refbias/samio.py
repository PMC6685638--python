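"""SAM/BAM round-tripping for internal alignments (via pysam).

The internal :class:`~refbias.mapper.ReadAlignment` already stores the
sequence reference-forward, exactly as SAM does, so conversion is direct.
Edit distance is carried in the ``NM`` tag and read groups in ``RG``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pysam

from .genome import ReferenceGenome
from .mapper import ReadAlignment

_SAM_OPS = {"=": 7, "X": 8, "I": 1, "D": 2, "M": 0}
_OPS_SAM = {0: "M", 1: "I", 2: "D", 7: "=", 8: "X"}

import re

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _cigartuples(cigar: str) -> list[tuple[int, int]]:
    return [(_SAM_OPS[op], int(n)) for n, op in _CIGAR_RE.findall(cigar)]


def write_sam(
    alignments: Sequence[ReadAlignment],
    reference: ReferenceGenome,
    path,
    read_groups: Optional[Sequence[str]] = None,
) -> None:
    """Write alignments as a plain-text SAM file with a proper header."""
    names = reference.names
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": reference.length(n)} for n in names],
    }
    groups = sorted(
        {a.read_group for a in alignments if a.read_group is not None}
        | set(read_groups or ())
    )
    if groups:
        header["RG"] = [{"ID": g} for g in groups]
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = a.read_id
            seg.query_sequence = a.sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in a.base_quals)
            )
            seg.reference_id = tid[a.chrom]
            seg.reference_start = a.start
            seg.mapping_quality = a.mapq
            seg.cigartuples = _cigartuples(a.cigar)
            seg.flag = (0x10 if a.strand == "-" else 0) | (
                0x400 if a.is_duplicate else 0
            )
            tags = [("NM", a.edit_distance)]
            if a.read_group is not None:
                tags.append(("RG", a.read_group))
            seg.set_tags(tags)
            out.write(seg)


def read_sam(path) -> list[ReadAlignment]:
    """Read mapped records from a SAM/BAM file into ReadAlignments."""
    out = []
    with pysam.AlignmentFile(str(path)) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            cigar = "".join(
                f"{n}{_OPS_SAM[op]}" for op, n in seg.cigartuples or ()
            )
            quals = (
                np.array(seg.query_qualities, dtype=np.int64)
                if seg.query_qualities is not None
                else np.full(len(seg.query_sequence), 40, dtype=np.int64)
            )
            has_indel = any(op in (1, 2) for op, _ in seg.cigartuples or ())
            out.append(
                ReadAlignment(
                    read_id=seg.query_name,
                    sequence=seg.query_sequence,
                    base_quals=quals,
                    chrom=seg.reference_name,
                    start=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    mapq=seg.mapping_quality,
                    edit_distance=int(seg.get_tag("NM"))
                    if seg.has_tag("NM")
                    else 0,
                    has_indel=has_indel,
                    cigar=cigar,
                    read_group=seg.get_tag("RG") if seg.has_tag("RG") else None,
                    is_duplicate=seg.is_duplicate,
                )
            )
    return out
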