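"""Reference genome container and FASTA round-tripping.

Sequences are stored as plain upper-case strings over the alphabet
{A, C, G, T, N}.  All internal coordinates are 0-based half-open; the
conversion from the 1-based on-disk conventions (EIGENSTRAT, VCF) happens
exactly once, at parse time.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import pyfaidx

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceGenome:
    """An in-memory reference assembly: an ordered mapping name -> sequence.

    Supports point substitution (returning a new genome, the original is
    never mutated) and subsequence extraction, which is all the internal
    mapper and the remapping filters need.
    """

    def __init__(self, sequences: Mapping[str, str]):
        seqs = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            extra = set(seq) - _VALID
            if extra:
                raise ValueError(
                    f"sequence {name!r} contains invalid bases: {sorted(extra)}"
                )
            if name in seqs:
                raise ValueError(f"duplicate sequence name {name!r}")
            seqs[name] = seq
        self._seqs = seqs

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def items(self) -> Iterable[tuple[str, str]]:
        return self._seqs.items()

    def length(self, name: str) -> int:
        return len(self._seqs[name])

    def total_length(self) -> int:
        return sum(len(s) for s in self._seqs.values())

    def subsequence(self, name: str, start: int, end: int) -> str:
        """Extract [start, end) of a named sequence (0-based half-open)."""
        if start < 0 or end > len(self._seqs[name]) or start > end:
            raise IndexError(
                f"[{start}, {end}) out of range for {name!r} "
                f"(length {len(self._seqs[name])})"
            )
        return self._seqs[name][start:end]

    def with_substitutions(
        self, substitutions: Iterable[tuple[str, int, str]]
    ) -> "ReferenceGenome":
        """Return a new genome with point substitutions applied.

        ``substitutions`` is an iterable of (name, position0, base).
        """
        muts: dict[str, list[tuple[int, str]]] = {}
        for name, pos, base in substitutions:
            if name not in self._seqs:
                raise KeyError(f"unknown sequence {name!r}")
            if base not in _VALID:
                raise ValueError(f"invalid base {base!r}")
            if not 0 <= pos < len(self._seqs[name]):
                raise IndexError(f"position {pos} out of range for {name!r}")
            muts.setdefault(name, []).append((pos, base))
        new = {}
        for name, seq in self._seqs.items():
            if name in muts:
                chars = list(seq)
                for pos, base in muts[name]:
                    chars[pos] = base
                seq = "".join(chars)
            new[name] = seq
        return ReferenceGenome(new)

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        try:
            return cls({name: str(fa[name][:]) for name in fa.keys()})
        finally:
            fa.close()

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def __eq__(self, other) -> bool:
        return isinstance(other, ReferenceGenome) and self._seqs == other._seqs

    def __repr__(self) -> str:
        return (
            f"ReferenceGenome({len(self._seqs)} sequences, "
            f"{self.total_length()} bp)"
        )
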