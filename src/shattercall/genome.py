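"""Reference genome container and nucleotide-sequence helpers.

Coordinates are 1-based inclusive everywhere inside this package;
conversion to 0-based half-open formats (BEDPE) happens only at the file
format boundary in :mod:`shattercall.io_cli`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C bases in *seq* (0 for the empty string)."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def chrom_sort_key(name: str) -> tuple:
    """Natural sort key so that '2' < '11' and 'chr2' < 'chr11'."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass
class ReferenceGenome:
    """Ordered map of chromosome name -> nucleotide sequence (A/C/G/T only).

    All sequences must be non-empty and names unique (enforced by the dict).
    """

    chromosomes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not name:
                raise ValueError("chromosome name must be non-empty")
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid bases: {sorted(bad)}"
                )

    # -- basic queries -------------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __iter__(self) -> Iterator[str]:
        return iter(self.chromosomes)

    def length(self, name: str) -> int:
        return len(self.chromosomes[name])

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom`` between *start* and *end*, 1-based inclusive.

        Coordinates are clamped to the chromosome bounds, so a window
        hanging over an edge returns the truncated sequence.
        """
        if chrom not in self.chromosomes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self.chromosomes[chrom]
        start = max(1, start)
        end = min(len(seq), end)
        if end < start:
            return ""
        return seq[start - 1 : end]

    def base(self, chrom: str, pos: int) -> str:
        seq = self.chromosomes[chrom]
        if not 1 <= pos <= len(seq):
            raise IndexError(f"{chrom}:{pos} out of bounds (length {len(seq)})")
        return seq[pos - 1]


def flank_into(ref: ReferenceGenome, chrom: str, pos: int, strand: str, n: int) -> str:
    """Reference sequence approaching a junction whose last retained base
    is ``chrom:pos`` on *strand*, reading in junction orientation.

    For '+' this is ``ref[pos-n+1 .. pos]``; for '-' it is the reverse
    complement of ``ref[pos .. pos+n-1]``.  Truncated at chromosome edges.
    """
    if strand == "+":
        return ref.fetch(chrom, pos - n + 1, pos)
    if strand == "-":
        return revcomp(ref.fetch(chrom, pos, pos + n - 1))
    raise ValueError(f"invalid strand {strand!r}")


def flank_from(ref: ReferenceGenome, chrom: str, pos: int, strand: str, n: int) -> str:
    """Reference sequence leaving a junction whose first retained base is
    ``chrom:pos`` on *strand*, reading in junction orientation.

    For '+' this is ``ref[pos .. pos+n-1]``; for '-' it is the reverse
    complement of ``ref[pos-n+1 .. pos]``.  Truncated at chromosome edges.
    """
    if strand == "+":
        return ref.fetch(chrom, pos, pos + n - 1)
    if strand == "-":
        return revcomp(ref.fetch(chrom, pos - n + 1, pos))
    raise ValueError(f"invalid strand {strand!r}")
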