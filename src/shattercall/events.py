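"""Rearrangement events and junction chemistry specifications."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .genome import VALID_BASES


class JunctionClass(str, Enum):
    MICROHOMOLOGY = "MICROHOMOLOGY"
    BLUNT = "BLUNT"
    INSERTION = "INSERTION"


#: Orientation classes of a rearrangement junction.
#: CT = inter-chromosomal translocation; LD = long deletion (concordant
#: orientation, excessive distance); FF = forward/forward (inversion-type,
#: the reverse/reverse flavour is folded in); RF = reverse/forward
#: (duplication-type).
REARRANGEMENT_TYPES = ("CT", "LD", "FF", "RF")


@dataclass(frozen=True)
class InsertionOrigin:
    """Templated origin of an inserted junction sequence.

    ``anchor`` names the breakpoint ('break1' or 'break2'); ``offset`` is
    ``hit_start - breakpoint_position`` on the reference forward strand
    (negative = upstream); ``orientation`` is 'forward' or 'reverse'.
    """

    anchor: str
    offset: int
    orientation: str

    def __post_init__(self) -> None:
        if self.anchor not in ("break1", "break2"):
            raise ValueError(f"anchor must be break1/break2, got {self.anchor!r}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"invalid orientation {self.orientation!r}")


@dataclass(frozen=True)
class JunctionSpec:
    """Chemistry of one junction: microhomology, blunt, or insertion."""

    jclass: JunctionClass
    seq: str = ""
    origin: Optional[InsertionOrigin] = None

    def __post_init__(self) -> None:
        if self.seq and (set(self.seq) - VALID_BASES):
            raise ValueError(f"junction sequence has invalid bases: {self.seq!r}")
        if self.jclass is JunctionClass.MICROHOMOLOGY and len(self.seq) < 1:
            raise ValueError("microhomology requires a sequence of length >= 1")
        if self.jclass is JunctionClass.BLUNT and self.seq:
            raise ValueError("blunt junction must not carry a sequence")
        if self.jclass is JunctionClass.INSERTION and not self.seq:
            raise ValueError("insertion junction requires a non-empty sequence")
        if self.origin is not None and self.jclass is not JunctionClass.INSERTION:
            raise ValueError("origin is only meaningful for insertions")

    # convenience constructors ----------------------------------------
    @staticmethod
    def microhomology(seq: str) -> "JunctionSpec":
        return JunctionSpec(JunctionClass.MICROHOMOLOGY, seq)

    @staticmethod
    def blunt() -> "JunctionSpec":
        return JunctionSpec(JunctionClass.BLUNT)

    @staticmethod
    def insertion(seq: str, origin: Optional[InsertionOrigin] = None) -> "JunctionSpec":
        return JunctionSpec(JunctionClass.INSERTION, seq, origin)


@dataclass(frozen=True)
class RearrangementEvent:
    """A planned or called rearrangement: two breakpoints, an orientation
    type, and (when known) its junction chemistry.

    Positions are 1-based.  For same-chromosome types (LD/FF/RF),
    ``pos1 < pos2`` is required; CT requires different chromosomes.
    """

    id: str
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    rtype: str
    junction: Optional[JunctionSpec] = None

    def __post_init__(self) -> None:
        if self.rtype not in REARRANGEMENT_TYPES:
            raise ValueError(f"unknown rearrangement type {self.rtype!r}")
        if self.pos1 < 1 or self.pos2 < 1:
            raise ValueError(f"event {self.id}: positions must be >= 1")
        if self.rtype == "CT":
            if self.chrom1 == self.chrom2:
                raise ValueError(f"event {self.id}: CT requires distinct chromosomes")
        else:
            if self.chrom1 != self.chrom2:
                raise ValueError(
                    f"event {self.id}: {self.rtype} requires a single chromosome"
                )
            if not self.pos1 < self.pos2:
                raise ValueError(f"event {self.id}: requires pos1 < pos2")

    @property
    def breakpoints(self) -> list[tuple[str, int]]:
        return [(self.chrom1, self.pos1), (self.chrom2, self.pos2)]

    @property
    def is_interchromosomal(self) -> bool:
        return self.chrom1 != self.chrom2
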