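"""Junction chemistry classification and breakpoint proximity statistics.

Classifies a sequence spanning a rearrangement junction into
microhomology / blunt / insertion by maximal exact anchored extension
against the two reference sides, searches for templated origins of
inserted sequence, and computes inter-event breakpoint distances.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .events import InsertionOrigin, JunctionClass, RearrangementEvent
from .genome import ReferenceGenome, revcomp
from .synthetic_data import JunctionSide


class NoAnchorError(ValueError):
    """A junction flank could not be located on its reference side."""


@dataclass(frozen=True)
class JunctionCall:
    """Classification of one junction."""

    event_id: str
    jclass: JunctionClass
    mh_seq: str = ""
    ins_seq: str = ""
    ins_origin: Optional[InsertionOrigin] = None

    def __post_init__(self) -> None:
        if self.jclass is JunctionClass.MICROHOMOLOGY:
            if not self.mh_seq or self.ins_seq:
                raise ValueError("microhomology call requires mh_seq only")
        elif self.jclass is JunctionClass.BLUNT:
            if self.mh_seq or self.ins_seq:
                raise ValueError("blunt call carries no sequence")
        else:
            if not self.ins_seq or self.mh_seq:
                raise ValueError("insertion call requires ins_seq only")

    @property
    def mh_len(self) -> int:
        return len(self.mh_seq)

    @property
    def ins_len(self) -> int:
        return len(self.ins_seq)


def _as_side(anchor) -> JunctionSide:
    if isinstance(anchor, JunctionSide):
        return anchor
    chrom, pos, strand = anchor
    return JunctionSide(chrom, pos, strand)


def classify_junction(
    junction_seq: str,
    ref: ReferenceGenome,
    break1,
    break2,
    flank: int = 30,
    event_id: str = "",
) -> JunctionCall:
    """Classify a fusion-spanning sequence against its two reference sides.

    ``break1`` is the (chrom, pos, strand) of the last retained base on
    the incoming side; ``break2`` of the first retained base on the
    outgoing side.  The junction sequence must carry at least *flank*
    matchable bases on each side.  The two anchored matches are extended
    maximally; overlap = microhomology, gap = insertion, abutment =
    blunt (so a k-bp microhomology always beats a (k-1)+insertion
    reading).
    """
    if flank < 20:
        raise ValueError("flank must be >= 20")
    n = len(junction_seq)
    if n < 2 * flank:
        raise ValueError(
            f"junction sequence ({n} bp) shorter than two flanks ({2 * flank} bp)"
        )
    side1 = _as_side(break1)
    side2 = _as_side(break2)

    # Each reference walk covers n bases on both sides of its breakpoint
    # (in junction orientation) so a maximal match may extend across the
    # junction point itself.
    if side1.strand == "+":
        left_ref = ref.fetch(side1.chrom, side1.pos - n + 1, side1.pos + n)
    else:
        left_ref = revcomp(ref.fetch(side1.chrom, side1.pos - n, side1.pos + n - 1))
    a = left_ref.find(junction_seq[:flank])
    if a < 0:
        raise NoAnchorError("left flank does not match the break1-side reference")
    i = flank
    while i < n and a + i < len(left_ref) and junction_seq[i] == left_ref[a + i]:
        i += 1
    left_extent_end = i - 1  # last junction index matching the left side

    if side2.strand == "+":
        right_ref = ref.fetch(side2.chrom, side2.pos - n, side2.pos + n - 1)
    else:
        right_ref = revcomp(ref.fetch(side2.chrom, side2.pos - n + 1, side2.pos + n))
    b = right_ref.find(junction_seq[n - flank :])
    if b < 0:
        raise NoAnchorError("right flank does not match the break2-side reference")
    t = 0
    while (
        n - flank - 1 - t >= 0
        and b - 1 - t >= 0
        and junction_seq[n - flank - 1 - t] == right_ref[b - 1 - t]
    ):
        t += 1
    right_extent_start = n - flank - t  # first junction index matching the right side

    overlap = left_extent_end - right_extent_start + 1
    if overlap > 0:
        return JunctionCall(
            event_id=event_id,
            jclass=JunctionClass.MICROHOMOLOGY,
            mh_seq=junction_seq[right_extent_start : left_extent_end + 1],
        )
    if overlap == 0:
        return JunctionCall(event_id=event_id, jclass=JunctionClass.BLUNT)
    return JunctionCall(
        event_id=event_id,
        jclass=JunctionClass.INSERTION,
        ins_seq=junction_seq[left_extent_end + 1 : right_extent_start],
    )


def find_insertion_origin(
    ins_seq: str,
    ref: ReferenceGenome,
    anchors: dict[str, tuple[str, int]],
    search_window: int = 500,
) -> Optional[InsertionOrigin]:
    """Exact-match search for the template of an inserted sequence.

    Scans ``+-search_window`` around each named breakpoint anchor for
    the insert and its reverse complement; returns the nearest hit as
    (anchor, offset, orientation) with offset = hit start - anchor
    position (negative = upstream), or None when no exact copy exists.
    """
    if not ins_seq:
        raise ValueError("ins_seq must be non-empty")
    if search_window < len(ins_seq):
        raise ValueError("search_window must be at least the insert length")
    candidates: list[tuple[int, str, int, str]] = []
    for name, (chrom, pos) in anchors.items():
        lo = max(1, pos - search_window)
        hi = pos + search_window + len(ins_seq) - 1
        region = ref.fetch(chrom, lo, hi)
        for orientation, target in (("forward", ins_seq), ("reverse", revcomp(ins_seq))):
            start = region.find(target)
            while start != -1:
                offset = (lo + start) - pos
                candidates.append((abs(offset), name, offset, orientation))
                start = region.find(target, start + 1)
    if not candidates:
        return None
    candidates.sort()
    _, name, offset, orientation = candidates[0]
    return InsertionOrigin(name, offset, orientation)


def breakpoint_distances(
    events: Sequence[RearrangementEvent], max_report: int = 1_000
) -> list[tuple[tuple[str, str], tuple[str, str], int]]:
    """All same-chromosome breakpoint distances between different events.

    Returns ((event_a, breakpoint_a), (event_b, breakpoint_b), bp)
    tuples with distance <= max_report, sorted by distance.  Breakpoint
    labels are 'break1'/'break2'.
    """
    points = []
    for e in events:
        points.append((e.id, "break1", e.chrom1, e.pos1))
        points.append((e.id, "break2", e.chrom2, e.pos2))
    out = []
    for i in range(len(points)):
        id_a, lab_a, chrom_a, pos_a = points[i]
        for j in range(i + 1, len(points)):
            id_b, lab_b, chrom_b, pos_b = points[j]
            if id_a == id_b or chrom_a != chrom_b:
                continue
            d = abs(pos_a - pos_b)
            if d <= max_report:
                out.append(((id_a, lab_a), (id_b, lab_b), d))
    out.sort(key=lambda rec: rec[2])
    return out


def summarize_junction_classes(calls: Sequence[JunctionCall]) -> dict:
    """Census of junction classes plus the longest microhomology."""
    counts = Counter(c.jclass for c in calls)
    return {
        "MICROHOMOLOGY": counts.get(JunctionClass.MICROHOMOLOGY, 0),
        "BLUNT": counts.get(JunctionClass.BLUNT, 0),
        "INSERTION": counts.get(JunctionClass.INSERTION, 0),
        "max_mh_len": max((c.mh_len for c in calls), default=0),
    }
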