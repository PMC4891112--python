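"""Truth-known synthetic inputs for every downstream stage.

This module generates random reference genomes, rescales the bundled
demo tables onto them, plants rearrangements with exact junction
chemistry (microhomology / blunt / insertion, optionally templated),
simulates mate-pair reads whose mapping is emulated by coordinate
lifting, simulates SNP-probe copy-number/BAF tracks, and provides the
microbeam dosimetry helper.

Mapping emulation: no real aligner runs.  A simulated read is assigned
reference coordinates by lifting its derivative-contig interval through
the planted block structure; a read overlapping a junction is assigned
to the side covering at least half of it, with the overhang treated as
clipped (a deliberate simplification of BWA behaviour).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .events import JunctionClass, RearrangementEvent
from .genome import ReferenceGenome, chrom_sort_key, revcomp
from .sv_calling import ReadEnd, ReadPair


class ConflictError(ValueError):
    """Two planted events require contradictory reference edits."""


# ---------------------------------------------------------------------------
# dosimetry
# ---------------------------------------------------------------------------

_JOULE_PER_KEV = 1.602176634e-16


@dataclass(frozen=True)
class IrradiationConfig:
    """Microbeam shot parameters: proton count, LET, spot size, medium."""

    n_protons: int
    let_keV_per_um: float = 11.7
    spot_diameter_um: float = 2.0
    density_kg_per_m3: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_protons < 0:
            raise ValueError("n_protons must be >= 0")
        if self.let_keV_per_um <= 0 or self.spot_diameter_um <= 0:
            raise ValueError("LET and spot diameter must be positive")
        if self.density_kg_per_m3 <= 0:
            raise ValueError("density must be positive")


def compute_absorbed_dose(cfg: IrradiationConfig) -> float:
    """Absorbed dose (Gy) deposited in the beam-spot volume.

    Thin-slab estimate: energy over a unit path length is
    ``n_protons * LET * l``; the mass of the traversed slab is
    ``density * spot_area * l``, so the path length cancels and

        dose = n_protons * LET / (density * spot_area).

    Exactly linear in ``n_protons``.  For 100 protons at 11.7 keV/um in
    a 2 um water spot this yields ~59.7 Gy (the source experiment
    reports a rounded 55 Gy for the same configuration; the surrounding
    assumptions there are unstated, so no agreement is forced).
    """
    radius_m = cfg.spot_diameter_um * 1e-6 / 2.0
    area_m2 = math.pi * radius_m**2
    if area_m2 == 0:
        raise ValueError("spot area must be positive")
    let_j_per_m = cfg.let_keV_per_um * _JOULE_PER_KEV / 1e-6
    return cfg.n_protons * let_j_per_m / (cfg.density_kg_per_m3 * area_m2)


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------


def generate_reference(
    chrom_lengths: dict[str, int], gc_fraction: float = 0.41, seed: int = 0
) -> ReferenceGenome:
    """Random reference genome with the requested base composition.

    Bases are drawn i.i.d. with P(G) = P(C) = gc/2, so for chromosomes
    of at least ~100 kb the realized GC fraction lies within about two
    percentage points of the target.  Deterministic for a fixed seed.
    """
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must lie in [0, 1]")
    for name, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {name!r}: length must be positive")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    chroms: dict[str, str] = {}
    for name in sorted(chrom_lengths, key=chrom_sort_key):
        draws = rng.choice(alphabet, size=chrom_lengths[name], p=[at, gc, gc, at])
        chroms[name] = draws.tobytes().decode("ascii")
    return ReferenceGenome(chroms)


# ---------------------------------------------------------------------------
# coordinate rescaling of full-scale tables onto small synthetic genomes
# ---------------------------------------------------------------------------


@dataclass
class RescaleMap:
    """Order-preserving per-chromosome compression of genomic positions.

    Consecutive gaps between anchor positions are capped at ``gap_cap``
    but never stretched, so small distances (e.g. a 5 bp or 377 bp
    breakpoint proximity) survive exactly while chromosomes shrink to a
    tractable size.
    """

    gap_cap: int
    margin: int
    mapping: dict[str, dict[int, int]] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def position(self, chrom: str, pos: int) -> int:
        return self.mapping[chrom][pos]


def build_rescale_map(
    positions_by_chrom: dict[str, Sequence[int]],
    gap_cap: int = 12_000,
    margin: int = 15_000,
) -> RescaleMap:
    if gap_cap <= 0 or margin <= 0:
        raise ValueError("gap_cap and margin must be positive")
    rmap = RescaleMap(gap_cap=gap_cap, margin=margin)
    for chrom in sorted(positions_by_chrom, key=chrom_sort_key):
        anchors = sorted(set(positions_by_chrom[chrom]))
        table: dict[int, int] = {}
        new = margin
        prev = None
        for pos in anchors:
            if prev is not None:
                new += min(pos - prev, gap_cap)
            table[pos] = new
            prev = pos
        rmap.mapping[chrom] = table
        rmap.chrom_lengths[chrom] = new + margin
    return rmap


def rescale_events(
    events: Sequence[RearrangementEvent],
    gap_cap: int = 12_000,
    margin: int = 15_000,
) -> tuple[list[RearrangementEvent], RescaleMap]:
    """Map full-scale event coordinates onto a compact synthetic genome."""
    by_chrom: dict[str, list[int]] = {}
    for e in events:
        by_chrom.setdefault(e.chrom1, []).append(e.pos1)
        by_chrom.setdefault(e.chrom2, []).append(e.pos2)
    rmap = build_rescale_map(by_chrom, gap_cap, margin)
    scaled = [
        RearrangementEvent(
            id=e.id,
            chrom1=e.chrom1,
            pos1=rmap.position(e.chrom1, e.pos1),
            chrom2=e.chrom2,
            pos2=rmap.position(e.chrom2, e.pos2),
            rtype=e.rtype,
            junction=e.junction,
        )
        for e in events
    ]
    return scaled, rmap


def rescale_cna_segments(
    segments: Sequence[dict],
    gap_cap: int = 60_000,
    margin: int = 50_000,
) -> tuple[list[dict], RescaleMap]:
    """Map full-scale copy-number segments onto compact coordinates.

    With the default 60 kb cap and 50 kb margins, a 1 kb probe grid
    leaves every rescaled segment and every neutral gap at least ~30
    probes wide.
    """
    by_chrom: dict[str, list[int]] = {}
    for s in segments:
        by_chrom.setdefault(s["chrom"], []).extend((s["start"], s["end"]))
    rmap = build_rescale_map(by_chrom, gap_cap, margin)
    scaled = [
        {
            **s,
            "start": rmap.position(s["chrom"], s["start"]),
            "end": rmap.position(s["chrom"], s["end"]),
        }
        for s in segments
    ]
    return scaled, rmap


# ---------------------------------------------------------------------------
# junction anchors and chemistry engineering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JunctionSide:
    """One side of a junction.

    The left side's ``pos`` is the last retained base walking into the
    junction; the right side's ``pos`` is the first retained base
    walking out of it.  ``strand`` '-' means the retained sequence is
    the reverse complement of the reference.
    """

    chrom: str
    pos: int
    strand: str


def junction_anchors(event: RearrangementEvent) -> tuple[JunctionSide, JunctionSide]:
    """Retained-base anchors of the single junction an event creates.

    LD keeps ``[1..pos1]`` and resumes at ``pos2+1`` (removing
    ``(pos1, pos2]``); CT fuses the chrom1 prefix to the chrom2 suffix
    starting at ``pos2``; RF joins ``pos2`` back to ``pos1``
    (duplication-type); FF joins ``pos1`` to the reverse complement
    starting at ``pos2`` (inversion-type).
    """
    if event.rtype == "LD":
        return (
            JunctionSide(event.chrom1, event.pos1, "+"),
            JunctionSide(event.chrom2, event.pos2 + 1, "+"),
        )
    if event.rtype == "CT":
        return (
            JunctionSide(event.chrom1, event.pos1, "+"),
            JunctionSide(event.chrom2, event.pos2, "+"),
        )
    if event.rtype == "RF":
        return (
            JunctionSide(event.chrom1, event.pos2, "+"),
            JunctionSide(event.chrom1, event.pos1, "+"),
        )
    if event.rtype == "FF":
        return (
            JunctionSide(event.chrom1, event.pos1, "+"),
            JunctionSide(event.chrom1, event.pos2, "-"),
        )
    raise ValueError(f"unknown rearrangement type {event.rtype!r}")


_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class _Editor:
    """Tracked base edits on a mutable genome copy; conflicting writes to
    the same position raise :class:`ConflictError`."""

    def __init__(self, ref: ReferenceGenome):
        self.seqs = {name: bytearray(seq, "ascii") for name, seq in ref.chromosomes.items()}
        self.registry: dict[tuple[str, int], str] = {}

    def base(self, chrom: str, pos: int) -> str:
        seq = self.seqs[chrom]
        if not 1 <= pos <= len(seq):
            raise ValueError(f"position {chrom}:{pos} out of bounds")
        return chr(seq[pos - 1])

    def write(self, chrom: str, pos: int, base: str) -> None:
        seq = self.seqs[chrom]
        if not 1 <= pos <= len(seq):
            raise ValueError(f"cannot write outside chromosome: {chrom}:{pos}")
        prev = self.registry.get((chrom, pos))
        if prev is not None and prev != base:
            raise ConflictError(
                f"conflicting junction chemistry at {chrom}:{pos} "
                f"({prev!r} vs {base!r}); events overlap"
            )
        self.registry[(chrom, pos)] = base
        seq[pos - 1] = ord(base)

    def write_avoiding(self, chrom: str, pos: int, forbidden: set[str]) -> None:
        """Ensure the base at *pos* is none of *forbidden*, editing it if
        necessary (respecting earlier pinned writes)."""
        current = self.base(chrom, pos)
        pinned = self.registry.get((chrom, pos))
        if pinned is not None:
            if pinned in forbidden:
                raise ConflictError(
                    f"junction guard conflict at {chrom}:{pos}: pinned base "
                    f"{pinned!r} is forbidden here"
                )
            return
        if current not in forbidden:
            self.write(chrom, pos, current)  # pin as-is
            return
        for b in _BASES:
            if b not in forbidden:
                self.write(chrom, pos, b)
                return
        raise ConflictError(f"no admissible base at {chrom}:{pos}")

    def finish(self) -> ReferenceGenome:
        return ReferenceGenome(
            {name: seq.decode("ascii") for name, seq in self.seqs.items()}
        )


def _engineer_event(editor: _Editor, event: RearrangementEvent) -> None:
    """Write the bases realizing one event's junction chemistry.

    Microhomology of length k is written onto both retained flanks;
    guard bases immediately beyond each maximal matched extent are
    forced to differ so the planted chemistry is also the classifier's
    unique maximal answer.
    """
    spec = event.junction
    left, right = junction_anchors(event)
    mh = spec.seq if spec.jclass is JunctionClass.MICROHOMOLOGY else ""
    k = len(mh)

    # microhomology bases on the left retained flank
    for i, base in enumerate(mh):
        if left.strand == "+":
            editor.write(left.chrom, left.pos - k + 1 + i, base)
        else:
            editor.write(left.chrom, left.pos + k - 1 - i, _COMP[base])
    # ... and immediately before the right retained flank
    for i, base in enumerate(mh):
        if right.strand == "+":
            editor.write(right.chrom, right.pos - k + i, base)
        else:
            editor.write(right.chrom, right.pos + k - i, _COMP[base])

    # guard 1: stop the left-side match exactly at the junction.  The
    # next junction character is the insertion's first base, or the first
    # retained right base.
    if spec.jclass is JunctionClass.INSERTION:
        next_char = spec.seq[0]
    elif right.strand == "+":
        next_char = editor.base(right.chrom, right.pos)
    else:
        next_char = _COMP[editor.base(right.chrom, right.pos)]
    if left.strand == "+":
        editor.write_avoiding(left.chrom, left.pos + 1, {next_char})
    else:
        editor.write_avoiding(left.chrom, left.pos - 1, {_COMP[next_char]})

    # guard 2: stop the right-side match exactly after the microhomology.
    # The junction character preceding the right extent is the insertion's
    # last base, or the left flank base k+1 positions from the junction.
    if spec.jclass is JunctionClass.INSERTION:
        prev_char = spec.seq[-1]
    elif left.strand == "+":
        prev_char = editor.base(left.chrom, left.pos - k)
    else:
        prev_char = _COMP[editor.base(left.chrom, left.pos + k)]
    if right.strand == "+":
        editor.write_avoiding(right.chrom, right.pos - k - 1, {prev_char})
    else:
        editor.write_avoiding(right.chrom, right.pos + k + 1, {_COMP[prev_char]})

    # templated insertion origin: write the insert (or its reverse
    # complement) at the stated offset from the named breakpoint
    if spec.jclass is JunctionClass.INSERTION and spec.origin is not None:
        anchor_chrom, anchor_pos = (
            (event.chrom1, event.pos1)
            if spec.origin.anchor == "break1"
            else (event.chrom2, event.pos2)
        )
        planted = spec.seq if spec.origin.orientation == "forward" else revcomp(spec.seq)
        start = anchor_pos + spec.origin.offset
        for i, base in enumerate(planted):
            editor.write(anchor_chrom, start + i, base)


def _scrub_untemplated_insertions(
    editor: _Editor, events: Sequence[RearrangementEvent], window: int = 600
) -> None:
    """Destroy accidental exact copies of origin-unknown insertion
    sequences near their breakpoints, so origin searches return none.

    Only inserts of at least 5 bp are scrubbed: shorter strings occur
    with near-certainty in any window and an exact-origin search for
    them carries no information.
    """
    for event in events:
        spec = event.junction
        if spec is None or spec.jclass is not JunctionClass.INSERTION or spec.origin:
            continue
        if len(spec.seq) < 5:
            continue
        targets = {spec.seq, revcomp(spec.seq)}
        for chrom, pos in event.breakpoints:
            seq = editor.seqs[chrom]
            lo = max(1, pos - window - len(spec.seq))
            hi = min(len(seq), pos + window + len(spec.seq))
            region = seq[lo - 1 : hi].decode("ascii")
            for target in targets:
                start = region.find(target)
                while start != -1:
                    # flip one unpinned base inside the accidental copy
                    for off in range(len(target)):
                        gpos = lo + start + off
                        if (chrom, gpos) not in editor.registry:
                            cur = editor.base(chrom, gpos)
                            editor.write(
                                chrom, gpos, _BASES[(_BASES.index(cur) + 1) % 4]
                            )
                            break
                    else:
                        raise ConflictError(
                            f"cannot scrub insertion copy near {chrom}:{pos}"
                        )
                    region = editor.seqs[chrom][lo - 1 : hi].decode("ascii")
                    start = region.find(target, start + 1)


def engineer_junction_chemistry(
    ref: ReferenceGenome, events: Sequence[RearrangementEvent]
) -> ReferenceGenome:
    """Return a copy of *ref* edited so each event's junction chemistry is
    realizable and uniquely classifiable.  Raises :class:`ConflictError`
    when two events demand contradictory edits."""
    editor = _Editor(ref)
    for event in events:
        if event.junction is None:
            continue
        _engineer_event(editor, event)
    _scrub_untemplated_insertions(editor, events)
    return editor.finish()


# ---------------------------------------------------------------------------
# derivative genome construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentBlock:
    """A reference interval carried into a derivative contig; '-' strand
    blocks contribute their reverse complement."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class InsertBlock:
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class LiftedInterval:
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class DerivativeContig:
    """A derivative molecule: ordered blocks plus the materialized
    sequence and cumulative offsets for coordinate lifting."""

    name: str
    blocks: list
    seq: str
    _ends: np.ndarray = field(repr=False, default=None)

    @staticmethod
    def build(ref: ReferenceGenome, name: str, blocks: Sequence) -> "DerivativeContig":
        parts = []
        for b in blocks:
            if isinstance(b, InsertBlock):
                parts.append(b.seq)
            elif b.strand == "+":
                parts.append(ref.fetch(b.chrom, b.start, b.end))
            else:
                parts.append(revcomp(ref.fetch(b.chrom, b.start, b.end)))
        seq = "".join(parts)
        ends = np.cumsum([b.length for b in blocks])
        return DerivativeContig(name=name, blocks=list(blocks), seq=seq, _ends=ends)

    def __len__(self) -> int:
        return len(self.seq)

    def lift(self, start: int, end: int) -> Optional[LiftedInterval]:
        """Reference placement of contig interval [start, end] (1-based
        inclusive): the overlapped real block covering the most bases
        wins (ties to the earlier block) and the interval is clipped to
        it.  Returns None when the interval lies wholly in inserted
        sequence."""
        if start < 1 or end > len(self.seq) or start > end:
            raise ValueError(f"interval [{start}, {end}] outside contig {self.name}")
        ends = self._ends
        starts = np.concatenate(([1], ends[:-1] + 1))
        i0 = int(np.searchsorted(ends, start))
        i1 = int(np.searchsorted(ends, end))
        best = None
        best_overlap = -1
        for i in range(i0, i1 + 1):
            block = self.blocks[i]
            if isinstance(block, InsertBlock):
                continue
            overlap = min(end, int(ends[i])) - max(start, int(starts[i])) + 1
            if overlap > best_overlap:
                best_overlap = overlap
                best = i
        if best is None:
            return None
        block = self.blocks[best]
        x = max(start, int(starts[best])) - int(starts[best])
        y = min(end, int(ends[best])) - int(starts[best])
        if block.strand == "+":
            return LiftedInterval(block.chrom, block.start + x, block.start + y, "+")
        return LiftedInterval(block.chrom, block.end - y, block.end - x, "-")


@dataclass
class JunctionTruth:
    """One planted junction: identity, chemistry, and coordinates in both
    reference and derivative space."""

    event_id: str
    rtype: str
    jclass: JunctionClass
    junction_seq: str  # microhomology or insertion sequence ('' for blunt)
    contig: str
    junction_pos: int  # contig coordinate of the last left-flank base
    ins_len: int
    anchor1: JunctionSide
    anchor2: JunctionSide
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    bases_removed: int
    bases_added: int


@dataclass
class DerivativeGenome:
    """Derivative contigs plus the (chemistry-edited) reference and the
    junction truth table."""

    reference: ReferenceGenome
    contigs: dict[str, DerivativeContig]
    truth: list[JunctionTruth]
    rescale_map: Optional[RescaleMap] = None

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs.values())

    def junction_sequence(self, entry: JunctionTruth, flank: int) -> str:
        """Derivative sequence spanning a planted junction with *flank*
        bases of context on each side (the Sanger-amplicon analogue)."""
        contig = self.contigs[entry.contig]
        lo = max(0, entry.junction_pos - flank)
        hi = min(len(contig.seq), entry.junction_pos + entry.ins_len + flank)
        return contig.seq[lo:hi]


def _event_blocks(
    ref: ReferenceGenome, event: RearrangementEvent
) -> tuple[list, int, int]:
    """Block list for one event's derivative contig, plus the removed and
    added base counts relative to the chromosome content it replaces."""
    c1, p1, c2, p2 = event.chrom1, event.pos1, event.chrom2, event.pos2
    l1 = ref.length(c1)
    ins = ""
    if event.junction is not None and event.junction.jclass is JunctionClass.INSERTION:
        ins = event.junction.seq
    middle = [InsertBlock(ins)] if ins else []
    if event.rtype == "LD":
        if p2 >= l1:
            raise ValueError(f"event {event.id}: deletion end must precede chromosome end")
        blocks = [SegmentBlock(c1, 1, p1), *middle, SegmentBlock(c1, p2 + 1, l1)]
        return blocks, p2 - p1, len(ins)
    if event.rtype == "CT":
        l2 = ref.length(c2)
        if p1 > l1 or p2 > l2:
            raise ValueError(f"event {event.id}: breakpoint out of bounds")
        blocks = [SegmentBlock(c1, 1, p1), *middle, SegmentBlock(c2, p2, l2)]
        return blocks, 0, len(ins)
    if event.rtype == "RF":
        blocks = [SegmentBlock(c1, 1, p2), *middle, SegmentBlock(c1, p1, l1)]
        # the retraversed [p1, p2] segment is counted as added sequence
        return blocks, 0, len(ins) + (p2 - p1 + 1)
    if event.rtype == "FF":
        blocks = [SegmentBlock(c1, 1, p1), *middle, SegmentBlock(c1, p1 + 1, p2, "-")]
        return blocks, l1 - p2, len(ins)
    raise ValueError(f"unknown rearrangement type {event.rtype!r}")


def plant_rearrangements(
    ref: ReferenceGenome,
    events: Sequence[RearrangementEvent],
    rescale_map: Optional[RescaleMap] = None,
) -> DerivativeGenome:
    """Plant *events* into *ref* and return the derivative genome with its
    junction truth table.

    Each event is realized on its own derivative contig (``der_<id>``)
    built from the pristine chromosome arms it joins, so events sharing
    a chromosome -- including breakpoints only a few bases apart --
    coexist the way they would on distinct copies of that chromosome.
    Chromosomes untouched by any event pass through unchanged.  The
    reference is first edited (a handful of bases per junction) so the
    requested chemistry is exactly realizable; the edited reference is
    returned as part of the result and must be used downstream.
    """
    for event in events:
        for chrom, pos in event.breakpoints:
            if chrom not in ref:
                raise ValueError(f"event {event.id}: unknown chromosome {chrom!r}")
            if not 1 <= pos <= ref.length(chrom):
                raise ValueError(
                    f"event {event.id}: breakpoint {chrom}:{pos} out of bounds"
                )
    ref = engineer_junction_chemistry(ref, events)

    contigs: dict[str, DerivativeContig] = {}
    truth: list[JunctionTruth] = []
    touched: set[str] = set()
    for event in events:
        touched.update((event.chrom1, event.chrom2))
        blocks, removed, added = _event_blocks(ref, event)
        contig = DerivativeContig.build(ref, f"der_{event.id}", blocks)
        left, right = junction_anchors(event)
        spec = event.junction
        jclass = spec.jclass if spec is not None else JunctionClass.BLUNT
        jseq = spec.seq if spec is not None else ""
        ins_len = len(jseq) if jclass is JunctionClass.INSERTION else 0
        truth.append(
            JunctionTruth(
                event_id=event.id,
                rtype=event.rtype,
                jclass=jclass,
                junction_seq=jseq,
                contig=contig.name,
                junction_pos=blocks[0].length,
                ins_len=ins_len,
                anchor1=left,
                anchor2=right,
                chrom1=event.chrom1,
                pos1=event.pos1,
                chrom2=event.chrom2,
                pos2=event.pos2,
                bases_removed=removed,
                bases_added=added,
            )
        )
        contigs[contig.name] = contig
    for name in ref.names:
        if name not in touched:
            contigs[name] = DerivativeContig.build(
                ref, name, [SegmentBlock(name, 1, ref.length(name))]
            )
    return DerivativeGenome(
        reference=ref, contigs=contigs, truth=truth, rescale_map=rescale_map
    )


# ---------------------------------------------------------------------------
# mate-pair read simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadSimParams:
    """Paired-end simulation parameters (FR-oriented fragments)."""

    read_length: int = 125
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    coverage: float = 30.0
    substitution_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.read_length >= self.insert_mean:
            raise ValueError("read_length must be smaller than insert_mean")
        if self.insert_sd < 0:
            raise ValueError("insert_sd must be >= 0")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.substitution_error_rate < 1:
            raise ValueError("substitution_error_rate must lie in [0, 1)")


def _as_contigs(source: Union[DerivativeGenome, ReferenceGenome]) -> list[DerivativeContig]:
    if isinstance(source, DerivativeGenome):
        return list(source.contigs.values())
    return [
        DerivativeContig.build(source, name, [SegmentBlock(name, 1, source.length(name))])
        for name in source.names
    ]


def _apply_errors(seq: str, n_err: int, rng: np.random.Generator) -> str:
    positions = rng.choice(len(seq), size=n_err, replace=False)
    out = bytearray(seq, "ascii")
    for p in positions:
        cur = chr(out[p])
        alt = _BASES[(_BASES.index(cur) + int(rng.integers(1, 4))) % 4]
        out[p] = ord(alt)
    return out.decode("ascii")


def simulate_read_pairs(
    source: Union[DerivativeGenome, ReferenceGenome],
    params: Optional[ReadSimParams] = None,
) -> list[ReadPair]:
    """Simulate FR paired-end fragments and report coordinates in
    reference space via coordinate lifting.

    Pairs whose fragment straddles a planted junction acquire the
    discordant chromosome/position/strand signature the junction
    implies.  Read 1 is the fragment's forward end, read 2 the reverse
    complement of its tail.  Deterministic for a fixed seed.
    """
    params = params or ReadSimParams()
    contigs = _as_contigs(source)
    if not contigs or all(len(c) == 0 for c in contigs):
        raise ValueError("cannot simulate reads from an empty genome")
    rng = np.random.default_rng(params.seed)
    r = params.read_length
    pairs: list[ReadPair] = []
    for contig in contigs:
        n_len = len(contig)
        if n_len < r:
            continue
        n_pairs = int(round(params.coverage * n_len / (2 * r)))
        if n_pairs == 0:
            continue
        frags = np.rint(
            rng.normal(params.insert_mean, params.insert_sd, size=n_pairs)
        ).astype(int)
        frags = np.clip(frags, r, n_len)
        starts = (rng.random(n_pairs) * (n_len - frags + 1)).astype(int) + 1
        if params.substitution_error_rate > 0:
            n_errs = rng.binomial(r, params.substitution_error_rate, size=(n_pairs, 2))
        else:
            n_errs = None
        seq = contig.seq
        for i in range(n_pairs):
            s = int(starts[i])
            f = int(frags[i])
            seq1 = seq[s - 1 : s - 1 + r]
            seq2 = revcomp(seq[s + f - r - 1 : s + f - 1])
            lift1 = contig.lift(s, s + r - 1)
            lift2 = contig.lift(s + f - r, s + f - 1)
            if lift1 is None or lift2 is None:
                continue  # read swallowed by inserted sequence
            nm1 = nm2 = 0
            if n_errs is not None:
                nm1, nm2 = int(n_errs[i, 0]), int(n_errs[i, 1])
                if nm1:
                    seq1 = _apply_errors(seq1, nm1, rng)
                if nm2:
                    seq2 = _apply_errors(seq2, nm2, rng)
            strand1 = lift1.strand
            strand2 = "-" if lift2.strand == "+" else "+"
            pairs.append(
                ReadPair(
                    id=f"{contig.name}:{i}",
                    end1=ReadEnd(lift1.chrom, lift1.start, strand1, nm1, seq1),
                    end2=ReadEnd(lift2.chrom, lift2.start, strand2, nm2, seq2),
                )
            )
    return pairs


# ---------------------------------------------------------------------------
# SNP-probe track simulation
# ---------------------------------------------------------------------------

PROBE_COLUMNS = ("chrom", "pos", "signal", "baf", "is_het")


@dataclass
class ProbeTrack:
    """Per-probe copy-number signal and B-allele frequency records."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PROBE_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"probe track missing columns: {sorted(missing)}")
        if not np.isfinite(self.df["signal"]).all():
            raise ValueError("probe signals must be finite")
        for chrom, sub in self.df.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing or sub["pos"].duplicated().any():
                raise ValueError(f"probe positions must strictly increase on {chrom}")

    @property
    def n_probes(self) -> int:
        return len(self.df)

    def chromosomes(self) -> list[str]:
        return sorted(self.df["chrom"].unique(), key=chrom_sort_key)

    def subset(self, chrom: str, start: Optional[int] = None, end: Optional[int] = None) -> pd.DataFrame:
        sub = self.df[self.df["chrom"] == chrom]
        if start is not None:
            sub = sub[sub["pos"] >= start]
        if end is not None:
            sub = sub[sub["pos"] <= end]
        return sub


def simulate_probe_track(
    ref: Union[ReferenceGenome, dict[str, int]],
    cna_truth: Sequence[dict],
    probe_spacing: int = 1_000,
    noise_sd: float = 0.3,
    het_fraction: float = 0.5,
    seed: int = 0,
    baf_noise_sd: Optional[float] = None,
) -> ProbeTrack:
    """Simulate an SNP-probe track: copy-number signal 2.0 outside truth
    segments, the segment's planted copy inside, Gaussian noise on top,
    and allele-dosage BAF for heterozygous probes (0.5 at two balanced
    copies; 0/1 under LOH; b/c for integer copy c > 2)."""
    lengths = ref.lengths if isinstance(ref, ReferenceGenome) else dict(ref)
    if probe_spacing <= 0:
        raise ValueError("probe_spacing must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 <= het_fraction <= 1:
        raise ValueError("het_fraction must lie in [0, 1]")
    for seg in cna_truth:
        if seg["chrom"] not in lengths:
            raise ValueError(f"truth segment on unknown chromosome {seg['chrom']!r}")
        if not 1 <= seg["start"] <= seg["end"] <= lengths[seg["chrom"]]:
            raise ValueError(f"truth segment out of bounds: {seg}")
    if baf_noise_sd is None:
        baf_noise_sd = noise_sd / 10.0

    rng = np.random.default_rng(seed)
    frames = []
    for chrom in sorted(lengths, key=chrom_sort_key):
        n = lengths[chrom] // probe_spacing
        if n == 0:
            continue
        pos = probe_spacing * np.arange(1, n + 1)
        copy = np.full(n, 2.0)
        for seg in cna_truth:
            if seg["chrom"] != chrom:
                continue
            inside = (pos >= seg["start"]) & (pos <= seg["end"])
            copy[inside] = float(seg.get("copy", 2.0))
        signal = copy + (rng.normal(0.0, noise_sd, size=n) if noise_sd else 0.0)
        is_het = rng.random(n) < het_fraction
        baf = rng.integers(0, 2, size=n).astype(float)  # homozygous: 0 or 1
        c_int = np.maximum(np.rint(copy).astype(int), 0)
        for i in np.flatnonzero(is_het):
            c = c_int[i]
            if c <= 1:
                baf[i] = float(rng.integers(0, 2))  # one parental allele lost
            elif c == 2:
                baf[i] = 0.5
            else:
                baf[i] = float(rng.integers(1, c)) / c
        if baf_noise_sd:
            baf = np.clip(baf + rng.normal(0.0, baf_noise_sd, size=n), 0.0, 1.0)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "signal": signal, "baf": baf, "is_het": is_het}
            )
        )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(PROBE_COLUMNS))
    )
    return ProbeTrack(df)


# ---------------------------------------------------------------------------
# truth bookkeeping
# ---------------------------------------------------------------------------


def expected_call_coordinates(truth: JunctionTruth) -> tuple[str, int, str, int]:
    """Canonically ordered (chrom1, pos1, chrom2, pos2) a caller should
    report for a planted junction, from its retained-base anchors."""
    a, b = truth.anchor1, truth.anchor2
    (ca, pa), (cb, pb) = (a.chrom, a.pos), (b.chrom, b.pos)
    if (chrom_sort_key(ca), pa) <= (chrom_sort_key(cb), pb):
        return ca, pa, cb, pb
    return cb, pb, ca, pa


def match_calls_to_truth(
    calls: Sequence[RearrangementEvent],
    truth: Sequence[JunctionTruth],
    tolerance: int = 300,
) -> tuple[dict[str, str], list[RearrangementEvent], list[JunctionTruth]]:
    """Greedy matching of calls to planted junctions.

    Returns (call id -> event id, unmatched calls, unrecovered truth).
    A match requires the same rearrangement type and chromosome pair and
    both breakpoints within *tolerance* of the expected coordinates.
    """
    remaining = list(truth)
    matched: dict[str, str] = {}
    unmatched_calls: list[RearrangementEvent] = []
    for call in calls:
        hit = None
        for entry in remaining:
            c1, p1, c2, p2 = expected_call_coordinates(entry)
            if (
                call.rtype == entry.rtype
                and call.chrom1 == c1
                and call.chrom2 == c2
                and abs(call.pos1 - p1) <= tolerance
                and abs(call.pos2 - p2) <= tolerance
            ):
                hit = entry
                break
        if hit is None:
            unmatched_calls.append(call)
        else:
            matched[call.id] = hit.event_id
            remaining.remove(hit)
    return matched, unmatched_calls, remaining
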