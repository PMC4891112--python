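"""Chromothripsis-criteria scoring.

Per chromosome: breakpoint localization against a length-weighted
permutation null, copy-state oscillation between the two predominant
states, and retained heterozygosity from BAF, combined into a
configurable (and deliberately explicit) flagging rule.  The three
criteria are qualitative in origin; every numeric threshold here is an
operationalization knob, not an established constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cna_calling import CNASegment
from .events import RearrangementEvent
from .genome import chrom_sort_key
from .synthetic_data import ProbeTrack


@dataclass(frozen=True)
class LocalizationResult:
    chromosome: str
    breakpoint_count: int
    event_count: int
    localization_p: float


def event_counts_by_chromosome(
    events: Sequence[RearrangementEvent],
) -> dict[str, int]:
    """Number of events with at least one breakpoint on each chromosome."""
    counts: dict[str, int] = {}
    for e in events:
        for chrom in {e.chrom1, e.chrom2}:
            counts[chrom] = counts.get(chrom, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: chrom_sort_key(kv[0])))


def breakpoint_counts_by_chromosome(
    events: Sequence[RearrangementEvent],
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for e in events:
        for chrom, _pos in e.breakpoints:
            counts[chrom] = counts.get(chrom, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: chrom_sort_key(kv[0])))


def localization_test(
    events: Sequence[RearrangementEvent],
    chrom_lengths: dict[str, int],
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict[str, LocalizationResult]:
    """Per-chromosome breakpoint-clustering test.

    The null redraws each event's chromosome assignment with
    probability proportional to chromosome length (intrachromosomal
    events keep both breakpoints together; interchromosomal events draw
    two chromosomes independently), preserving the event structure of
    the observed set.  The one-sided p-value is the add-one-corrected
    fraction of permutations whose breakpoint count on that chromosome
    reaches the observed count, which makes it valid (super-uniform)
    under the null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    names = sorted(chrom_lengths, key=chrom_sort_key)
    if not events:
        return {}
    for e in events:
        for chrom, _ in e.breakpoints:
            if chrom not in chrom_lengths:
                raise ValueError(f"event {e.id}: no length for chromosome {chrom!r}")
    lengths = np.array([chrom_lengths[c] for c in names], dtype=float)
    probs = lengths / lengths.sum()
    n_chrom = len(names)
    idx = {c: i for i, c in enumerate(names)}

    observed = np.zeros(n_chrom, dtype=int)
    for e in events:
        for chrom, _ in e.breakpoints:
            observed[idx[chrom]] += 1

    n_intra = sum(1 for e in events if not e.is_interchromosomal)
    n_inter = len(events) - n_intra
    rng = np.random.default_rng(seed)
    null_counts = np.zeros((n_perm, n_chrom), dtype=np.int32)
    row = np.repeat(np.arange(n_perm), n_intra)
    if n_intra:
        draws = rng.choice(n_chrom, size=(n_perm, n_intra), p=probs)
        np.add.at(null_counts, (row, draws.ravel()), 2)
    if n_inter:
        draws = rng.choice(n_chrom, size=(n_perm, n_inter, 2), p=probs)
        row2 = np.repeat(np.arange(n_perm), n_inter * 2)
        np.add.at(null_counts, (row2, draws.ravel()), 1)

    exceed = (null_counts >= observed[None, :]).sum(axis=0)
    pvals = (1.0 + exceed) / (n_perm + 1.0)

    ev_counts = event_counts_by_chromosome(events)
    return {
        c: LocalizationResult(
            chromosome=c,
            breakpoint_count=int(observed[i]),
            event_count=ev_counts.get(c, 0),
            localization_p=float(pvals[i]),
        )
        for i, c in enumerate(names)
    }


def oscillation_count(calls: Sequence[CNASegment], chromosome: str) -> int:
    """Number of switches between the two most frequent copy states
    along *chromosome*; segments in other states are ignored."""
    segs = sorted(
        (s for s in calls if s.chrom == chromosome), key=lambda s: s.start
    )
    if not segs:
        return 0
    freq: dict[str, int] = {}
    for s in segs:
        freq[s.call] = freq.get(s.call, 0) + 1
    order = {call: i for i, call in enumerate(dict.fromkeys(s.call for s in segs))}
    top = sorted(freq, key=lambda c: (-freq[c], order[c]))[:2]
    states = [s.call for s in segs if s.call in top]
    return sum(1 for a, b in zip(states, states[1:]) if a != b)


def heterozygosity_check(
    track: ProbeTrack,
    segment: CNASegment,
    baf_low: float = 0.15,
    min_het_probes: int = 10,
) -> Optional[bool]:
    """Whether a segment retains heterozygosity.

    Uses the median folded BAF (distance from the nearer homozygous
    extreme) of informative probes: retained when it exceeds
    ``baf_low``.  Returns None (indeterminate) with fewer than
    ``min_het_probes`` informative probes.
    """
    sub = track.subset(segment.chrom, segment.start, segment.end)
    het = sub[sub["is_het"].astype(bool)]
    if len(het) < min_het_probes:
        return None
    folded = 0.5 - np.abs(het["baf"].values - 0.5)
    return bool(np.median(folded) > baf_low)


@dataclass
class AssessConfig:
    flag_min_breakpoints: int = 3
    localization_alpha: float = 0.05
    min_oscillations: int = 2
    baf_low: float = 0.15
    min_het_probes: int = 10
    n_perm: int = 10_000

    def __post_init__(self) -> None:
        if self.flag_min_breakpoints < 1:
            raise ValueError("flag_min_breakpoints must be >= 1")
        if not 0 < self.localization_alpha < 1:
            raise ValueError("localization_alpha must lie in (0, 1)")
        if not 0 <= self.baf_low < 0.5:
            raise ValueError("baf_low must lie in [0, 0.5)")


@dataclass
class ChromosomeAssessment:
    chromosome: str
    breakpoint_count: int
    event_count: int
    localization_p: float
    oscillation_count: int
    het_retained_amp: Optional[bool]
    flagged: bool


def assess(
    events: Sequence[RearrangementEvent],
    cna_calls: Sequence[CNASegment],
    track: Optional[ProbeTrack],
    chrom_lengths: dict[str, int],
    cfg: Optional[AssessConfig] = None,
    seed: int = 0,
) -> list[ChromosomeAssessment]:
    """Score every chromosome against the three chromothripsis criteria.

    A chromosome is flagged when it carries at least
    ``flag_min_breakpoints`` breakpoints, its localization p-value is
    below ``localization_alpha``, and it shows either copy-state
    oscillation (>= ``min_oscillations`` switches) or retained
    heterozygosity inside an amplified segment.
    """
    cfg = cfg or AssessConfig()
    loc = localization_test(events, chrom_lengths, n_perm=cfg.n_perm, seed=seed)
    out = []
    for chrom in sorted(chrom_lengths, key=chrom_sort_key):
        res = loc.get(chrom)
        bp = res.breakpoint_count if res else 0
        ec = res.event_count if res else 0
        p = res.localization_p if res else 1.0
        osc = oscillation_count(cna_calls, chrom)
        het: Optional[bool] = None
        if track is not None:
            amp_flags = [
                heterozygosity_check(track, s, cfg.baf_low, cfg.min_het_probes)
                for s in cna_calls
                if s.chrom == chrom and s.call == "AMP"
            ]
            if any(f is True for f in amp_flags):
                het = True
            elif amp_flags and all(f is False for f in amp_flags):
                het = False
        flagged = (
            bp >= cfg.flag_min_breakpoints
            and p < cfg.localization_alpha
            and (osc >= cfg.min_oscillations or het is True)
        )
        out.append(
            ChromosomeAssessment(
                chromosome=chrom,
                breakpoint_count=bp,
                event_count=ec,
                localization_p=p,
                oscillation_count=osc,
                het_retained_amp=het,
                flagged=flagged,
            )
        )
    return out
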