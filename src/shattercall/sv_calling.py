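"""Rearrangement identification from discordant mate pairs.

The cascade: classify read pairs by orientation/distance, single-linkage
cluster the inconsistent ones, require minimum support, subtract clusters
also present in parental samples, drop pairs that re-align concordantly
(blastn-like ungapped local search with Karlin-Altschul E-values), drop
high-mismatch reads, and require at least one perfect pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .events import RearrangementEvent
from .genome import ReferenceGenome, chrom_sort_key, revcomp


class PairClass(Enum):
    PROPER = "PROPER"
    CT = "CT"
    LD = "LD"
    FF_TYPE = "FF"
    RF_TYPE = "RF"


#: PairClass -> rearrangement-type label used in event output.
PAIRCLASS_TO_RTYPE = {
    PairClass.CT: "CT",
    PairClass.LD: "LD",
    PairClass.FF_TYPE: "FF",
    PairClass.RF_TYPE: "RF",
}


@dataclass(frozen=True)
class ReadEnd:
    """One aligned read: leftmost 1-based position, strand, mismatch count."""

    chrom: str
    pos: int
    strand: str
    nm: int = 0
    seq: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("read position must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.nm < 0:
            raise ValueError("mismatch count must be >= 0")

    @property
    def end(self) -> int:
        return self.pos + max(len(self.seq), 1) - 1


@dataclass(frozen=True)
class ReadPair:
    id: str
    end1: ReadEnd
    end2: ReadEnd

    @property
    def sides(self) -> tuple[ReadEnd, ReadEnd]:
        """Reads ordered canonically by (chromosome, position)."""
        a, b = self.end1, self.end2
        if (chrom_sort_key(a.chrom), a.pos) <= (chrom_sort_key(b.chrom), b.pos):
            return a, b
        return b, a

    @property
    def is_perfect(self) -> bool:
        return self.end1.nm == 0 and self.end2.nm == 0


@dataclass
class CallerConfig:
    """Thresholds of the identification cascade.

    Defaults: 500 bp clustering window, support >= 3, concordant pairs
    within 500 bp, realignment exclusion at E < 1e-7, at most 2
    mismatches per read, and at least one perfect pair per call.
    """

    cluster_window: int = 500
    min_support: int = 3
    proper_max_distance: int = 500
    evalue_threshold: float = 1e-7
    max_mismatches: int = 2
    require_perfect_pair: bool = True
    # blastn-like surrogate scoring (ungapped, +1/-2; Karlin-Altschul
    # lambda/K for those scores)
    realign_word_size: int = 12
    realign_match: int = 1
    realign_mismatch: int = -2
    realign_lambda: float = 1.33
    realign_k: float = 0.621
    realign_xdrop: int = 20

    def __post_init__(self) -> None:
        if self.cluster_window <= 0 or self.proper_max_distance <= 0:
            raise ValueError("windows must be positive")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if not 0 < self.evalue_threshold:
            raise ValueError("evalue_threshold must be positive")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


def classify_read_pair(pair: ReadPair, cfg: CallerConfig) -> PairClass:
    """Orientation/distance class of one pair.

    PROPER = same chromosome, forward/reverse orientation, within the
    concordant distance.  Different chromosomes = CT.  Same-chromosome
    FR beyond the distance = LD; FF and RR = FF_TYPE; RF = RF_TYPE.
    """
    left, right = pair.sides
    if left.chrom != right.chrom:
        return PairClass.CT
    distance = right.pos - left.pos
    if left.strand == "+" and right.strand == "-":
        if distance <= cfg.proper_max_distance:
            return PairClass.PROPER
        return PairClass.LD
    if left.strand == "-" and right.strand == "+":
        return PairClass.RF_TYPE
    return PairClass.FF_TYPE  # ++ or -- (RR folded into FF)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _consensus(reads: Sequence[ReadEnd]) -> int:
    """Innermost aligned base toward the junction for one footprint.

    Forward reads approach the junction from the left (innermost = max
    aligned end); reverse reads from the right (innermost = min start).
    With mixed strands the majority wins; ties take the smaller
    coordinate.
    """
    fwd = [r for r in reads if r.strand == "+"]
    rev = [r for r in reads if r.strand == "-"]
    cand = []
    if fwd:
        cand.append((len(fwd), max(r.end for r in fwd)))
    if rev:
        cand.append((len(rev), min(r.pos for r in rev)))
    cand.sort(key=lambda c: (-c[0], c[1]))
    return cand[0][1]


@dataclass
class Cluster:
    """Inconsistent read pairs supporting one candidate rearrangement."""

    pairs: list[ReadPair]
    pclass: PairClass
    chrom1: str
    chrom2: str
    break1: int
    break2: int

    @property
    def support(self) -> int:
        return len(self.pairs)

    @property
    def has_perfect_pair(self) -> bool:
        return any(p.is_perfect for p in self.pairs)

    @staticmethod
    def from_pairs(pairs: Sequence[ReadPair], pclass: PairClass) -> "Cluster":
        if not pairs:
            raise ValueError("cluster requires at least one pair")
        side1 = [p.sides[0] for p in pairs]
        side2 = [p.sides[1] for p in pairs]
        return Cluster(
            pairs=list(pairs),
            pclass=pclass,
            chrom1=side1[0].chrom,
            chrom2=side2[0].chrom,
            break1=_consensus(side1),
            break2=_consensus(side2),
        )


def cluster_inconsistent_pairs(
    pairs: Sequence[ReadPair], cfg: CallerConfig
) -> list[Cluster]:
    """Single-linkage clustering of non-proper pairs.

    Two pairs are linked when they share orientation class and
    chromosome assignment and both footprints (canonical side 1 and
    side 2 read starts) lie within ``cfg.cluster_window``.
    """
    groups: dict[tuple, list[ReadPair]] = {}
    for pair in pairs:
        pclass = classify_read_pair(pair, cfg)
        if pclass is PairClass.PROPER:
            continue
        left, right = pair.sides
        groups.setdefault((pclass, left.chrom, right.chrom), []).append(pair)

    clusters: list[Cluster] = []
    w = cfg.cluster_window
    for (pclass, _c1, _c2), members in groups.items():
        members.sort(key=lambda p: (p.sides[0].pos, p.sides[1].pos, p.id))
        n = len(members)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            si1, si2 = members[i].sides
            for j in range(i + 1, n):
                sj1, sj2 = members[j].sides
                if sj1.pos - si1.pos > w:
                    break  # sorted by side1 start: no further links from i
                if abs(sj2.pos - si2.pos) <= w:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        comps: dict[int, list[ReadPair]] = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(members[i])
        for comp in comps.values():
            clusters.append(Cluster.from_pairs(comp, pclass))

    clusters.sort(
        key=lambda c: (chrom_sort_key(c.chrom1), c.break1, chrom_sort_key(c.chrom2), c.break2)
    )
    return clusters


def filter_by_support(clusters: Sequence[Cluster], cfg: CallerConfig) -> list[Cluster]:
    """Keep clusters supported by at least ``cfg.min_support`` pairs."""
    return [c for c in clusters if c.support >= cfg.min_support]


def subtract_parental(
    sample: Sequence[Cluster],
    parental: Sequence[Sequence[Cluster]],
    match_window: int = 500,
) -> list[Cluster]:
    """Remove sample clusters that match any parental cluster.

    A match requires the same orientation class, the same chromosome
    pair, and both consensus breakpoints within ``match_window``.
    """
    kept = []
    for c in sample:
        matched = False
        for pset in parental:
            for p in pset:
                if (
                    p.pclass is c.pclass
                    and p.chrom1 == c.chrom1
                    and p.chrom2 == c.chrom2
                    and abs(p.break1 - c.break1) <= match_window
                    and abs(p.break2 - c.break2) <= match_window
                ):
                    matched = True
                    break
            if matched:
                break
        if not matched:
            kept.append(c)
    return kept


# ---------------------------------------------------------------------------
# realignment filter (blastn-like surrogate)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentHit:
    chrom: str
    start: int  # 1-based leftmost aligned reference base
    end: int
    strand: str
    score: int
    evalue: float


class RealignmentIndex:
    """Exact-word index over a reference with ungapped seed extension.

    A self-contained surrogate for a blastn search: non-overlapping
    word seeds, X-drop ungapped extension at +1/-2, and ungapped
    Karlin-Altschul E-values (lambda=1.33, K=0.621 by default).
    """

    def __init__(self, ref: ReferenceGenome, cfg: Optional[CallerConfig] = None):
        cfg = cfg or CallerConfig()
        self.cfg = cfg
        self.ref = ref
        self.total_length = ref.total_length
        w = cfg.realign_word_size
        index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in ref.chromosomes.items():
            for i in range(len(seq) - w + 1):
                index.setdefault(seq[i : i + w], []).append((chrom, i))
        self._index = index

    def evalue(self, score: int, query_length: int) -> float:
        cfg = self.cfg
        return (
            cfg.realign_k
            * query_length
            * self.total_length
            * math.exp(-cfg.realign_lambda * score)
        )

    def _extend(self, query: str, qpos: int, target: str, tpos: int) -> tuple[int, int, int]:
        """Ungapped X-drop extension of a word seed; returns
        (score, leftmost target offset, rightmost target offset)."""
        cfg = self.cfg
        w = cfg.realign_word_size
        score = w * cfg.realign_match
        # rightward
        best, best_ext = score, 0
        cur, ext = score, 0
        qi, ti = qpos + w, tpos + w
        while qi + ext < len(query) and ti + ext < len(target):
            cur += (
                cfg.realign_match
                if query[qi + ext] == target[ti + ext]
                else cfg.realign_mismatch
            )
            ext += 1
            if cur > best:
                best, best_ext = cur, ext
            if cur < best - cfg.realign_xdrop:
                break
        right = tpos + w + best_ext - 1
        score = best
        # leftward
        best, best_ext = score, 0
        cur, ext = score, 0
        while qpos - 1 - ext >= 0 and tpos - 1 - ext >= 0:
            cur += (
                cfg.realign_match
                if query[qpos - 1 - ext] == target[tpos - 1 - ext]
                else cfg.realign_mismatch
            )
            ext += 1
            if cur > best:
                best, best_ext = cur, ext
            if cur < best - cfg.realign_xdrop:
                break
        left = tpos - best_ext
        return best, left, right

    def search(self, seq: str, max_evalue: Optional[float] = None) -> list[AlignmentHit]:
        """All local alignment hits of *seq* (both strands) with
        E-value below ``max_evalue`` (default: config threshold)."""
        if max_evalue is None:
            max_evalue = self.cfg.evalue_threshold
        w = self.cfg.realign_word_size
        hits: dict[tuple, AlignmentHit] = {}
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            if len(s) < w:
                continue
            seed_starts = list(range(0, len(s) - w + 1, w))
            if seed_starts[-1] != len(s) - w:
                seed_starts.append(len(s) - w)
            for i in seed_starts:
                for chrom, gpos in self._index.get(s[i : i + w], ()):
                    diag = gpos - i
                    key = (chrom, strand, diag)
                    if key in hits:
                        continue
                    target = self.ref.chromosomes[chrom]
                    score, left, right = self._extend(s, i, target, gpos)
                    ev = self.evalue(score, len(s))
                    hits[key] = AlignmentHit(chrom, left + 1, right + 1, strand, score, ev)
        return [h for h in hits.values() if h.evalue < max_evalue]


def _has_concordant_placement(
    hits1: Sequence[AlignmentHit], hits2: Sequence[AlignmentHit], cfg: CallerConfig
) -> bool:
    for h1 in hits1:
        for h2 in hits2:
            if h1.chrom != h2.chrom:
                continue
            if abs(h1.start - h2.start) > cfg.proper_max_distance:
                continue
            left, right = (h1, h2) if h1.start <= h2.start else (h2, h1)
            if left.strand == "+" and right.strand == "-":
                return True
    return False


def realignment_filter(
    cluster: Cluster,
    index: RealignmentIndex | ReferenceGenome,
    cfg: CallerConfig,
) -> tuple[Optional[Cluster], dict[str, bool]]:
    """Drop supporting pairs that re-align concordantly to the reference.

    A pair is excluded when both reads have local alignments with
    E-value below threshold that place them in forward/reverse
    orientation within the concordant distance.  Returns the rebuilt
    cluster (or None if empty) and per-pair keep verdicts.
    """
    if isinstance(index, ReferenceGenome):
        index = RealignmentIndex(index, cfg)
    verdicts: dict[str, bool] = {}
    kept: list[ReadPair] = []
    for pair in cluster.pairs:
        if not pair.end1.seq or not pair.end2.seq:
            raise ValueError(f"pair {pair.id}: read sequences required for realignment")
        hits1 = index.search(pair.end1.seq)
        hits2 = index.search(pair.end2.seq)
        drop = _has_concordant_placement(hits1, hits2, cfg)
        verdicts[pair.id] = not drop
        if not drop:
            kept.append(pair)
    if not kept:
        return None, verdicts
    return Cluster.from_pairs(kept, cluster.pclass), verdicts


def mismatch_and_perfect_filter(
    cluster: Cluster, cfg: CallerConfig
) -> Optional[Cluster]:
    """Drop pairs with a read above the mismatch cap; then require
    minimum support and (optionally) at least one perfect pair."""
    kept = [
        p
        for p in cluster.pairs
        if p.end1.nm <= cfg.max_mismatches and p.end2.nm <= cfg.max_mismatches
    ]
    if len(kept) < cfg.min_support:
        return None
    rebuilt = Cluster.from_pairs(kept, cluster.pclass)
    if cfg.require_perfect_pair and not rebuilt.has_perfect_pair:
        return None
    return rebuilt


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------


@dataclass
class CallResult:
    events: list[RearrangementEvent]
    audit: list[dict] = field(default_factory=list)


def call_rearrangements(
    pairs: Sequence[ReadPair],
    parental_pair_sets: Sequence[Sequence[ReadPair]],
    ref: ReferenceGenome,
    cfg: Optional[CallerConfig] = None,
) -> CallResult:
    """Run the full cascade and return typed breakpoint calls plus a
    per-candidate audit of every filter stage.

    Parental samples are clustered without a support threshold so that
    even weakly covered shared rearrangements subtract.
    """
    cfg = cfg or CallerConfig()
    clusters = cluster_inconsistent_pairs(pairs, cfg)
    candidates = filter_by_support(clusters, cfg)
    parental_clusters = [
        cluster_inconsistent_pairs(pset, cfg) for pset in parental_pair_sets
    ]

    audit: list[dict] = []
    for c in clusters:
        audit.append(
            {
                "rtype": PAIRCLASS_TO_RTYPE[c.pclass],
                "chrom1": c.chrom1,
                "pos1": c.break1,
                "chrom2": c.chrom2,
                "pos2": c.break2,
                "support_initial": c.support,
                "pass_support": c.support >= cfg.min_support,
                "pass_parental": None,
                "support_realigned": None,
                "support_mismatch": None,
                "perfect_pair": None,
                "final": False,
            }
        )
    by_id = {id(c): row for c, row in zip(clusters, audit)}

    after_parental = subtract_parental(candidates, parental_clusters, cfg.cluster_window)
    surviving = {id(c) for c in after_parental}
    for c in candidates:
        by_id[id(c)]["pass_parental"] = id(c) in surviving

    index = RealignmentIndex(ref, cfg)
    final_clusters: list[Cluster] = []
    for c in after_parental:
        row = by_id[id(c)]
        realigned, _verdicts = realignment_filter(c, index, cfg)
        row["support_realigned"] = realigned.support if realigned else 0
        if realigned is None:
            continue
        cleaned = mismatch_and_perfect_filter(realigned, cfg)
        if cleaned is None:
            row["support_mismatch"] = sum(
                1
                for p in realigned.pairs
                if p.end1.nm <= cfg.max_mismatches and p.end2.nm <= cfg.max_mismatches
            )
            row["perfect_pair"] = realigned.has_perfect_pair
            continue
        row["support_mismatch"] = cleaned.support
        row["perfect_pair"] = cleaned.has_perfect_pair
        if cleaned.support >= cfg.min_support:
            row["final"] = True
            final_clusters.append(cleaned)

    final_clusters.sort(
        key=lambda c: (chrom_sort_key(c.chrom1), c.break1, chrom_sort_key(c.chrom2), c.break2)
    )
    events = []
    for i, c in enumerate(final_clusters):
        p1, p2 = c.break1, c.break2
        if c.chrom1 == c.chrom2:
            # same-chromosome events store pos1 < pos2; consensus noise on
            # near-adjacent footprints may invert the order
            p1, p2 = sorted((p1, p2))
            if p1 == p2:
                p2 = p1 + 1
        events.append(
            RearrangementEvent(
                id=f"SV{i + 1:03d}",
                chrom1=c.chrom1,
                pos1=p1,
                chrom2=c.chrom2,
                pos2=p2,
                rtype=PAIRCLASS_TO_RTYPE[c.pclass],
            )
        )
    return CallResult(events=events, audit=audit)
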