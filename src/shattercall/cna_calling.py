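"""Copy-number calling from SNP-probe tracks.

Baseline subtraction (so shared alterations cancel), recursive binary
segmentation with a Welch t-test split criterion, and Amp/Del
thresholding.  Defaults mirror the published analysis: minimum 30
probes per region, split p-value 0.001, signal-to-noise 0.3, deletion
at <= 1.8 copies, amplification at >= 2.6 copies.

The segmentation is a deterministic, self-contained surrogate for the
proprietary algorithm used in the source analysis; its three published
parameters map onto the split-acceptance rule documented in
:func:`segment_probe_track`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import chrom_sort_key
from .synthetic_data import ProbeTrack


@dataclass(frozen=True)
class CNASegment:
    """A copy-number segment; ``length`` follows the end - start
    convention of the bundled demo table."""

    chrom: str
    start: int
    end: int
    mean_copy: float
    call: str = "NEUTRAL"
    n_probes: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start > end on {self.chrom}")
        if self.call not in ("AMP", "DEL", "NEUTRAL"):
            raise ValueError(f"invalid call {self.call!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SegmentationConfig:
    min_probes: int = 30
    p_threshold: float = 0.001
    snr: float = 0.3
    del_threshold: float = 1.8
    amp_threshold: float = 2.6

    def __post_init__(self) -> None:
        if self.min_probes < 2:
            raise ValueError("min_probes must be >= 2")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if not self.del_threshold < 2 < self.amp_threshold:
            raise ValueError("thresholds must bracket the diploid level 2")


def subtract_baseline(sample: ProbeTrack, baseline: ProbeTrack) -> ProbeTrack:
    """Differential track re-centred at 2 copies: sample - baseline + 2.

    Alterations shared with the baseline cancel, so only de novo changes
    deviate from 2.0.  BAF and heterozygosity flags are carried over
    from the sample.  Probe grids must be identical.
    """
    a, b = sample.df, baseline.df
    if len(a) != len(b) or not (
        (a["chrom"].values == b["chrom"].values).all()
        and (a["pos"].values == b["pos"].values).all()
    ):
        raise ValueError("sample and baseline probe grids differ")
    out = a.copy()
    out["signal"] = a["signal"].values - b["signal"].values + 2.0
    return ProbeTrack(out)


def robust_noise_sd(track: ProbeTrack) -> float:
    """Noise SD estimated from the median absolute deviation of
    first-differences, scaled by 1.4826/sqrt(2) — robust to the small
    number of true copy-number jumps."""
    diffs = []
    for chrom, sub in track.df.groupby("chrom", sort=False):
        d = np.diff(sub["signal"].values)
        if d.size:
            diffs.append(d)
    if not diffs:
        return 0.0
    d = np.concatenate(diffs)
    return float(np.median(np.abs(d - np.median(d))) * 1.4826 / np.sqrt(2.0))


def _welch_best_split(x: np.ndarray, min_probes: int) -> Optional[tuple[int, float, float]]:
    """Best split point of *x* by Welch's t-statistic.

    Returns (split index, two-sided p-value, |mean difference|) for the
    split maximizing |t| over all cuts leaving at least ``min_probes``
    on each side, or None when no admissible cut exists.
    """
    n = x.size
    if n < 2 * min_probes:
        return None
    cs = np.cumsum(x)
    css = np.cumsum(x * x)
    k = np.arange(min_probes, n - min_probes + 1)  # left side sizes
    n1 = k.astype(float)
    n2 = (n - k).astype(float)
    s1 = cs[k - 1]
    s2 = cs[-1] - s1
    m1 = s1 / n1
    m2 = s2 / n2
    q1 = css[k - 1] - n1 * m1 * m1
    q2 = (css[-1] - css[k - 1]) - n2 * m2 * m2
    v1 = np.maximum(q1, 0.0) / np.maximum(n1 - 1, 1.0)
    v2 = np.maximum(q2, 0.0) / np.maximum(n2 - 1, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = v1 / n1 + v2 / n2
        t = np.where(se2 > 0, np.abs(m1 - m2) / np.sqrt(se2), np.inf)
        t = np.where(np.abs(m1 - m2) > 0, t, 0.0)
        df = np.where(
            se2 > 0,
            se2**2
            / (
                np.where(n1 > 1, (v1 / n1) ** 2 / (n1 - 1), np.inf)
                + np.where(n2 > 1, (v2 / n2) ** 2 / (n2 - 1), np.inf)
            ),
            1.0,
        )
    best = int(np.argmax(t))
    t_best = float(t[best])
    if not np.isfinite(t_best):
        p = 0.0
    else:
        p = float(2.0 * stats.t.sf(t_best, max(float(df[best]), 1.0)))
    return int(k[best]), p, float(abs(m1[best] - m2[best]))


def _sse_best_split(x: np.ndarray) -> int:
    """Split index minimizing the two-segment sum of squared errors
    (least-squares changepoint localization; stable at segment edges)."""
    n = x.size
    cs = np.cumsum(x)
    k = np.arange(1, n)
    n1 = k.astype(float)
    n2 = (n - k).astype(float)
    s1 = cs[k - 1]
    s2 = cs[-1] - s1
    # minimizing SSE == maximizing explained between-group sum of squares
    between = s1 * s1 / n1 + s2 * s2 / n2
    return int(k[np.argmax(between)])


def _refine_boundaries(x: np.ndarray, bounds: list[int], max_passes: int = 10) -> list[int]:
    """Relocate each internal boundary to the least-squares optimum
    within its flanking segment pair; iterate until stable."""
    bounds = sorted(bounds)
    for _ in range(max_passes):
        changed = False
        edges = [0] + bounds + [x.size]
        for i in range(1, len(edges) - 1):
            lo, hi = edges[i - 1], edges[i + 1]
            k = lo + _sse_best_split(x[lo:hi])
            if k != edges[i] and lo < k < hi:
                edges[i] = k
                changed = True
        bounds = sorted(set(edges[1:-1]))
        if not changed:
            break
    return bounds


def _welch_pair(x1: np.ndarray, x2: np.ndarray) -> tuple[float, float]:
    """(two-sided p, |mean difference|) of Welch's t-test between two
    neighbouring segments; degenerate inputs give p = 1."""
    n1, n2 = x1.size, x2.size
    gap = float(abs(x1.mean() - x2.mean()))
    if n1 < 2 or n2 < 2:
        return 1.0, gap
    v1 = float(x1.var(ddof=1))
    v2 = float(x2.var(ddof=1))
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        return (0.0 if gap > 0 else 1.0), gap
    t = gap / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / max(n1 - 1, 1) + (v2 / n2) ** 2 / max(n2 - 1, 1))
    return float(2.0 * stats.t.sf(t, max(df, 1.0))), gap


def segment_probe_track(
    track: ProbeTrack, cfg: Optional[SegmentationConfig] = None
) -> list[CNASegment]:
    """Recursive binary segmentation of the differential signal.

    Each chromosome is split recursively at the cut maximizing Welch's
    t-statistic; a split is accepted when its p-value is below
    ``p_threshold``, both sides hold at least ``min_probes`` probes, and
    the mean difference is at least ``snr`` times the track's robust
    noise SD.  A least-squares refinement pass then relocates each
    boundary to its optimum (recursive splitting alone can misplace a
    boundary by many probes when a flanking region was split late), and
    boundaries whose adjacent segments no longer differ significantly
    are dissolved; refine/prune alternates until stable.
    Chromosomes with too few probes come back as a single segment.
    Segment bounds are the first/last probe positions, so the
    per-chromosome segments tile the probe extent.
    """
    cfg = cfg or SegmentationConfig()
    noise = robust_noise_sd(track)
    min_gap = cfg.snr * noise
    segments: list[CNASegment] = []

    def split(x: np.ndarray, offset: int, bounds: list[int]) -> None:
        res = _welch_best_split(x, cfg.min_probes)
        if res is None:
            return
        k, p, gap = res
        if p < cfg.p_threshold and gap >= min_gap:
            bounds.append(offset + k)
            split(x[:k], offset, bounds)
            split(x[k:], offset + k, bounds)

    for chrom in track.chromosomes():
        sub = track.subset(chrom)
        x = sub["signal"].values.astype(float)
        pos = sub["pos"].values
        bounds: list[int] = []
        split(x, 0, bounds)
        while True:
            bounds = _refine_boundaries(x, bounds)
            edges = [0] + bounds + [x.size]
            weakest = None  # (p, boundary) of the least significant cut
            for lo, b, hi in zip(edges[:-2], edges[1:-1], edges[2:]):
                p, gap = _welch_pair(x[lo:b], x[b:hi])
                if p >= cfg.p_threshold or gap < min_gap:
                    if weakest is None or p > weakest[0]:
                        weakest = (p, b)
            if weakest is None:
                break
            bounds.remove(weakest[1])
        edges = [0] + bounds + [x.size]
        for lo, hi in zip(edges[:-1], edges[1:]):
            segments.append(
                CNASegment(
                    chrom=chrom,
                    start=int(pos[lo]),
                    end=int(pos[hi - 1]),
                    mean_copy=float(np.mean(x[lo:hi])),
                    n_probes=int(hi - lo),
                )
            )
    segments.sort(key=lambda s: (chrom_sort_key(s.chrom), s.start))
    return segments


def call_cnas(
    segments: Sequence[CNASegment], cfg: Optional[SegmentationConfig] = None
) -> list[CNASegment]:
    """Threshold segment means into AMP/DEL/NEUTRAL calls and merge
    adjacent same-call segments (probe-weighted mean).

    A non-neutral call additionally requires at least ``min_probes``
    probes; smaller shifted segments are reported neutral (and merge
    into their neighbours).  Segments with an unknown probe count
    (n_probes == 0, e.g. read from a minimal SEG file) are exempt.
    """
    cfg = cfg or SegmentationConfig()

    def label(s: CNASegment) -> str:
        if 0 < s.n_probes < cfg.min_probes:
            return "NEUTRAL"
        if s.mean_copy <= cfg.del_threshold:
            return "DEL"
        if s.mean_copy >= cfg.amp_threshold:
            return "AMP"
        return "NEUTRAL"

    labelled = [replace(s, call=label(s)) for s in segments]
    labelled.sort(key=lambda s: (chrom_sort_key(s.chrom), s.start))
    merged: list[CNASegment] = []
    for seg in labelled:
        if merged and merged[-1].chrom == seg.chrom and merged[-1].call == seg.call:
            prev = merged[-1]
            total = prev.n_probes + seg.n_probes
            mean = (
                (prev.mean_copy * prev.n_probes + seg.mean_copy * seg.n_probes) / total
                if total
                else (prev.mean_copy + seg.mean_copy) / 2
            )
            merged[-1] = CNASegment(
                chrom=prev.chrom,
                start=prev.start,
                end=seg.end,
                mean_copy=mean,
                call=prev.call,
                n_probes=total,
            )
        else:
            merged.append(seg)
    return merged


def summarize_cna_burden(
    per_subline_calls: dict[str, Sequence[CNASegment]],
) -> tuple[int, dict[str, int]]:
    """(rounded percentage of sublines with >= 1 non-neutral call,
    per-chromosome count of non-neutral calls across sublines)."""
    n = len(per_subline_calls)
    with_cna = 0
    per_chrom: dict[str, int] = {}
    for calls in per_subline_calls.values():
        hits = [c for c in calls if c.call != "NEUTRAL"]
        if hits:
            with_cna += 1
        for c in hits:
            per_chrom[c.chrom] = per_chrom.get(c.chrom, 0) + 1
    pct = int(round(100.0 * with_cna / n)) if n else 0
    per_chrom = dict(sorted(per_chrom.items(), key=lambda kv: chrom_sort_key(kv[0])))
    return pct, per_chrom


def cna_table(calls: Sequence[CNASegment]) -> pd.DataFrame:
    """Non-neutral calls as a published-style summary table
    (Chromosome / Call / Start / End / Length)."""
    rows = [
        {
            "Chromosome": c.chrom,
            "Call": "Amp" if c.call == "AMP" else "Del",
            "Start": c.start,
            "End": c.end,
            "Length": c.length,
        }
        for c in calls
        if c.call != "NEUTRAL"
    ]
    return pd.DataFrame(rows, columns=["Chromosome", "Call", "Start", "End", "Length"])
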