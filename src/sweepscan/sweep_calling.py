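"""Outlier windows, interval consolidation, context intersection, gene overlap.

The empirical tail rule selects, for tail="high", all windows whose value is
>= the k-th largest defined value with k = max(1, ceil(q * N)); ties at the
boundary are all included (deterministic, no random dropping).  tail="low"
is symmetric.  Merging follows interval-consolidation defaults: book-ended
intervals (next start == end + 1 in 1-based inclusive coordinates) merge at
max_gap = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sweepscan.data_io import GeneModel, internal_to_bed
from sweepscan.pooled_het import ScoreTrack

logger = logging.getLogger(__name__)


@dataclass
class OutlierRule:
    method: str
    tail: str                      # "low" | "high"
    q: float = 0.001
    threshold: float | None = None  # fixed override; bypasses the quantile rule

    def __post_init__(self):
        if self.tail not in ("low", "high"):
            raise ValueError("tail must be 'low' or 'high'")
        if not (0 < self.q < 0.5):
            raise ValueError("q must be in (0, 0.5)")


@dataclass
class OutlierWindow:
    chrom: str
    start: int
    end: int
    value: float


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    method: str
    tail: str
    peak_score: float
    n_windows: int
    context: str | tuple[str, str]
    support: list = field(default_factory=list)   # (method, context) pairs

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def call_outlier_windows(track: ScoreTrack, rule: OutlierRule) -> list[OutlierWindow]:
    """Windows in the extreme tail of the track's empirical distribution."""
    defined = track.defined
    vals = track.values
    n_defined = int(defined.sum())
    if n_defined == 0:
        raise ValueError(f"track {track.statistic}/{track.context}: no defined windows")
    if rule.threshold is None and n_defined < 1.0 / rule.q:
        logger.warning("only %d defined windows for q=%g; tail poorly resolved",
                       n_defined, rule.q)
    if rule.threshold is not None:
        thr = rule.threshold
    else:
        k = max(1, math.ceil(rule.q * n_defined))
        dv = np.sort(vals[defined])
        thr = dv[-k] if rule.tail == "high" else dv[k - 1]
    if rule.tail == "high":
        sel = defined & (vals >= thr)
    else:
        sel = defined & (vals <= thr)
    out = []
    for w in np.flatnonzero(sel):
        out.append(OutlierWindow(chrom=track.grid.chrom,
                                 start=int(track.grid.starts[w]),
                                 end=int(track.grid.ends[w]),
                                 value=float(vals[w])))
    return out


def merge_regions(windows: list[OutlierWindow], max_gap: int = 0,
                  method: str = "NA", tail: str = "high",
                  context: str | tuple[str, str] = "NA") -> list[CandidateRegion]:
    """Consolidate outlier windows into disjoint regions.

    Intervals merge when the gap between them is <= max_gap; gap 0 merges
    overlapping and book-ended intervals.
    """
    if not windows:
        return []
    windows = sorted(windows, key=lambda w: (w.chrom, w.start, w.end))
    better = max if tail == "high" else min
    regions: list[CandidateRegion] = []
    cur = None
    for w in windows:
        if cur is not None and w.chrom == cur.chrom and \
                w.start - cur.end - 1 <= max_gap:
            cur.end = max(cur.end, w.end)
            cur.peak_score = better(cur.peak_score, w.value)
            cur.n_windows += 1
        else:
            cur = CandidateRegion(chrom=w.chrom, start=w.start, end=w.end,
                                  method=method, tail=tail, peak_score=w.value,
                                  n_windows=1, context=context,
                                  support=[(method, context)])
            regions.append(cur)
    return regions


def intersect_contexts(regionsets: list[list[CandidateRegion]], mode: str = "intersection",
                       k: int | None = None) -> list[CandidateRegion]:
    """Interval algebra across region sets with per-base support counting.

    mode "union" keeps bases covered by >= 1 set, "intersection" by all sets,
    "k_of_n" by >= k sets.  Output sub-regions carry the supporting
    (method, context) pairs; adjacent sub-regions with identical support merge.
    """
    if not regionsets:
        raise ValueError("no region sets supplied")
    n = len(regionsets)
    if mode == "union":
        k_req = 1
    elif mode == "intersection":
        k_req = n
    elif mode == "k_of_n":
        if k is None or not (1 <= k <= n):
            raise ValueError("k_of_n requires 1 <= k <= n")
        k_req = k
    else:
        raise ValueError(f"unknown mode {mode!r}")

    chroms = sorted({r.chrom for rs in regionsets for r in rs})
    out: list[CandidateRegion] = []
    for chrom in chroms:
        # boundary sweep over elementary segments
        bounds = set()
        per_set: list[list[CandidateRegion]] = []
        for rs in regionsets:
            rows = [r for r in rs if r.chrom == chrom]
            per_set.append(rows)
            for r in rows:
                bounds.add(r.start)
                bounds.add(r.end + 1)
        bounds = sorted(bounds)
        prev = None
        for lo, hi_excl in zip(bounds[:-1], bounds[1:]):
            hi = hi_excl - 1
            supporters = []
            for rows in per_set:
                for r in rows:
                    if r.start <= lo and hi <= r.end:
                        supporters.extend(r.support or [(r.method, r.context)])
                        break
            n_sets = sum(1 for rows in per_set
                         if any(r.start <= lo and hi <= r.end for r in rows))
            if n_sets < k_req:
                prev = None
                continue
            key = tuple(sorted(map(repr, supporters)))
            if prev is not None and prev[1] == key and prev[0].end + 1 == lo:
                prev[0].end = hi
            else:
                region = CandidateRegion(chrom=chrom, start=lo, end=hi,
                                         method="combined", tail="NA",
                                         peak_score=math.nan, n_windows=0,
                                         context="combined",
                                         support=list(supporters))
                out.append(region)
                prev = (region, key)
    return out


def annotate_genes(regions: list[CandidateRegion], genes: list[GeneModel]
                   ) -> pd.DataFrame:
    """Region x overlapping-gene table; regions with zero genes appear too.

    Overlap means sharing >= 1 bp in 1-based inclusive coordinates.
    """
    region_chroms = {r.chrom for r in regions}
    gene_chroms = {g.chrom for g in genes}
    unmatched = region_chroms - gene_chroms
    if regions and genes and unmatched:
        logger.warning("%d region chromosome(s) absent from gene annotation: %s",
                       len(unmatched), sorted(unmatched))
    rows = []
    for r in regions:
        hits = [g for g in genes
                if g.chrom == r.chrom and g.start <= r.end and g.end >= r.start]
        rows.append({
            "chrom": r.chrom, "start": r.start, "end": r.end,
            "method": r.method, "context": str(r.context),
            "peak_score": r.peak_score,
            "n_genes": len(hits),
            "genes": ",".join(g.gene_name for g in hits) if hits else ".",
        })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "method",
                                       "context", "peak_score", "n_genes", "genes"])


def regions_to_bed(regions: list[CandidateRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        b0, b1 = internal_to_bed(r.start, r.end)
        rows.append({"chrom": r.chrom, "start": b0, "end": b1,
                     "name": f"{r.method}:{r.context}", "score": r.peak_score})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])


def regions_to_table(regions: list[CandidateRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append({"chrom": r.chrom, "start": r.start, "end": r.end,
                     "method": r.method, "tail": r.tail,
                     "peak_score": r.peak_score, "n_windows": r.n_windows,
                     "context": str(r.context)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "method", "tail",
                                       "peak_score", "n_windows", "context"])
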