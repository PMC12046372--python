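"""Sliding-window grid shared by all four statistics.

Windows are anchored at position 1 and are 1-based inclusive; only windows
fully contained in the chromosome are emitted unless a trailing partial
window is explicitly requested.  A SNP belongs to every window whose span
contains it (two windows for the default 20 kb / 10 kb geometry away from
the edges).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from sweepscan.data_io import HaplotypeSet, internal_to_bed

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 20_000
DEFAULT_STEP = 10_000
DEFAULT_MIN_SNPS = 20


@dataclass
class WindowGrid:
    chrom: str
    window_size: int
    step: int
    starts: np.ndarray              # int64, 1-based
    ends: np.ndarray                # inclusive
    min_snps: int = DEFAULT_MIN_SNPS
    snp_index: list[np.ndarray] | None = None   # per-window variant column indices
    n_snps: np.ndarray | None = None
    scored: np.ndarray | None = None            # bool per window

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    @property
    def n_scored(self) -> int:
        if self.scored is None:
            raise ValueError("SNPs not assigned yet")
        return int(self.scored.sum())

    def to_bed(self) -> list[tuple[str, int, int]]:
        out = []
        for s, e in zip(self.starts, self.ends):
            b0, b1 = internal_to_bed(int(s), int(e))
            out.append((self.chrom, b0, b1))
        return out


def build_window_grid(chrom_length: int, window_size: int = DEFAULT_WINDOW_SIZE,
                      step: int = DEFAULT_STEP, chrom: str = "1",
                      min_snps: int = DEFAULT_MIN_SNPS,
                      include_partial: bool = False) -> WindowGrid:
    """Windows start at 1, 1+step, ...; full containment in [1, chrom_length]."""
    if not (window_size >= step >= 1):
        raise ValueError("require window_size >= step >= 1")
    if chrom_length < window_size:
        logger.warning("chromosome length %d shorter than window size %d: empty grid",
                       chrom_length, window_size)
        if not include_partial:
            return WindowGrid(chrom, window_size, step,
                              np.array([], dtype=np.int64),
                              np.array([], dtype=np.int64), min_snps)
    last_full_start = chrom_length - window_size + 1
    starts = np.arange(1, max(last_full_start, 0) + 1, step, dtype=np.int64)
    ends = starts + window_size - 1
    if include_partial:
        next_start = 1 + step * len(starts)
        if next_start <= chrom_length and (len(starts) == 0 or ends[-1] < chrom_length):
            starts = np.append(starts, next_start)
            ends = np.append(ends, chrom_length)
    return WindowGrid(chrom=chrom, window_size=window_size, step=step,
                      starts=starts, ends=ends, min_snps=min_snps)


def assign_snps(grid: WindowGrid, h: HaplotypeSet) -> WindowGrid:
    """Fill per-window SNP membership; sparse windows stay but are unscored."""
    pos = h.positions
    snp_index: list[np.ndarray] = []
    counts = np.zeros(grid.n_windows, dtype=np.int64)
    for w, (s, e) in enumerate(zip(grid.starts, grid.ends)):
        lo = np.searchsorted(pos, s, side="left")
        hi = np.searchsorted(pos, e, side="right")
        idx = np.arange(lo, hi, dtype=np.intp)
        snp_index.append(idx)
        counts[w] = hi - lo
    grid.snp_index = snp_index
    grid.n_snps = counts
    grid.scored = counts >= grid.min_snps
    logger.info("%d of %d windows scored (min_snps=%d)",
                grid.n_scored, grid.n_windows, grid.min_snps)
    return grid
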