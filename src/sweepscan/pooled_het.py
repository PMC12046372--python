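"""Windowed pooled heterozygosity Hp and Z-standardization.

Hp per window: with S_maj and S_min the sums over the window's SNPs of the
major- and minor-allele counts in the population,

    Hp = 2 * S_maj * S_min / (S_maj + S_min)**2

Allele counts come from called genotypes (non-missing alleles only);
major/minor is decided per SNP within the population, ties broken toward
REF (the value is symmetric, so the tie rule only fixes reporting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from sweepscan.data_io import HaplotypeSet
from sweepscan.windows import WindowGrid

logger = logging.getLogger(__name__)


@dataclass
class ScoreTrack:
    """Per-window values of one statistic for one population or pair.

    ``values`` is aligned with ``grid``'s windows; unscored/undefined windows
    hold NaN.  ``context`` is a population label or a (popA, popB) tuple.
    """

    statistic: str
    context: str | tuple[str, str]
    grid: WindowGrid
    values: np.ndarray
    n_snps: np.ndarray
    standardized: bool = False

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.grid.chrom,
            "start": self.grid.starts,
            "end": self.grid.ends,
            "n_snps": self.n_snps,
            self.statistic: self.values,
        })

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def pop_allele_counts(h: HaplotypeSet, sample_idx: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """(ref_count, alt_count) per variant over non-missing alleles of a population."""
    rows = h.hap_rows(sample_idx)
    haps = h.haplotypes[rows]
    miss = np.repeat(h.missing[sample_idx], 2, axis=0)
    alt = np.where(miss, 0, haps).sum(axis=0)
    total = (~miss).sum(axis=0)
    return total - alt, alt


def window_hp(h: HaplotypeSet, pop_samples: Sequence[str], grid: WindowGrid,
              population: str = "pop") -> ScoreTrack:
    """Pooled heterozygosity per scored window for one population."""
    if grid.snp_index is None:
        raise ValueError("grid has no SNP assignment; call assign_snps first")
    if len(pop_samples) == 0:
        raise ValueError("population is empty")
    sample_idx = h.sample_indices(pop_samples)
    ref_n, alt_n = pop_allele_counts(h, sample_idx)
    n_maj = np.maximum(ref_n, alt_n)       # ties resolve toward REF == maximum works
    n_min = np.minimum(ref_n, alt_n)

    values = np.full(grid.n_windows, np.nan)
    for w in range(grid.n_windows):
        if not grid.scored[w]:
            continue
        idx = grid.snp_index[w]
        s_maj = float(n_maj[idx].sum())
        s_min = float(n_min[idx].sum())
        tot = s_maj + s_min
        if tot == 0:
            logger.warning("window %d: all SNPs fully missing in %s", w, population)
            continue
        values[w] = 2.0 * s_maj * s_min / (tot * tot)
    return ScoreTrack(statistic="Hp", context=population, grid=grid,
                      values=values, n_snps=grid.n_snps.copy())


def z_standardize(track: ScoreTrack) -> ScoreTrack:
    """Genome-wide z-scores over the track's defined windows (population sd)."""
    defined = track.defined
    vals = track.values[defined]
    if vals.size < 2:
        raise ValueError(f"track {track.statistic}/{track.context}: "
                         "need >= 2 defined windows to standardize")
    mean = vals.mean()
    sd = vals.std(ddof=0)
    if sd == 0:
        raise ValueError(f"track {track.statistic}/{track.context}: sd is zero")
    z = np.full_like(track.values, np.nan)
    z[defined] = (vals - mean) / sd
    name = track.statistic if track.statistic.startswith("Z") else "Z" + track.statistic
    return replace(track, statistic=name, values=z, standardized=True)
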