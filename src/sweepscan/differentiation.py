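"""Weir-Cockerham (1984) two-population FST, per SNP and windowed.

Per SNP, with populations i = 1..r (r = 2), sizes n_i (non-missing
diploids), allele frequencies p_i, observed heterozygote proportions h_i:

    n_bar = sum(n_i) / r
    n_c   = (r*n_bar - sum(n_i^2)/(r*n_bar)) / (r - 1)
    p_bar = sum(n_i*p_i) / (r*n_bar)
    s2    = sum(n_i*(p_i - p_bar)^2) / ((r-1)*n_bar)
    h_bar = sum(n_i*h_i) / (r*n_bar)
    a = (n_bar/n_c) * (s2 - (p_bar*(1-p_bar) - s2*(r-1)/r - h_bar/4) / (n_bar-1))
    b = (n_bar/(n_bar-1)) * (p_bar*(1-p_bar) - s2*(r-1)/r - h_bar*(2*n_bar-1)/(4*n_bar))
    c = h_bar / 2

theta = a / (a + b + c), undefined (NaN) when the denominator is zero.
The windowed value is the weighted ratio-of-sums  sum(a) / sum(a+b+c);
negative estimates are reported as-is, never clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from sweepscan.data_io import HaplotypeSet
from sweepscan.pooled_het import ScoreTrack
from sweepscan.windows import WindowGrid

logger = logging.getLogger(__name__)


@dataclass
class FstComponents:
    """Per-SNP variance components; ``defined`` marks usable SNPs."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    defined: np.ndarray   # both pops genotyped and n_bar > 1

    @property
    def theta(self) -> np.ndarray:
        denom = self.a + self.b + self.c
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where((denom != 0) & self.defined, self.a / denom, np.nan)
        return t


def _pop_snp_stats(h: HaplotypeSet, sample_idx: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n non-missing diploids, ALT frequency, het proportion) per variant."""
    d0 = h.haplotypes[2 * sample_idx]
    d1 = h.haplotypes[2 * sample_idx + 1]
    miss = h.missing[sample_idx]
    n = (~miss).sum(axis=0).astype(float)
    alt = np.where(miss, 0, d0 + d1).sum(axis=0).astype(float)
    het = np.where(miss, False, d0 != d1).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
        hprop = np.where(n > 0, het / n, np.nan)
    return n, p, hprop


def wc_fst_components(h: HaplotypeSet, popA_samples: Sequence[str],
                      popB_samples: Sequence[str]) -> FstComponents:
    """Vectorized Weir-Cockerham components for every variant."""
    idxA = h.sample_indices(popA_samples)
    idxB = h.sample_indices(popB_samples)
    n1, p1, h1 = _pop_snp_stats(h, idxA)
    n2, p2, h2 = _pop_snp_stats(h, idxB)
    return wc_components_from_stats(n1, p1, h1, n2, p2, h2)


def wc_components_from_stats(n1, p1, h1, n2, p2, h2) -> FstComponents:
    """Components from per-population (n, p, het) arrays; r = 2."""
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    r = 2.0
    defined = (n1 >= 1) & (n2 >= 1)
    n_bar = (n1 + n2) / r
    defined &= n_bar > 1  # a and b divide by n_bar - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        inner = p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4
        a = (n_bar / n_c) * (s2 - inner / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar))
        c = h_bar / 2
    a = np.where(defined, a, np.nan)
    b = np.where(defined, b, np.nan)
    c = np.where(defined, c, np.nan)
    n_undef = int((~defined).sum())
    if n_undef:
        logger.info("%d variants lack genotypes in one or both populations", n_undef)
    return FstComponents(a=a, b=b, c=c, defined=defined)


def wc_fst_snp(h: HaplotypeSet, popA_samples: Sequence[str],
               popB_samples: Sequence[str], variant: int) -> tuple[float, float, float, float]:
    """(a, b, c, theta) at one variant; theta is NaN when undefined."""
    comp = wc_fst_components(h, popA_samples, popB_samples)
    return (float(comp.a[variant]), float(comp.b[variant]), float(comp.c[variant]),
            float(comp.theta[variant]))


def windowed_fst(comp: FstComponents, grid: WindowGrid,
                 context: tuple[str, str] = ("popA", "popB")) -> ScoreTrack:
    """Weighted ratio-of-sums FST per scored window."""
    if grid.snp_index is None:
        raise ValueError("grid has no SNP assignment; call assign_snps first")
    values = np.full(grid.n_windows, np.nan)
    counts = np.zeros(grid.n_windows, dtype=np.int64)
    for w in range(grid.n_windows):
        idx = grid.snp_index[w]
        idx = idx[comp.defined[idx]]
        counts[w] = len(idx)
        if len(idx) < grid.min_snps:
            continue
        num = float(comp.a[idx].sum())
        den = float((comp.a[idx] + comp.b[idx] + comp.c[idx]).sum())
        if den <= 0:
            logger.warning("window %d: non-positive FST denominator, undefined", w)
            continue
        values[w] = num / den
    return ScoreTrack(statistic="FST", context=context, grid=grid,
                      values=values, n_snps=counts, standardized=False)


def observed_heterozygosity(h: HaplotypeSet, pop_samples: Sequence[str]
                            ) -> tuple[pd.Series, float]:
    """Per-sample fraction of non-missing genotypes that are heterozygous,
    and the population mean of those fractions."""
    idx = h.sample_indices(pop_samples)
    d0 = h.haplotypes[2 * idx]
    d1 = h.haplotypes[2 * idx + 1]
    miss = h.missing[idx]
    het = np.where(miss, False, d0 != d1).sum(axis=1).astype(float)
    n = (~miss).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n > 0, het / n, np.nan)
    per_sample = pd.Series(frac, index=[h.sample_ids[i] for i in idx])
    return per_sample, float(np.nanmean(frac))
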