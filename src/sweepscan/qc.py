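"""Variant quality control: MAF, call rate, and greedy windowed LD pruning.

Keep rules are exclusive on the keep side: a variant survives iff
MAF > maf_min and call rate > callrate_min (so MAF == 0.05 or call rate
== 0.95 are excluded at the defaults).  LD pruning is PLINK-style greedy:
within each window of ``ld_window_snps`` variants, remove the later member
of any kept pair whose genotype-dosage r-squared exceeds ``ld_r2_max``,
then slide by ``ld_step_snps``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from sweepscan.data_io import HaplotypeSet

logger = logging.getLogger(__name__)


@dataclass
class QcConfig:
    maf_min: float = 0.05
    callrate_min: float = 0.95
    ld_r2_max: float = 0.1
    ld_window_snps: int = 50
    ld_step_snps: int = 5

    def __post_init__(self):
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        if not (0 < self.callrate_min <= 1):
            raise ValueError("callrate_min must be in (0, 1]")
        if not (0 < self.ld_r2_max <= 1):
            raise ValueError("ld_r2_max must be in (0, 1]")


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_removed_maf: int
    n_removed_callrate: int
    n_dual: int  # failed both; counted under MAF
    kept_index: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_removed_maf": self.n_removed_maf,
            "n_removed_callrate": self.n_removed_callrate,
            "n_dual": self.n_dual,
        }


def variant_maf(h: HaplotypeSet) -> np.ndarray:
    """Minor-allele frequency per variant over non-missing alleles."""
    miss = np.repeat(h.missing, 2, axis=0)
    alt = np.where(miss, 0, h.haplotypes).sum(axis=0).astype(float)
    total = (~miss).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(total > 0, alt / total, np.nan)
    return np.minimum(p_alt, 1.0 - p_alt)


def variant_callrate(h: HaplotypeSet) -> np.ndarray:
    return 1.0 - h.missing.mean(axis=0)


def filter_variants(h: HaplotypeSet, cfg: QcConfig | None = None
                    ) -> tuple[HaplotypeSet, FilterReport]:
    """Keep variants with MAF > maf_min AND call rate > callrate_min."""
    cfg = cfg or QcConfig()
    if h.n_variants == 0:
        raise ValueError("empty HaplotypeSet")
    maf = variant_maf(h)
    callrate = variant_callrate(h)
    pass_maf = np.nan_to_num(maf, nan=0.0) > cfg.maf_min
    pass_cr = callrate > cfg.callrate_min
    keep = pass_maf & pass_cr
    fail_maf = ~pass_maf
    fail_cr_only = pass_maf & ~pass_cr
    dual = (~pass_maf) & (~pass_cr)
    report = FilterReport(
        n_input=h.n_variants,
        n_kept=int(keep.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_removed_callrate=int(fail_cr_only.sum()),
        n_dual=int(dual.sum()),
        kept_index=np.flatnonzero(keep),
    )
    if report.n_kept == 0:
        logger.warning("all %d variants removed by QC filters", h.n_variants)
    return h.take_variants(report.kept_index), report


def genotype_dosages(h: HaplotypeSet) -> np.ndarray:
    """Per-sample ALT dosage (0/1/2) with NaN for missing genotypes."""
    dos = (h.haplotypes[0::2].astype(float) + h.haplotypes[1::2].astype(float))
    dos[h.missing] = np.nan
    return dos


def _pair_r2(dos_i: np.ndarray, dos_j: np.ndarray) -> float:
    ok = ~(np.isnan(dos_i) | np.isnan(dos_j))
    if ok.sum() < 2:
        return 0.0
    x, y = dos_i[ok], dos_j[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0  # monomorphic in the shared samples: defined as no LD
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune(h: HaplotypeSet, cfg: QcConfig | None = None
             ) -> tuple[np.ndarray, int]:
    """Greedy left-to-right windowed pruning on one chromosome.

    Returns (kept variant indices, removed count); deterministic.
    """
    cfg = cfg or QcConfig()
    m = h.n_variants
    dos = genotype_dosages(h)
    kept = np.ones(m, dtype=bool)
    w = 0
    while w < m:
        window = range(w, min(w + cfg.ld_window_snps, m))
        for i in window:
            if not kept[i]:
                continue
            for j in window:
                if j <= i or not kept[j]:
                    continue
                if _pair_r2(dos[:, i], dos[:, j]) > cfg.ld_r2_max:
                    kept[j] = False
        if w + cfg.ld_window_snps >= m:
            break
        w += cfg.ld_step_snps
    kept_idx = np.flatnonzero(kept)
    return kept_idx, int(m - kept.sum())


def ld_prune_multi(sets: dict[str, HaplotypeSet], cfg: QcConfig | None = None
                   ) -> dict[str, np.ndarray]:
    """Prune each chromosome independently (LD pruning never crosses chromosomes)."""
    return {chrom: ld_prune(h, cfg)[0] for chrom, h in sets.items()}
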