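"""EHH decay, integrated haplotype homozygosity, iHS and XP-EHH.

EHH at marker m for a set S of haplotypes carrying a core allele (n = |S|):
group S by exact identity over all markers between the core and m inclusive;
EHH(m) = sum_g C(k_g, 2) / C(n, 2).  The curve starts at (0, 1) and is
monotone non-increasing.

iHH is the trapezoidal integral of EHH against cM distance, truncated at the
first marker with EHH below the decay cutoff (that marker's segment is
included).  A direction that reaches the chromosome end before decaying is
"truncated"; truncated cores are dropped by default.

Defaults (decay cutoff 0.05, core MAF 0.05, 50 equal-width standardization
bins) follow common haplotype-scan tooling conventions and are configurable.
The ancestral allele defaults to REF; this choice flips iHS signs, so make
it deliberately (``ancestral_mode`` = "ref" | "major" | "flag").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from sweepscan.data_io import (
    ANCESTRAL_UNKNOWN,
    ALT_IS_ANCESTRAL,
    REF_IS_ANCESTRAL,
    GeneticMap,
    HaplotypeSet,
    interpolate_cm,
)
from sweepscan.pooled_het import ScoreTrack
from sweepscan.windows import WindowGrid

logger = logging.getLogger(__name__)

DEFAULT_EHH_CUTOFF = 0.05
DEFAULT_N_BINS = 50

STATUS_OK = "ok"
STATUS_MAF = "skipped_maf"
STATUS_TRUNCATED = "skipped_truncated"
STATUS_MISSING = "skipped_missing"
STATUS_BIN = "skipped_bin"
STATUS_ANCESTRAL = "skipped_ancestral"


@dataclass
class SnpScore:
    index: int
    position: int
    freq: float                 # derived-allele (iHS) or pooled (XP-EHH) frequency
    raw: float | None
    z: float | None
    status: str


@dataclass
class EhhCurve:
    core: int
    allele: str
    direction: str              # "left" | "right"
    dist: np.ndarray            # cM from core, >= 0, starts at 0
    ehh: np.ndarray             # starts at 1, non-increasing
    hit_end: bool               # reached chromosome end with EHH >= cutoff

    def __post_init__(self):
        self.dist = np.asarray(self.dist, dtype=float)
        self.ehh = np.asarray(self.ehh, dtype=float)
        if len(self.ehh) == 0 or self.ehh[0] != 1.0 or self.dist[0] != 0.0:
            raise ValueError("EHH curve must start at (0, 1)")
        if np.any(np.diff(self.ehh) > 1e-12):
            raise ValueError("EHH must be non-increasing")


def _require_complete(h: HaplotypeSet, sample_idx: np.ndarray) -> None:
    if h.missing[sample_idx].any():
        raise ValueError(
            "missing genotypes present; haplotype statistics require a "
            "missing-free input — apply HaplotypeSet.drop_missing_variants() first"
        )


def _walk(haps: np.ndarray, core: int, step: int, cm: np.ndarray,
          cutoff: float) -> tuple[np.ndarray, np.ndarray, bool]:
    """March outward from the core one marker at a time, refining groups."""
    n, m = haps.shape
    denom = n * (n - 1) / 2.0
    gid = haps[:, core].astype(np.int64)  # core marker included in identity
    dists = [0.0]
    ehhs = [1.0]
    j = core + step
    hit_end = True
    while 0 <= j < m:
        gid, counts = _refine(gid, haps[:, j])
        e = float((counts * (counts - 1) // 2).sum() / denom)
        dists.append(abs(cm[j] - cm[core]))
        ehhs.append(e)
        if e < cutoff:
            hit_end = False
            break
        j += step
    return np.array(dists), np.array(ehhs), hit_end


def _refine(gid: np.ndarray, alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split groups by the next marker's alleles; returns (new gid, group sizes).

    Counting-based relabel (no sort): keys are gid*2 + allele, compacted to
    consecutive ids via a cumulative-presence lookup.
    """
    key = gid * 2 + alleles
    counts = np.bincount(key)
    present = counts > 0
    lookup = np.cumsum(present) - 1
    return lookup[key], counts[present]


def ehh_decay(h: HaplotypeSet, core: int, allele, direction: str,
              gmap: GeneticMap | None = None,
              cutoff: float = DEFAULT_EHH_CUTOFF,
              sample_idx: np.ndarray | None = None) -> EhhCurve:
    """EHH decay curve from ``core`` in one direction for one allele class.

    ``allele`` is 0 (REF), 1 (ALT) or "all" (pooled, as used by XP-EHH).
    """
    if sample_idx is None:
        sample_idx = np.arange(h.n_samples, dtype=np.intp)
    _require_complete(h, sample_idx)
    haps = h.haplotypes[h.hap_rows(sample_idx)]
    if allele == "all":
        rows = np.arange(haps.shape[0])
    else:
        rows = np.flatnonzero(haps[:, core] == allele)
    if len(rows) < 2:
        raise ValueError(f"fewer than 2 haplotypes carry allele {allele!r} at core {core}")
    cm = np.asarray(interpolate_cm(gmap, h.chrom, h.positions.astype(float)))
    step = -1 if direction == "left" else 1
    dist, ehh, hit_end = _walk(haps[rows], core, step, cm, cutoff)
    return EhhCurve(core=core, allele=str(allele), direction=direction,
                    dist=dist, ehh=ehh, hit_end=hit_end)


def ihh(curve_left: EhhCurve, curve_right: EhhCurve,
        cutoff: float = DEFAULT_EHH_CUTOFF) -> tuple[float, bool]:
    """Two-sided trapezoidal iHH; second element flags chromosome-end truncation."""
    total = 0.0
    truncated = False
    for curve in (curve_left, curve_right):
        if len(curve.ehh) == 0:
            raise ValueError("empty EHH curve")
        if curve.hit_end:
            truncated = True
        total += float(np.trapezoid(curve.ehh, curve.dist))
    return total, truncated


def _ihh_one(dist: np.ndarray, ehh: np.ndarray) -> float:
    return float(np.trapezoid(ehh, dist))


def _ancestral_code(h: HaplotypeSet, haps: np.ndarray, j: int, mode: str) -> int | None:
    if mode == "ref":
        return 0
    if mode == "major":
        alt_count = int(haps[:, j].sum())
        return 1 if alt_count > haps.shape[0] - alt_count else 0
    if mode == "flag":
        flag = h.ancestral[j]
        if flag == REF_IS_ANCESTRAL:
            return 0
        if flag == ALT_IS_ANCESTRAL:
            return 1
        return None  # ANCESTRAL_UNKNOWN
    raise ValueError(f"unknown ancestral_mode {mode!r}")


def ihs_scan(h: HaplotypeSet, pop_samples: Sequence[str],
             gmap: GeneticMap | None = None, maf_min: float = 0.05,
             cutoff: float = DEFAULT_EHH_CUTOFF, n_bins: int = DEFAULT_N_BINS,
             ancestral_mode: str = "ref",
             keep_truncated: bool = False) -> list[SnpScore]:
    """Per-SNP iHS = ln(iHH_ancestral / iHH_derived), standardized in
    equal-width derived-allele-frequency bins."""
    sample_idx = h.sample_indices(pop_samples)
    _require_complete(h, sample_idx)
    haps = h.haplotypes[h.hap_rows(sample_idx)]
    n, m = haps.shape
    cm = np.asarray(interpolate_cm(gmap, h.chrom, h.positions.astype(float)))

    scores: list[SnpScore] = []
    for j in range(m):
        anc = _ancestral_code(h, haps, j, ancestral_mode)
        if anc is None:
            scores.append(SnpScore(j, int(h.positions[j]), math.nan, None, None,
                                   STATUS_ANCESTRAL))
            continue
        der = 1 - anc
        daf = float((haps[:, j] == der).mean())
        maf = min(daf, 1.0 - daf)
        n_der = int(round(daf * n))
        if maf <= maf_min or n_der < 2 or n - n_der < 2:
            scores.append(SnpScore(j, int(h.positions[j]), daf, None, None, STATUS_MAF))
            continue
        raw = None
        truncated = False
        ihh_by_class = {}
        for label, allele in (("anc", anc), ("der", der)):
            rows = np.flatnonzero(haps[:, j] == allele)
            sub = haps[rows]
            value = 0.0
            for step in (-1, 1):
                dist, ehh, hit_end = _walk(sub, j, step, cm, cutoff)
                if hit_end:
                    truncated = True
                value += _ihh_one(dist, ehh)
            ihh_by_class[label] = value
        if truncated and not keep_truncated:
            scores.append(SnpScore(j, int(h.positions[j]), daf, None, None,
                                   STATUS_TRUNCATED))
            continue
        if ihh_by_class["anc"] <= 0 or ihh_by_class["der"] <= 0:
            scores.append(SnpScore(j, int(h.positions[j]), daf, None, None,
                                   STATUS_TRUNCATED))
            continue
        # log difference (not log of ratio) keeps A/B antisymmetry bit-exact
        raw = math.log(ihh_by_class["anc"]) - math.log(ihh_by_class["der"])
        scores.append(SnpScore(j, int(h.positions[j]), daf, raw, None, STATUS_OK))

    _standardize_binned(scores, n_bins)
    n_ok = sum(1 for s in scores if s.status == STATUS_OK)
    if n_ok == 0:
        logger.warning("iHS scan produced no scored SNPs")
    return scores


def _standardize_binned(scores: list[SnpScore], n_bins: int) -> None:
    """In-place z within equal-width frequency bins over (0, 1)."""
    bins: dict[int, list[SnpScore]] = {}
    for s in scores:
        if s.status == STATUS_OK:
            b = min(int(s.freq * n_bins), n_bins - 1)
            bins.setdefault(b, []).append(s)
    for b, members in bins.items():
        raws = np.array([s.raw for s in members])
        if len(members) < 2 or raws.std(ddof=0) == 0:
            logger.warning("frequency bin %d has <2 usable scores; members skipped", b)
            for s in members:
                s.status = STATUS_BIN
            continue
        mean, sd = raws.mean(), raws.std(ddof=0)
        for s in members:
            s.z = (s.raw - mean) / sd


def _walk_pair(hapsA: np.ndarray, hapsB: np.ndarray, core: int, step: int,
               cm: np.ndarray, cutoff: float):
    """Shared-boundary pooled walk for XP-EHH: stop when BOTH EHH < cutoff."""
    m = hapsA.shape[1]
    nA, nB = hapsA.shape[0], hapsB.shape[0]
    denA = nA * (nA - 1) / 2.0
    denB = nB * (nB - 1) / 2.0
    gidA = hapsA[:, core].astype(np.int64)
    gidB = hapsB[:, core].astype(np.int64)
    dists = [0.0]
    ehhA = [1.0]
    ehhB = [1.0]
    j = core + step
    hit_end = True
    while 0 <= j < m:
        gidA, cA = _refine(gidA, hapsA[:, j])
        eA = float((cA * (cA - 1) // 2).sum() / denA)
        gidB, cB = _refine(gidB, hapsB[:, j])
        eB = float((cB * (cB - 1) // 2).sum() / denB)
        dists.append(abs(cm[j] - cm[core]))
        ehhA.append(eA)
        ehhB.append(eB)
        if eA < cutoff and eB < cutoff:
            hit_end = False
            break
        j += step
    return np.array(dists), np.array(ehhA), np.array(ehhB), hit_end


def xpehh_scan(hA: HaplotypeSet, hB: HaplotypeSet,
               gmap: GeneticMap | None = None,
               cutoff: float = DEFAULT_EHH_CUTOFF,
               keep_truncated: bool = False) -> list[SnpScore]:
    """Per-SNP XP-EHH = ln(iHH_A / iHH_B) over all haplotypes of each
    population, integrated to a shared decay boundary; genome-wide z."""
    if not np.array_equal(hA.positions, hB.positions):
        raise ValueError("populations must share an identical variant grid")
    for h in (hA, hB):
        _require_complete(h, np.arange(h.n_samples, dtype=np.intp))
        if 2 * h.n_samples < 2:
            raise ValueError("each population needs >= 2 haplotypes")
    hapsA = hA.haplotypes
    hapsB = hB.haplotypes
    m = hA.n_variants
    cm = np.asarray(interpolate_cm(gmap, hA.chrom, hA.positions.astype(float)))
    n_total = hapsA.shape[0] + hapsB.shape[0]

    scores: list[SnpScore] = []
    for j in range(m):
        pooled_freq = float((hapsA[:, j].sum() + hapsB[:, j].sum()) / n_total)
        ihhA = ihhB = 0.0
        truncated = False
        for step in (-1, 1):
            dist, eA, eB, hit_end = _walk_pair(hapsA, hapsB, j, step, cm, cutoff)
            if hit_end:
                truncated = True
            ihhA += _ihh_one(dist, eA)
            ihhB += _ihh_one(dist, eB)
        if truncated and not keep_truncated:
            scores.append(SnpScore(j, int(hA.positions[j]), pooled_freq, None, None,
                                   STATUS_TRUNCATED))
            continue
        if ihhA <= 0 or ihhB <= 0:
            scores.append(SnpScore(j, int(hA.positions[j]), pooled_freq, None, None,
                                   STATUS_TRUNCATED))
            continue
        raw = math.log(ihhA) - math.log(ihhB)
        scores.append(SnpScore(j, int(hA.positions[j]), pooled_freq, raw, None,
                               STATUS_OK))

    ok = [s for s in scores if s.status == STATUS_OK]
    if ok:
        raws = np.array([s.raw for s in ok])
        sd = raws.std(ddof=0)
        if sd == 0:
            logger.warning("XP-EHH raw scores are constant; z set to 0")
            for s in ok:
                s.z = 0.0
        else:
            mean = raws.mean()
            for s in ok:
                s.z = (s.raw - mean) / sd
    else:
        logger.warning("XP-EHH scan produced no scored SNPs")
    return scores


def window_mean_scores(scores: list[SnpScore], grid: WindowGrid,
                       mode: str = "abs", statistic: str = "iHS_win",
                       context: str | tuple[str, str] = "pop") -> ScoreTrack:
    """Windowed mean of standardized per-SNP scores (|z| by default)."""
    if mode not in ("abs", "signed"):
        raise ValueError("mode must be 'abs' or 'signed'")
    if grid.snp_index is None:
        raise ValueError("grid has no SNP assignment; call assign_snps first")
    z_by_index = np.full(max((s.index for s in scores), default=-1) + 1, np.nan)
    for s in scores:
        if s.status == STATUS_OK and s.z is not None:
            z_by_index[s.index] = abs(s.z) if mode == "abs" else s.z
    values = np.full(grid.n_windows, np.nan)
    counts = np.zeros(grid.n_windows, dtype=np.int64)
    for w in range(grid.n_windows):
        idx = grid.snp_index[w]
        idx = idx[idx < len(z_by_index)]
        zs = z_by_index[idx]
        zs = zs[~np.isnan(zs)]
        counts[w] = len(zs)
        if len(zs) >= grid.min_snps:
            values[w] = zs.mean()
    return ScoreTrack(statistic=statistic, context=context, grid=grid,
                      values=values, n_snps=counts, standardized=False)


def scores_to_frame(scores: list[SnpScore], chrom: str):
    import pandas as pd

    return pd.DataFrame({
        "chrom": chrom,
        "pos": [s.position for s in scores],
        "freq": [s.freq for s in scores],
        "raw": [s.raw for s in scores],
        "z": [s.z for s in scores],
        "status": [s.status for s in scores],
    })
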