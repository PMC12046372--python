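"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's algorithms: EHH is
computed by direct pairwise identity counting, interval support by per-base
counting on an explicit axis, and so on.  Expected values in the tests are
either frozen hand computations or outputs of these oracles.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from sweepscan.data_io import HaplotypeSet


def make_hapset(haps, positions=None, chrom="1", sample_ids=None,
                missing=None, ancestral=None) -> HaplotypeSet:
    """Build a HaplotypeSet from a plain 2D array of {0,1} haplotype rows."""
    haps = np.asarray(haps, dtype=np.int8)
    n_hap, m = haps.shape
    assert n_hap % 2 == 0
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_hap // 2)]
    return HaplotypeSet(
        chrom=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        ref=np.full(m, "A", dtype="U1"),
        alt=np.full(m, "G", dtype="U1"),
        haplotypes=haps,
        sample_ids=sample_ids,
        missing=missing,
        ancestral=ancestral,
    )


# ---------------------------------------------------------------------------
# EHH / iHH oracles: direct pair counting, no group refinement
# ---------------------------------------------------------------------------

def ehh_oracle(haps: np.ndarray, core: int, marker: int) -> float:
    """EHH at ``marker`` by counting identical pairs over [core..marker]."""
    lo, hi = min(core, marker), max(core, marker)
    seg = haps[:, lo:hi + 1]
    n = seg.shape[0]
    pairs = 0
    for i, j in itertools.combinations(range(n), 2):
        if np.array_equal(seg[i], seg[j]):
            pairs += 1
    return pairs / (n * (n - 1) / 2)


def ehh_curve_oracle(haps: np.ndarray, core: int, step: int, cm: np.ndarray,
                     cutoff: float):
    """(dists, ehhs, hit_end) matching the walk contract, via the pair oracle."""
    m = haps.shape[1]
    dists, ehhs = [0.0], [1.0]
    j = core + step
    hit_end = True
    while 0 <= j < m:
        e = ehh_oracle(haps, core, j)
        dists.append(abs(cm[j] - cm[core]))
        ehhs.append(e)
        if e < cutoff:
            hit_end = False
            break
        j += step
    return np.array(dists), np.array(ehhs), hit_end


def ihh_oracle(haps: np.ndarray, core: int, cm: np.ndarray, cutoff: float
               ) -> tuple[float, bool]:
    """Two-sided trapezoidal iHH via the pair-counting oracle."""
    total = 0.0
    truncated = False
    for step in (-1, 1):
        d, e, hit_end = ehh_curve_oracle(haps, core, step, cm, cutoff)
        if hit_end:
            truncated = True
        total += float(np.trapezoid(e, d))
    return total, truncated


def xpehh_raw_oracle(hapsA: np.ndarray, hapsB: np.ndarray, core: int,
                     cm: np.ndarray, cutoff: float,
                     keep_truncated: bool = False) -> float | None:
    """Raw XP-EHH at a core by pair counting with the shared stopping rule."""
    m = hapsA.shape[1]
    ihhA = ihhB = 0.0
    for step in (-1, 1):
        dists, eAs, eBs = [0.0], [1.0], [1.0]
        j = core + step
        hit_end = True
        while 0 <= j < m:
            eA = ehh_oracle(hapsA, core, j)
            eB = ehh_oracle(hapsB, core, j)
            dists.append(abs(cm[j] - cm[core]))
            eAs.append(eA)
            eBs.append(eB)
            if eA < cutoff and eB < cutoff:
                hit_end = False
                break
            j += step
        if hit_end and not keep_truncated:
            return None
        ihhA += float(np.trapezoid(eAs, dists))
        ihhB += float(np.trapezoid(eBs, dists))
    if ihhA <= 0 or ihhB <= 0:
        return None
    return float(np.log(ihhA) - np.log(ihhB))


# ---------------------------------------------------------------------------
# Interval oracles
# ---------------------------------------------------------------------------

def per_base_support(regionsets, axis_start: int, axis_end: int) -> np.ndarray:
    """Number of region sets covering each base of [axis_start, axis_end]."""
    cover = np.zeros(axis_end - axis_start + 1, dtype=int)
    for rs in regionsets:
        seen = np.zeros_like(cover, dtype=bool)
        for r in rs:
            lo = max(r.start, axis_start) - axis_start
            hi = min(r.end, axis_end) - axis_start
            if hi >= lo:
                seen[lo:hi + 1] = True
        cover += seen
    return cover


def regions_to_base_mask(regions, axis_start: int, axis_end: int) -> np.ndarray:
    mask = np.zeros(axis_end - axis_start + 1, dtype=bool)
    for r in regions:
        lo = max(r.start, axis_start) - axis_start
        hi = min(r.end, axis_end) - axis_start
        if hi >= lo:
            mask[lo:hi + 1] = True
    return mask


# ---------------------------------------------------------------------------
# Shared simulated datasets (kept deliberately small)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_sweep_dataset():
    from sweepscan.synthetic_data import SimConfig, SweepConfig, simulate_wf

    cfg = SimConfig(
        n_demes=2, deme_size=100, sample_size=20, chrom_length=150_000,
        mu=4e-6, recomb=2e-6, migration=0.01, generations=350,
        sweep=SweepConfig(enabled=True, deme=0, position=75_000, s=0.1,
                          introduction_generation=200, require_established=0.9),
        seed=11)
    h, popmap, gmap, truth = simulate_wf(cfg)
    return cfg, h, popmap, gmap, truth


@pytest.fixture(scope="session")
def small_neutral_dataset():
    from sweepscan.synthetic_data import SimConfig, simulate_wf

    cfg = SimConfig(n_demes=2, deme_size=60, sample_size=15, chrom_length=100_000,
                    mu=4e-6, recomb=2e-6, migration=0.5, generations=200, seed=7)
    h, popmap, gmap, truth = simulate_wf(cfg)
    return cfg, h, popmap, gmap, truth
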