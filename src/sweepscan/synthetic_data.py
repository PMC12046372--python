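"""Seeded forward Wright-Fisher simulator with an optional hard sweep.

Island model of ``n_demes`` demes of ``deme_size`` diploids.  Each
generation, every offspring haplotype is a recombinant mosaic of one
parent's two haplotypes (crossover count ~ Poisson(r*L), positions
uniform); parents are drawn proportional to fitness 1, 1+s, 1+2s by
sweep-allele count (additive); a Binomial(N, m) subset of each deme is
replaced by migrant copies from the other demes; new mutations arise under
the infinite-sites model (Poisson(mu*L*2N) per deme per generation,
position collisions re-drawn), so every variant is biallelic.

Rates are meant to be scaled up (mu, r around 1e-6 per bp) to reach
realistic SNP densities on short test chromosomes; they are not calibrated
to any real genome.  Founders carry no derived alleles, so REF is ancestral
by construction.

All randomness flows from ``SimConfig.seed``; sweep-establishment retries
re-run only the sweep phase from a snapshot taken at the introduction
generation, under a deterministic per-attempt substream.
"""

from __future__ import annotations

import copy
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from sweepscan import data_io
from sweepscan.data_io import (
    REF_IS_ANCESTRAL,
    GeneModel,
    GeneticMap,
    HaplotypeSet,
    PopulationMap,
)

logger = logging.getLogger(__name__)

BUDGET_GUARD = 50_000_000  # max n_demes * 2N * T offspring constructions


@dataclass
class SweepConfig:
    enabled: bool = False
    deme: int = 0
    position: int = 0              # bp in [1, L]
    s: float = 0.1
    introduction_generation: int = 0
    require_established: float = 0.0   # minimum final frequency in the swept deme
    stop_when_established: bool = True  # end the sweep phase once reached
    max_retries: int = 100


@dataclass
class SimConfig:
    n_demes: int = 2
    deme_size: int = 100           # diploids per deme
    sample_size: int = 25          # diploids sampled per deme
    chrom_length: int = 200_000
    mu: float = 3e-6               # per bp per generation
    recomb: float = 2e-6           # per bp per generation
    migration: float = 0.01        # per lineage per generation
    generations: int = 400
    sweep: SweepConfig = field(default_factory=SweepConfig)
    seed: int = 0
    chrom: str = "1"

    def __post_init__(self):
        if isinstance(self.sweep, dict):
            self.sweep = SweepConfig(**self.sweep)
        for name in ("mu", "recomb", "migration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sweep.enabled and not (1 <= self.sweep.position <= self.chrom_length):
            raise ValueError("sweep position must lie in [1, chrom_length]")
        if self.sample_size > self.deme_size:
            raise ValueError("sample_size cannot exceed deme_size")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class TruthRecord:
    sweep_enabled: bool
    sweep_position: int
    sweep_deme: int
    final_frequency: float         # in the swept deme (0 if disabled)
    trajectory: list[float]        # per generation since introduction
    n_restarts: int = 0


class _State:
    """Demes as lists of sorted int64 arrays of derived-mutation positions."""

    __slots__ = ("demes", "used_positions")

    def __init__(self, demes, used_positions):
        self.demes = demes                    # list[list[np.ndarray]], 2N haps per deme
        self.used_positions = used_positions  # set[int]

    def snapshot(self) -> "_State":
        return _State([list(d) for d in self.demes], set(self.used_positions))


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, L: int, r: float,
             rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a parent's two haplotypes."""
    k = rng.poisson(r * L)
    first = rng.integers(2)
    if k == 0:
        return hap_a if first == 0 else hap_b
    xs = np.sort(rng.integers(1, L + 1, size=k))
    sources = (hap_a, hap_b)
    bounds = np.concatenate(([0], xs, [L + 1]))
    parts = []
    which = first
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        src = sources[which]
        a = np.searchsorted(src, lo, side="right")
        b = np.searchsorted(src, hi, side="right")
        if b > a:
            parts.append(src[a:b])
        which ^= 1
    if not parts:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(parts)


def _sweep_counts(deme: list[np.ndarray], pos: int) -> np.ndarray:
    """Per-diploid count of the sweep allele (0/1/2)."""
    n = len(deme) // 2
    out = np.zeros(n, dtype=np.int64)
    for i in range(n):
        for hap in (deme[2 * i], deme[2 * i + 1]):
            j = np.searchsorted(hap, pos)
            if j < len(hap) and hap[j] == pos:
                out[i] += 1
    return out


def _one_generation(state: _State, cfg: SimConfig, rng: np.random.Generator,
                    sweep_active: bool) -> None:
    L = cfg.chrom_length
    n_demes = cfg.n_demes
    N = cfg.deme_size
    sw = cfg.sweep
    new_demes: list[list[np.ndarray]] = []
    for d in range(n_demes):
        deme = state.demes[d]
        if sweep_active and d == sw.deme:
            # local adaptation: the allele is beneficial only in its own deme
            counts = _sweep_counts(deme, sw.position)
            weights = 1.0 + sw.s * counts
            probs = weights / weights.sum()
            parent_idx = rng.choice(N, size=2 * N, p=probs)
        else:
            parent_idx = rng.integers(N, size=2 * N)
        offspring = []
        for i in range(N):
            pa, pb = parent_idx[2 * i], parent_idx[2 * i + 1]
            offspring.append(_meiosis(deme[2 * pa], deme[2 * pa + 1], L, cfg.recomb, rng))
            offspring.append(_meiosis(deme[2 * pb], deme[2 * pb + 1], L, cfg.recomb, rng))
        new_demes.append(offspring)

    # migration: replace a Binomial(N, m) subset of each deme with copies
    # of random individuals from other demes (pre-migration snapshot)
    if n_demes > 1 and cfg.migration > 0:
        snapshot = [list(d) for d in new_demes]
        for d in range(n_demes):
            k = rng.binomial(N, cfg.migration)
            if k == 0:
                continue
            targets = rng.choice(N, size=k, replace=False)
            for t in targets:
                src_deme = rng.integers(n_demes - 1)
                if src_deme >= d:
                    src_deme += 1
                src_ind = rng.integers(N)
                new_demes[d][2 * t] = snapshot[src_deme][2 * src_ind]
                new_demes[d][2 * t + 1] = snapshot[src_deme][2 * src_ind + 1]

    # mutation: infinite sites, collisions re-drawn
    for d in range(n_demes):
        n_mut = rng.poisson(cfg.mu * L * 2 * N)
        for _ in range(n_mut):
            pos = int(rng.integers(1, L + 1))
            while pos in state.used_positions:
                pos = int(rng.integers(1, L + 1))
            state.used_positions.add(pos)
            hap_i = int(rng.integers(2 * N))
            hap = new_demes[d][hap_i]
            j = np.searchsorted(hap, pos)
            new_demes[d][hap_i] = np.insert(hap, j, pos)

    state.demes = new_demes


def _sweep_frequency(state: _State, cfg: SimConfig) -> float:
    sw = cfg.sweep
    deme = state.demes[sw.deme]
    hits = 0
    for hap in deme:
        j = np.searchsorted(hap, sw.position)
        if j < len(hap) and hap[j] == sw.position:
            hits += 1
    return hits / len(deme)


def _introduce_sweep(state: _State, cfg: SimConfig, rng: np.random.Generator) -> None:
    sw = cfg.sweep
    state.used_positions.add(sw.position)
    hap_i = int(rng.integers(2 * cfg.deme_size))
    hap = state.demes[sw.deme][hap_i]
    j = np.searchsorted(hap, sw.position)
    if j < len(hap) and hap[j] == sw.position:
        return
    state.demes[sw.deme][hap_i] = np.insert(hap, j, sw.position)


def _sample_haplotype_set(state: _State, cfg: SimConfig,
                          rng: np.random.Generator
                          ) -> tuple[HaplotypeSet, PopulationMap]:
    sampled: list[np.ndarray] = []
    sample_ids: list[str] = []
    assignments: dict[str, str] = {}
    groups: dict[str, str] = {}
    for d in range(cfg.n_demes):
        pick = np.sort(rng.choice(cfg.deme_size, size=cfg.sample_size, replace=False))
        pop = f"deme{d}"
        if cfg.sweep.enabled:
            groups[pop] = "hot" if d == cfg.sweep.deme else "cold"
        else:
            groups[pop] = "hot" if d % 2 == 0 else "cold"
        for rank, i in enumerate(pick):
            sid = f"{pop}_s{rank}"
            sample_ids.append(sid)
            assignments[sid] = pop
            sampled.append(state.demes[d][2 * i])
            sampled.append(state.demes[d][2 * i + 1])

    n_haps = len(sampled)
    if sampled and any(len(h) for h in sampled):
        allpos, counts = np.unique(np.concatenate(sampled), return_counts=True)
        poly = (counts > 0) & (counts < n_haps)
        positions = allpos[poly]
    else:
        positions = np.empty(0, dtype=np.int64)
    m = len(positions)
    haps = np.zeros((n_haps, m), dtype=np.int8)
    for row, hap in enumerate(sampled):
        if len(hap) == 0:
            continue
        idx = np.searchsorted(positions, hap)
        ok = (idx < m)
        idx = idx[ok]
        hit = positions[idx] == hap[ok]
        haps[row, idx[hit]] = 1
    h = HaplotypeSet(
        chrom=cfg.chrom,
        positions=positions,
        ref=np.full(m, "A", dtype="U1"),
        alt=np.full(m, "G", dtype="U1"),
        haplotypes=haps,
        sample_ids=sample_ids,
        ancestral=np.full(m, REF_IS_ANCESTRAL, dtype=np.int8),
    )
    return h, PopulationMap(assignments=assignments, groups=groups)


def simulate_wf(cfg: SimConfig) -> tuple[HaplotypeSet, PopulationMap,
                                         GeneticMap, TruthRecord]:
    """Run the forward simulation and sample a phased dataset.

    Returns (haplotypes, population map, genetic map at 1 cM/Mb, truth).
    """
    cost = cfg.n_demes * 2 * cfg.deme_size * cfg.generations
    if cost > BUDGET_GUARD:
        raise ValueError(f"simulation budget exceeded: {cost} > {BUDGET_GUARD}; "
                         "reduce deme_size, generations, or n_demes")
    sw = cfg.sweep
    intro = min(sw.introduction_generation, cfg.generations) if sw.enabled else cfg.generations
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    state = _State([[np.empty(0, dtype=np.int64) for _ in range(2 * cfg.deme_size)]
                    for _ in range(cfg.n_demes)], set())

    for _ in range(intro):
        _one_generation(state, cfg, rng, sweep_active=False)

    if not sw.enabled:
        h, popmap = _sample_haplotype_set(state, cfg, rng)
        truth = TruthRecord(False, 0, -1, 0.0, [])
        return h, popmap, GeneticMap(), truth

    base = state.snapshot()
    n_restarts = 0
    for attempt in range(sw.max_retries + 1):
        sub = np.random.default_rng(np.random.SeedSequence(
            entropy=cfg.seed, spawn_key=(1, attempt)))
        state = base.snapshot()
        _introduce_sweep(state, cfg, sub)
        traj = [_sweep_frequency(state, cfg)]
        for _ in range(cfg.generations - intro):
            _one_generation(state, cfg, sub, sweep_active=True)
            freq = _sweep_frequency(state, cfg)
            traj.append(freq)
            if freq == 0.0:
                break  # lost: this attempt cannot establish
            if sw.stop_when_established and sw.require_established > 0 \
                    and freq >= sw.require_established:
                break  # young sweep: sample right at establishment
        if traj[-1] >= sw.require_established:
            h, popmap = _sample_haplotype_set(state, cfg, sub)
            truth = TruthRecord(True, sw.position, sw.deme, traj[-1], traj,
                                n_restarts=n_restarts)
            return h, popmap, GeneticMap(), truth
        n_restarts += 1
        logger.info("sweep attempt %d ended at frequency %.3f < %.3f; retrying",
                    attempt, traj[-1], sw.require_established)
    raise RuntimeError(f"sweep failed to establish within {sw.max_retries} retries")


# ---------------------------------------------------------------------------
# Hand-built micro fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str) -> dict:
    """Micro-datasets with frozen expected values for unit tests and demos."""
    if kind == "ehh_toy":
        # 4 carrier haplotypes (2 samples): identical at marker 1,
        # split 3/1 at marker 2 -> EHH = C(3,2)/C(4,2) = 0.5
        haps = np.array([
            [1, 0, 0],
            [1, 0, 0],
            [1, 0, 0],
            [1, 0, 1],
        ], dtype=np.int8)
        h = HaplotypeSet(chrom="1", positions=np.array([100, 200, 300]),
                         ref=np.array(list("AAA")), alt=np.array(list("GGG")),
                         haplotypes=haps, sample_ids=["s0", "s1"])
        return {"haplotypes": h, "core": 0, "allele": 1,
                "expected_ehh": [1.0, 1.0, 0.5]}
    if kind == "fst_toy":
        # popA fixed REF, popB fixed ALT, 10 diploids each -> theta = 1
        n = 10
        haps = np.vstack([np.zeros((2 * n, 1), dtype=np.int8),
                          np.ones((2 * n, 1), dtype=np.int8)])
        samples = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        h = HaplotypeSet(chrom="1", positions=np.array([1000]),
                         ref=np.array(["A"]), alt=np.array(["G"]),
                         haplotypes=haps, sample_ids=samples)
        return {"haplotypes": h,
                "popA": [f"a{i}" for i in range(n)],
                "popB": [f"b{i}" for i in range(n)],
                "expected_theta": 1.0}
    if kind == "window_toy":
        return {"chrom_length": 100_000, "window_size": 20_000, "step": 10_000,
                "expected_n_windows": 9,
                "expected_first": (1, 20_000), "expected_last": (80_001, 100_000)}
    if kind == "vcf_toy":
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "##contig=<ID=1>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3",
            "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0",
            "1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1\t1|1",
            "1\t300\t.\tG\tA,C\t.\tPASS\t.\tGT\t1|2\t0|1\t0|0",  # multiallelic, dropped
            "1\t400\t.\tT\tC\t.\tPASS\t.\tGT\t.|.\t0|1\t0|0",    # missing genotype
            "1\t500\t.\tA\tC\t.\tPASS\t.\tGT\t1|0\t0|0\t0|1",
            "1\t600\t.\tG\tT\t.\tPASS\t.\tGT\t0|1\t1|0\t0|0",
        ]
        return {"vcf_text": "\n".join(lines) + "\n",
                "expected_n_samples": 3, "expected_n_variants": 5,
                "expected_n_dropped": 1,
                "expected_missing": ("s1", 400)}
    raise ValueError(f"unknown fixture kind {kind!r}")


def random_genes(chrom: str, chrom_length: int, density_per_mb: float,
                 rng: np.random.Generator, mean_length: int = 5_000
                 ) -> list[GeneModel]:
    """Poisson-placed synthetic gene models, all within [1, chrom_length]."""
    n = rng.poisson(density_per_mb * chrom_length / 1e6)
    genes = []
    for i in range(n):
        start = int(rng.integers(1, chrom_length + 1))
        length = max(1, int(rng.exponential(mean_length)))
        end = min(chrom_length, start + length - 1)
        genes.append(GeneModel(gene_id=f"g{i}", gene_name=f"gene{i}", chrom=chrom,
                               start=start, end=end,
                               strand="+" if rng.integers(2) else "-"))
    genes.sort(key=lambda g: g.start)
    return genes


def export_dataset(h: HaplotypeSet, popmap: PopulationMap, out_dir: str,
                   prefix: str = "sim", genes: list[GeneModel] | None = None,
                   rate_cm_per_bp: float = 1e-6) -> dict[str, str]:
    """Write VCF + population map + PLINK .map (+ optional GFF3)."""
    data_io.ensure_dir(out_dir)
    paths = {
        "vcf": os.path.join(out_dir, f"{prefix}.vcf"),
        "popmap": os.path.join(out_dir, f"{prefix}.popmap.txt"),
        "map": os.path.join(out_dir, f"{prefix}.map"),
    }
    data_io.write_phased_vcf(h, paths["vcf"])
    data_io.write_population_map(popmap, paths["popmap"])
    data_io.write_plink_map(h, paths["map"], rate_cm_per_bp)
    if genes is not None:
        paths["genes"] = os.path.join(out_dir, f"{prefix}.genes.gff3")
        data_io.write_gff3(genes, paths["genes"])
    return paths
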