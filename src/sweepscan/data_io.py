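"""Readers and writers for the formats the scan touches.

Internal coordinate convention is 1-based inclusive everywhere; BED I/O
converts at the boundary.  Haplotypes are coded 0 = REF, 1 = ALT; ancestral
orientation is a separate per-variant flag and never a re-encoding.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

# ancestral flag codes
REF_IS_ANCESTRAL = 0
ALT_IS_ANCESTRAL = 1
ANCESTRAL_UNKNOWN = 2

_NUCLEOTIDES = frozenset("ACGT")


class InputError(ValueError):
    """Raised when an input file violates its documented contract."""


@dataclass
class HaplotypeSet:
    """Phased biallelic variants for one chromosome.

    ``haplotypes`` has one row per haploid sequence (two consecutive rows per
    diploid sample, in ``sample_ids`` order) and one column per variant.
    Missingness is genotype-level: both haplotype rows of a sample are missing
    together, tracked in the per-(sample, variant) ``missing`` mask.
    """

    chrom: str
    positions: np.ndarray          # int64, 1-based, strictly increasing
    ref: np.ndarray                # single-character alleles
    alt: np.ndarray
    haplotypes: np.ndarray         # int8, (2 * n_samples, n_variants), values {0, 1}
    sample_ids: list[str]
    ancestral: np.ndarray = field(default=None)  # int8 flags, see module constants
    missing: np.ndarray = field(default=None)    # bool, (n_samples, n_variants)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.ref = np.asarray(self.ref, dtype="U1")
        self.alt = np.asarray(self.alt, dtype="U1")
        if self.ancestral is None:
            self.ancestral = np.full(self.n_variants, ANCESTRAL_UNKNOWN, dtype=np.int8)
        else:
            self.ancestral = np.asarray(self.ancestral, dtype=np.int8)
        if self.missing is None:
            self.missing = np.zeros((self.n_samples, self.n_variants), dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return self.positions.shape[0]

    def validate(self) -> None:
        if self.haplotypes.shape != (2 * self.n_samples, self.n_variants):
            raise ValueError(
                f"haplotype matrix shape {self.haplotypes.shape} does not match "
                f"2x{self.n_samples} samples x {self.n_variants} variants"
            )
        if self.n_variants > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if self.missing.shape != (self.n_samples, self.n_variants):
            raise ValueError("missing mask shape mismatch")
        hap_missing = np.repeat(self.missing, 2, axis=0)
        observed = self.haplotypes[~hap_missing]
        if observed.size and not np.isin(observed, (0, 1)).all():
            raise ValueError("non-missing haplotype entries must be 0 or 1")

    # -- selection helpers ------------------------------------------------

    def sample_indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not present") from None

    def hap_rows(self, sample_idx: np.ndarray) -> np.ndarray:
        """Haplotype row indices (2 per sample) for the given sample indices."""
        sample_idx = np.asarray(sample_idx, dtype=np.intp)
        return np.column_stack([2 * sample_idx, 2 * sample_idx + 1]).reshape(-1)

    def subset_samples(self, sample_ids: Sequence[str]) -> "HaplotypeSet":
        idx = self.sample_indices(sample_ids)
        return HaplotypeSet(
            chrom=self.chrom,
            positions=self.positions.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            haplotypes=self.haplotypes[self.hap_rows(idx)].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            ancestral=self.ancestral.copy(),
            missing=self.missing[idx].copy(),
        )

    def take_variants(self, variant_idx: np.ndarray) -> "HaplotypeSet":
        variant_idx = np.asarray(variant_idx, dtype=np.intp)
        return HaplotypeSet(
            chrom=self.chrom,
            positions=self.positions[variant_idx],
            ref=self.ref[variant_idx],
            alt=self.alt[variant_idx],
            haplotypes=self.haplotypes[:, variant_idx].copy(),
            sample_ids=list(self.sample_ids),
            ancestral=self.ancestral[variant_idx],
            missing=self.missing[:, variant_idx].copy(),
        )

    def drop_missing_variants(self) -> "HaplotypeSet":
        """Variants fully genotyped in every sample (pre-pass for haplotype stats)."""
        keep = ~self.missing.any(axis=0)
        return self.take_variants(np.flatnonzero(keep))


@dataclass
class PopulationMap:
    assignments: dict[str, str]            # sample -> population
    groups: dict[str, str] = field(default_factory=dict)  # population -> hot/cold/other

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignments.values():
            seen.setdefault(pop, None)
        return list(seen)

    def samples_for(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def group_of(self, population: str) -> str:
        return self.groups.get(population, "other")


class GeneticMap:
    """Piecewise-linear bp->cM map with constant-rate extrapolation.

    Without anchors for a chromosome the map falls back (if enabled) to a
    constant 1 cM/Mb, i.e. cM = bp * 1e-6.
    """

    DEFAULT_RATE_CM_PER_BP = 1e-6

    def __init__(self, anchors: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
                 allow_fallback: bool = True):
        self.anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.allow_fallback = allow_fallback
        for chrom, (bp, cm) in (anchors or {}).items():
            bp = np.asarray(bp, dtype=np.float64)
            cm = np.asarray(cm, dtype=np.float64)
            order = np.argsort(bp)
            bp, cm = bp[order], cm[order]
            if np.any(np.diff(cm) < 0):
                raise InputError(f"cM not non-decreasing in bp on {chrom}")
            self.anchors[chrom] = (bp, cm)

    def interpolate(self, chrom: str, bp) -> np.ndarray | float:
        """cM position(s) for bp coordinate(s) on ``chrom``."""
        bp_arr = np.asarray(bp, dtype=np.float64)
        if chrom not in self.anchors:
            if not self.allow_fallback:
                raise InputError(f"no genetic-map anchors for chromosome {chrom!r}")
            out = bp_arr * self.DEFAULT_RATE_CM_PER_BP
            return float(out) if np.isscalar(bp) else out
        xs, ys = self.anchors[chrom]
        if len(xs) < 2:
            if not self.allow_fallback:
                raise InputError(f"need >= 2 anchors on {chrom!r}")
            out = ys[0] + (bp_arr - xs[0]) * self.DEFAULT_RATE_CM_PER_BP
            return float(out) if np.isscalar(bp) else out
        out = np.interp(bp_arr, xs, ys)
        # constant-rate extrapolation: continue the terminal segment slopes
        lo_rate = (ys[1] - ys[0]) / (xs[1] - xs[0])
        hi_rate = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        below = bp_arr < xs[0]
        above = bp_arr > xs[-1]
        out = np.where(below, ys[0] + (bp_arr - xs[0]) * lo_rate, out)
        out = np.where(above, ys[-1] + (bp_arr - xs[-1]) * hi_rate, out)
        return float(out) if np.isscalar(bp) else out


def interpolate_cm(gmap: GeneticMap | None, chrom: str, bp):
    """Module-level convenience: ``gmap=None`` means the 1 cM/Mb default."""
    if gmap is None:
        gmap = GeneticMap()
    return gmap.interpolate(chrom, bp)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    gene_name: str
    chrom: str
    start: int   # 1-based inclusive
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 1 or self.start > self.end:
            raise InputError(
                f"gene {self.gene_id}: invalid interval {self.start}-{self.end}"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(path: str, region: str | None = None,
                    allow_unphased: bool = False) -> HaplotypeSet:
    """Read biallelic SNPs from a phased VCF into a :class:`HaplotypeSet`.

    Multiallelic and non-SNP records are dropped (logged counts).  Unphased
    genotypes are rejected unless ``allow_unphased`` is set.  Missing
    genotypes mark both haplotypes of the sample missing.  A per-variant
    ancestral flag is populated from the INFO ``AA`` tag when present.
    """
    from cyvcf2 import VCF

    chrom_filter = start = end = None
    if region:
        if ":" in region:
            chrom_filter, span = region.split(":", 1)
            lo, hi = span.split("-")
            start, end = int(lo), int(hi)
        else:
            chrom_filter = region

    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises plain OSError/Exception on bad input
        raise InputError(f"cannot open VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    n = len(samples)
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    ancestral: list[int] = []
    hap_cols: list[np.ndarray] = []
    miss_cols: list[np.ndarray] = []
    chrom = None
    n_dropped_nonbiallelic = 0

    for v in vcf:
        if chrom_filter is not None and v.CHROM != chrom_filter:
            continue
        pos = v.POS
        if start is not None and not (start <= pos <= end):
            continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1 \
                or v.REF.upper() not in _NUCLEOTIDES or v.ALT[0].upper() not in _NUCLEOTIDES:
            n_dropped_nonbiallelic += 1
            continue
        if chrom is None:
            chrom = v.CHROM
        elif v.CHROM != chrom:
            raise InputError(
                f"multiple chromosomes in input ({chrom!r}, {v.CHROM!r}); "
                "read one chromosome at a time via region="
            )
        gts = v.genotypes  # list of [a0, a1, phased]
        hap = np.zeros(2 * n, dtype=np.int8)
        mis = np.zeros(n, dtype=bool)
        for i, gt in enumerate(gts):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                mis[i] = True
                continue
            if not phased and not allow_unphased and a0 != a1:
                raise InputError(
                    f"unphased heterozygous genotype at {v.CHROM}:{pos} sample "
                    f"{samples[i]}; pass allow_unphased=True to accept"
                )
            hap[2 * i] = a0
            hap[2 * i + 1] = a1
        positions.append(pos)
        refs.append(v.REF.upper())
        alts.append(v.ALT[0].upper())
        aa = v.INFO.get("AA")
        if aa is None:
            ancestral.append(ANCESTRAL_UNKNOWN)
        else:
            aa = str(aa).upper()
            if aa == v.REF.upper():
                ancestral.append(REF_IS_ANCESTRAL)
            elif aa == v.ALT[0].upper():
                ancestral.append(ALT_IS_ANCESTRAL)
            else:
                ancestral.append(ANCESTRAL_UNKNOWN)
        hap_cols.append(hap)
        miss_cols.append(mis)

    if n_dropped_nonbiallelic:
        logger.info("dropped %d multiallelic/non-SNP records from %s",
                    n_dropped_nonbiallelic, path)
    if chrom is None:
        chrom = chrom_filter or "unknown"
    m = len(positions)
    return HaplotypeSet(
        chrom=chrom,
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype="U1"),
        alt=np.array(alts, dtype="U1"),
        haplotypes=(np.column_stack(hap_cols) if m else
                    np.zeros((2 * n, 0), dtype=np.int8)),
        sample_ids=samples,
        ancestral=np.array(ancestral, dtype=np.int8),
        missing=(np.column_stack(miss_cols) if m else
                 np.zeros((n, 0), dtype=bool)),
    )


def write_phased_vcf(h: HaplotypeSet, path: str) -> None:
    """Write a HaplotypeSet as a minimal phased VCF 4.2 text file."""
    anc_code = {REF_IS_ANCESTRAL: None, ALT_IS_ANCESTRAL: None, ANCESTRAL_UNKNOWN: None}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={h.chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(h.sample_ids) + "\n")
        for j in range(h.n_variants):
            if h.ancestral[j] == REF_IS_ANCESTRAL:
                info = f"AA={h.ref[j]}"
            elif h.ancestral[j] == ALT_IS_ANCESTRAL:
                info = f"AA={h.alt[j]}"
            else:
                info = "."
            gts = []
            for i in range(h.n_samples):
                if h.missing[i, j]:
                    gts.append(".|.")
                else:
                    gts.append(f"{h.haplotypes[2 * i, j]}|{h.haplotypes[2 * i + 1, j]}")
            fh.write(f"{h.chrom}\t{h.positions[j]}\t.\t{h.ref[j]}\t{h.alt[j]}"
                     f"\t.\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n")
    del anc_code


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

def read_population_map(path: str) -> PopulationMap:
    """Two/three-column whitespace-delimited: sample, population[, group]."""
    assignments: dict[str, str] = {}
    groups: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise InputError(f"{path}:{lineno}: expected 2 or 3 columns")
            sample, pop = parts[0], parts[1]
            if sample in assignments:
                raise InputError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignments[sample] = pop
            if len(parts) == 3:
                group = parts[2].lower()
                prev = groups.get(pop)
                if prev is not None and prev != group:
                    raise InputError(
                        f"{path}:{lineno}: conflicting group for population {pop!r}")
                groups[pop] = group
    return PopulationMap(assignments=assignments, groups=groups)


def write_population_map(popmap: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.assignments.items():
            group = popmap.groups.get(pop)
            if group:
                fh.write(f"{sample}\t{pop}\t{group}\n")
            else:
                fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

def read_plink_map(path: str) -> GeneticMap:
    """PLINK .map: chrom, id, cM, bp."""
    anchors: dict[str, tuple[list[float], list[float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 4:
                raise InputError(f"{path}:{lineno}: expected 4 columns")
            chrom, _snp_id, cm, bp = parts[0], parts[1], float(parts[2]), int(parts[3])
            anchors.setdefault(chrom, ([], []))
            anchors[chrom][0].append(float(bp))
            anchors[chrom][1].append(cm)
    return GeneticMap({c: (np.array(b), np.array(m)) for c, (b, m) in anchors.items()})


def write_plink_map(h: HaplotypeSet, path: str,
                    rate_cm_per_bp: float = 1e-6) -> None:
    with open(path, "w") as fh:
        for j, pos in enumerate(h.positions):
            fh.write(f"{h.chrom}\tsnp{j}\t{pos * rate_cm_per_bp:.8f}\t{pos}\n")


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

def bed_to_internal(start0: int, end0: int) -> tuple[int, int]:
    """BED 0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


def internal_to_bed(start1: int, end1: int) -> tuple[int, int]:
    return start1 - 1, end1


def read_gene_annotation(path: str, format: str = "bed") -> list[GeneModel]:
    """Load gene models from BED4+ or GFF3, normalized to 1-based inclusive."""
    if format == "bed":
        return _read_genes_bed(path)
    if format == "gff3":
        return _read_genes_gff3(path)
    raise InputError(f"unknown annotation format {format!r}")


def _read_genes_bed(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, s0, e0 = parts[0], int(parts[1]), int(parts[2])
            if s0 < 0 or e0 < s0:
                raise InputError(f"{path}:{lineno}: bad BED interval {s0}-{e0}")
            name = parts[3] if len(parts) > 3 else f"gene{lineno}"
            strand = parts[5] if len(parts) > 5 else "."
            start, end = bed_to_internal(s0, e0)
            genes.append(GeneModel(gene_id=name, gene_name=name, chrom=chrom,
                                   start=start, end=end, strand=strand))
    return genes


def _read_genes_gff3(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(path, ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        name = feat.attributes.get("Name", [gene_id])[0]
        genes.append(GeneModel(gene_id=gene_id, gene_name=name, chrom=feat.seqid,
                               start=feat.start, end=feat.end,
                               strand=feat.strand or "."))
    if not genes:
        logger.warning("no 'gene' features found in %s", path)
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tsweepscan\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id};Name={g.gene_name}\n")


def ensure_dir(path: str) -> None:
    os.makedirs(path, exist_ok=True)
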