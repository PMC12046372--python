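"""End-to-end orchestration of the scan on files, driven by a RunConfig.

Stage order: optional QC -> window grid -> Hp/ZHp per population -> FST/ZFST
and XP-EHH per contrast -> iHS per population -> outlier calling -> merging
-> context intersection -> gene annotation.  Haplotype statistics run on a
missing-free SNP subset; Hp and FST use locus-wise non-missing counts on the
full set.  Everything is deterministic given inputs and config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import yaml

from sweepscan import data_io, differentiation, haplotype_stats, pooled_het, qc
from sweepscan import sweep_calling, windows
from sweepscan.data_io import HaplotypeSet, PopulationMap

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    vcf: str
    popmap: str
    out_dir: str
    genetic_map: str | None = None
    genes: str | None = None
    genes_format: str = "gff3"
    chrom_length: int | None = None      # default: last SNP position
    window_size: int = 20_000
    step: int = 10_000
    min_snps: int = 20
    ehh_cutoff: float = 0.05
    ihs_bins: int = 50
    ihs_maf_min: float = 0.05
    ihs_window_mode: str = "abs"
    ancestral_mode: str = "ref"
    outlier_q: dict[str, float] = field(default_factory=lambda: {
        "ZHp": 0.001, "iHS_win": 0.001, "ZFST": 0.001, "XPEHH_win": 0.001})
    merge_gap: int = 0
    qc_enabled: bool = False
    qc_maf_min: float = 0.05
    qc_callrate_min: float = 0.95
    populations: list[str] | None = None
    contrasts: list[list[str]] | None = None   # [hot, cold] pairs; default all hot x cold
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dict(self.__dict__)
        return d


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _resolve_contrasts(cfg: RunConfig, popmap: PopulationMap,
                       pops: list[str]) -> list[tuple[str, str]]:
    if cfg.contrasts:
        out = []
        for pair in cfg.contrasts:
            if len(pair) != 2:
                raise ValueError(f"contrast {pair!r} must have exactly two populations")
            for p in pair:
                if p not in pops:
                    raise ValueError(f"contrast references undeclared population {p!r}")
            out.append((pair[0], pair[1]))
        return out
    hot = [p for p in pops if popmap.group_of(p) == "hot"]
    cold = [p for p in pops if popmap.group_of(p) == "cold"]
    return [(a, b) for a in hot for b in cold]


def run_full_scan(cfg: RunConfig) -> dict[str, Any]:
    """Execute the whole scan; returns (and writes) the run manifest."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    data_io.ensure_dir(cfg.out_dir)

    popmap = data_io.read_population_map(cfg.popmap)
    pops = cfg.populations or popmap.populations
    for p in pops:
        if not popmap.samples_for(p):
            raise ValueError(f"population {p!r} has no samples")
    contrasts = _resolve_contrasts(cfg, popmap, pops)  # validate before any compute

    h = data_io.read_phased_vcf(cfg.vcf)
    gmap = data_io.read_plink_map(cfg.genetic_map) if cfg.genetic_map else None
    genes = (data_io.read_gene_annotation(cfg.genes, cfg.genes_format)
             if cfg.genes else None)

    manifest: dict[str, Any] = {"config": cfg.to_dict(), "stages": {},
                                "files": {}, "window_counts": {},
                                "region_counts": {}}

    if cfg.qc_enabled:
        h, report = qc.filter_variants(h, qc.QcConfig(
            maf_min=cfg.qc_maf_min, callrate_min=cfg.qc_callrate_min))
        manifest["stages"]["qc"] = report.to_dict()

    chrom_length = cfg.chrom_length or (int(h.positions[-1]) if h.n_variants else 0)
    grid = windows.build_window_grid(chrom_length, cfg.window_size, cfg.step,
                                     chrom=h.chrom, min_snps=cfg.min_snps)
    windows.assign_snps(grid, h)
    manifest["stages"]["windows"] = {"n_windows": grid.n_windows,
                                     "n_scored": grid.n_scored}

    # missing-free subset for haplotype statistics; its own grid assignment
    hm = h.drop_missing_variants()
    grid_hm = windows.build_window_grid(chrom_length, cfg.window_size, cfg.step,
                                        chrom=h.chrom, min_snps=cfg.min_snps)
    windows.assign_snps(grid_hm, hm)

    def _write_track(track, stem):
        path = os.path.join(cfg.out_dir, stem + ".tsv")
        track.write_tsv(path)
        manifest["files"][stem] = path
        manifest["window_counts"][stem] = int(track.defined.sum())
        return path

    all_regionsets: dict[str, list] = {}
    within_sets, between_sets = [], []

    # --- per-population: Hp/ZHp and iHS --------------------------------
    for pop in pops:
        samples = popmap.samples_for(pop)
        hp = pooled_het.window_hp(h, samples, grid, population=pop)
        zhp = pooled_het.z_standardize(hp)
        _write_track(hp, f"Hp.{pop}")
        _write_track(zhp, f"ZHp.{pop}")

        scores = haplotype_stats.ihs_scan(
            hm, samples, gmap, maf_min=cfg.ihs_maf_min, cutoff=cfg.ehh_cutoff,
            n_bins=cfg.ihs_bins, ancestral_mode=cfg.ancestral_mode)
        ihs_win = haplotype_stats.window_mean_scores(
            scores, grid_hm, mode=cfg.ihs_window_mode,
            statistic="iHS_win", context=pop)
        _write_track(ihs_win, f"iHS_win.{pop}")
        haplotype_stats.scores_to_frame(scores, hm.chrom).to_csv(
            os.path.join(cfg.out_dir, f"iHS_snp.{pop}.tsv"), sep="\t", index=False)

        for track, method, tail in ((zhp, "ZHp", "low"), (ihs_win, "iHS_win", "high")):
            if not track.defined.any():
                logger.warning("%s/%s: no defined windows, skipping outliers",
                               method, pop)
                continue
            rule = sweep_calling.OutlierRule(method=method, tail=tail,
                                             q=cfg.outlier_q.get(method, 0.001))
            outliers = sweep_calling.call_outlier_windows(track, rule)
            regions = sweep_calling.merge_regions(outliers, cfg.merge_gap,
                                                  method=method, tail=tail,
                                                  context=pop)
            all_regionsets[f"{method}.{pop}"] = regions
            within_sets.append(regions)
            manifest["region_counts"][f"{method}.{pop}"] = len(regions)

    # --- per-contrast: FST/ZFST and XP-EHH -----------------------------
    for pop_a, pop_b in contrasts:
        label = f"{pop_a}_vs_{pop_b}"
        comp = differentiation.wc_fst_components(
            h, popmap.samples_for(pop_a), popmap.samples_for(pop_b))
        fst = differentiation.windowed_fst(comp, grid, context=(pop_a, pop_b))
        zfst = pooled_het.z_standardize(fst)
        _write_track(fst, f"FST.{label}")
        _write_track(zfst, f"ZFST.{label}")

        hA = hm.subset_samples(popmap.samples_for(pop_a))
        hB = hm.subset_samples(popmap.samples_for(pop_b))
        xp_scores = haplotype_stats.xpehh_scan(hA, hB, gmap, cutoff=cfg.ehh_cutoff)
        xp_win = haplotype_stats.window_mean_scores(
            xp_scores, grid_hm, mode="abs", statistic="XPEHH_win",
            context=(pop_a, pop_b))
        _write_track(xp_win, f"XPEHH_win.{label}")

        for track, method in ((zfst, "ZFST"), (xp_win, "XPEHH_win")):
            if not track.defined.any():
                logger.warning("%s/%s: no defined windows, skipping outliers",
                               method, label)
                continue
            rule = sweep_calling.OutlierRule(method=method, tail="high",
                                             q=cfg.outlier_q.get(method, 0.001))
            outliers = sweep_calling.call_outlier_windows(track, rule)
            regions = sweep_calling.merge_regions(outliers, cfg.merge_gap,
                                                  method=method, tail="high",
                                                  context=(pop_a, pop_b))
            all_regionsets[f"{method}.{label}"] = regions
            between_sets.append(regions)
            manifest["region_counts"][f"{method}.{label}"] = len(regions)

    # --- consolidation and support ------------------------------------
    all_regions = [r for rs in all_regionsets.values() for r in rs]
    tbl = sweep_calling.regions_to_table(all_regions)
    regions_path = os.path.join(cfg.out_dir, "candidate_regions.tsv")
    tbl.to_csv(regions_path, sep="\t", index=False)
    manifest["files"]["candidate_regions"] = regions_path
    bed_path = os.path.join(cfg.out_dir, "candidate_regions.bed")
    sweep_calling.regions_to_bed(all_regions).to_csv(
        bed_path, sep="\t", index=False, header=False)
    manifest["files"]["candidate_regions_bed"] = bed_path

    support_path = os.path.join(cfg.out_dir, "support.tsv")
    for name, sets in (("within", within_sets), ("between", between_sets)):
        nonempty = [s for s in sets if s]
        if nonempty:
            union = sweep_calling.intersect_contexts(nonempty, mode="union")
            manifest["region_counts"][f"{name}_union"] = len(union)
    nonempty_all = [s for s in all_regionsets.values() if s]
    if nonempty_all:
        union_all = sweep_calling.intersect_contexts(nonempty_all, mode="union")
        rows = []
        for r in union_all:
            rows.append({"chrom": r.chrom, "start": r.start, "end": r.end,
                         "n_support": len(r.support),
                         "support": ";".join(f"{m}:{c}" for m, c in r.support)})
        import pandas as pd
        pd.DataFrame(rows).to_csv(support_path, sep="\t", index=False)
        manifest["files"]["support"] = support_path

    if genes is not None and all_regions:
        ann = sweep_calling.annotate_genes(all_regions, genes)
        ann_path = os.path.join(cfg.out_dir, "region_genes.tsv")
        ann.to_csv(ann_path, sep="\t", index=False)
        manifest["files"]["region_genes"] = ann_path

    manifest["hashes"] = {k: _sha256(v) for k, v in manifest["files"].items()}
    manifest_path = os.path.join(cfg.out_dir, "run_manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    logger.info("run complete: %d output files", len(manifest["files"]))
    return manifest


def plot_track(track, path: str, title: str | None = None) -> None:
    """Manhattan-style per-window plot of a score track."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    mid = (track.grid.starts + track.grid.ends) / 2
    ax.scatter(mid[track.defined] / 1e6, track.values[track.defined], s=4)
    ax.set_xlabel(f"position on {track.grid.chrom} (Mb)")
    ax.set_ylabel(track.statistic)
    ax.set_title(title or f"{track.statistic} {track.context}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
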