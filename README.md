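# sweepscan

Selection-signature scanning on phased haplotype data. The package computes
four genome-scan statistics on a shared sliding-window grid, standardizes
them, calls extreme-percentile outlier windows, consolidates them into
candidate regions, and annotates overlapping genes:

- **Hp / ZHp** — windowed pooled heterozygosity per population
  (`2·Σn_maj·Σn_min / (Σn_maj + Σn_min)²`), z-standardized genome-wide.
- **iHS** — per-SNP `ln(iHH_ancestral / iHH_derived)` from EHH decay curves,
  standardized within derived-allele-frequency bins, averaged (|z|) per window.
- **XP-EHH** — per-SNP `ln(iHH_A / iHH_B)` over all haplotypes of two
  populations with a shared decay boundary, standardized genome-wide,
  averaged (|z|) per window.
- **FST / ZFST** — Weir–Cockerham (1984) two-population variance components
  per SNP, windowed as the weighted ratio-of-sums `Σa / Σ(a+b+c)`.

A seeded forward Wright–Fisher simulator (island model, infinite-sites
mutation, Poisson recombination, optional deme-local hard sweep) generates
phased multi-population datasets with a known injected sweep, so the whole
pipeline is testable offline end to end.

Defaults follow common practice for this kind of scan: 20-kb windows with a
10-kb step and ≥20 SNPs per scored window; EHH decay cutoff 0.05; core MAF
0.05; 50 frequency bins; outlier tail fraction q = 0.001; book-ended interval
merging. All are configurable. Note the ancestral-allele convention for iHS
defaults to REF-as-ancestral and flips iHS signs if wrong for your data
(`--ancestral major|flag` are available).

## Inputs

- phased multi-sample VCF 4.x (GT with `|`; biallelic SNPs are admitted,
  multiallelic/non-SNP records dropped with a logged count); one chromosome
  at a time
- population map: `sample population [hot|cold|other]`, whitespace-delimited
- optional PLINK-style genetic map (`chrom id cM bp`); without one, a
  constant 1 cM/Mb is assumed
- gene annotation as BED4+ or GFF3 (internal coordinates are 1-based
  inclusive; BED converts at the boundary)

## CLI

```bash
# synthetic data with an injected sweep
sweepscan simulate --config sim.yaml --seed 1 --out-dir data/ --gene-density 10

# individual stages
sweepscan qc     --vcf in.vcf --maf 0.05 --callrate 0.95 --out qc.vcf --report qc.json
sweepscan hp     --vcf in.vcf --popmap pops.txt --pop deme0 --out hp.tsv
sweepscan ihs    --vcf in.vcf --popmap pops.txt --pop deme0 --out ihs.tsv
sweepscan xpehh  --vcf in.vcf --popmap pops.txt --pop-a deme0 --pop-b deme1 --out xp.tsv
sweepscan fst    --vcf in.vcf --popmap pops.txt --pop-a deme0 --pop-b deme1 --out fst.tsv
sweepscan call   --track zhp.tsv --tail low --q 0.001 --merge-gap 0 --out regions.tsv
sweepscan annotate --regions regions.tsv --genes genes.gff3 --out region_genes.tsv

# full scan from a YAML config (see RunConfig fields in sweepscan/pipeline.py)
sweepscan run-all --config run.yaml
sweepscan report --out-dir out/   # Manhattan-style plots per track
```

A minimal `run.yaml`:

```yaml
vcf: data/sim.vcf
popmap: data/sim.popmap.txt
out_dir: out
chrom_length: 200000
# contrasts default to every hot x cold population pair from the popmap
```

`run-all` writes per-window tracks (TSV), per-SNP score tables, candidate
regions (TSV + BED), a support table across methods/contrasts, gene
overlaps, and a `run_manifest.json` with scored-window counts, region
counts, and SHA-256 hashes of every output (runs are deterministic given
config + seed).

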