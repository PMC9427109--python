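# sgscan

Arrangement-aware population genomics for a balanced supergene
polymorphism. The package analyses a two-arrangement system (a standard
and a rearranged chromosome held at intermediate frequency by
disassortative mating between heterokaryotypes and standard
homokaryotypes): it identifies arrangement-diagnostic fixed differences
from morph-labelled genotypes, assigns sequence fragments to their
chromosome of origin, builds arrangement-resolved pseudo-haplotypes,
computes coverage-corrected windowed diversity and divergence statistics,
scans for selective sweeps and balancing selection with empirical-p
calibration, detects high-diversity outlier regions and haplogroups inside
the rearrangement, and integrates allele-specific expression with the
selection scans. A forward Wright–Fisher simulator of the whole system is
included so that every stage is testable end to end without external data.

## Modules

| module | contents |
|---|---|
| `sgscan.io_core` | genotype matrix, sample metadata, accessibility masks (BED), windows, VCF/GFF3/FASTA/TSV readers and writers |
| `sgscan.simulate` | forward simulator (disassortative mating, suppressed recombination in heterokaryotypes, sweeps, NFDS-balanced haplogroup backbones) and emitters for VCF, fragments, annotation and allele-resolved expression |
| `sgscan.phasing` | fixed-difference calling, pattern null probability, fragment-to-arrangement assignment, pseudo-haplotype construction |
| `sgscan.popgen` | π, d_XY, fixed-difference density, F_ST (Hudson; Weir–Cockerham behind a flag), Tajima's D, folded SFS, Nei–Gojobori π_N/π_S, LD decay, effective-size ratio with block bootstrap |
| `sgscan.scan` | pairwise-homozygosity-tract H statistic, per-window maxima, SNP-binned empirical p-values, kernel balancing statistic, windowed ABBA–BABA D |
| `sgscan.regions` | outlier-region detection with circular-rotation permutation test, haplogroup clustering, haplogroup d_XY tracks, genotype-plot matrices, allelic-bias tests, bias–H association, morph-bias enrichment |
| `sgscan.scenarios` | canonical desk-scale simulation presets used by tests and docs |

## CLI

`sgscan` exposes one subcommand per stage; all accept `--seed`,
`--config` (YAML) and `--log-level`:

```bash
sgscan simulate --config sim.yaml --out fixtures/          # full fixture bundle
sgscan fixdiff  --vcf sim.vcf --meta samples.tsv --out-vcf fd.vcf
sgscan phase    --vcf sim.vcf --meta samples.tsv --fragments frags.tsv \
                --region 100000-500000 --out haps.tsv
sgscan stats    --haplotypes haps.tsv --contig-length 600000 \
                --windows 10000,25000,50000 --out-prefix stats
sgscan scan     --haplotypes haps.tsv --contig-length 600000 \
                --window 25000 --out-prefix scan
sgscan regions  --stats stats.win10000.tsv --haplotypes haps.tsv \
                --out-prefix regions
sgscan ase      --expression expr.tsv --hscan scan.hscan.tsv \
                --genes genes.tsv --out-prefix ase
```

## Conventions

VCF positions are 1-based; all internal intervals (masks, windows, CDS and
rearrangement spans) are 0-based half-open. Genotypes and haplotype
alleles are coded 0/1 with −1 for missing. Window statistics divide by the
accessible length of each window (breadth-of-coverage correction), never
by the raw span.
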