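# genodiag

Diagnostics and population-genomic analyses for short-read cohorts mapped to
a custom assembly, built around five stages plus a seeded synthetic-data
generator so every stage has a ground-truth recovery test without any
external downloads:

- **phasing diagnostics** — per-window counts of trio-binning read tags
  (paternal / maternal / unassigned), window binnability, the parental bias
  ratio (`max/min`, with an infinite sentinel when one class is absent),
  and the count of windows biased beyond a fold threshold;
- **variant post-filtering** — per-sample genotype masking outside a
  coverage band (`(mean/3, 2.5×mean)`, strict), removal of SNPs/indels
  within 5 bp of an indel (evaluated against the pre-filter record set),
  site-quality and allele-count filters, bi-allelic autosomal SNP selection;
- **heterozygosity / ROH / F_ROH** — callable-base masks from dense depth
  tracks, coverage-corrected heterozygosity in tumbling windows (windows
  under 60 % callable are excluded), ROH calling on 10-kb windows with a
  relaxed-peak rule (low-het seed runs greedily merged across heterozygosity
  peaks while the callable-weighted mean of the merged span stays below
  0.25× the genome mean), and the genomic inbreeding coefficient
  F_ROH = Σ len(ROH ≥ 100 kb) / autosomal genome length;
- **SV presence/absence analytics** — presence matrices from a
  multi-assembly pangenome-deconstruction VCF, exact UpSet-style pattern
  counts, private-SV hotspot scans (fold enrichment over the genome-wide
  private rate), pairwise distances as the reciprocal of shared SV counts,
  and UPGMA clustering with Newick output;
- **deletion genotyping** — per-base depth over a scan window normalized by
  the mean outside an exclusion window, genotype classes from the mean
  normalized coverage over the event span (< 0.25 hom, ≤ 0.75 het,
  else absent; samples under 5× are low-confidence), and per-population
  summaries with normal-approximation 95 % CIs.

## CLI

One executable with a subcommand per stage; `--config` takes a YAML file
overriding any `PipelineParams` default, `--seed` fixes all randomness:

```sh
genodiag --seed 42 simulate --out data/            # synthetic dataset + truth
genodiag phase-diag --tags data/tags.tsv --layout data/layout.tsv --out-prefix out/pd
genodiag filter-vcf --vcf data/variants.vcf --layout data/layout.tsv \
    --mean-coverage 30 --out out/filtered.vcf --report out/report.json
genodiag het-windows --vcf data/variants.vcf --depth data/depth.tsv \
    --layout data/layout.tsv --out out/het.tsv
genodiag roh  --vcf data/variants.vcf --depth data/depth.tsv \
    --layout data/layout.tsv --out-prefix out/roh
genodiag froh --roh-bed out/roh.roh.bed --autosome-length 2682350267
genodiag sv-upset --sv-vcf data/sv.vcf --out out/upset.tsv
genodiag sv-tree  --sv-vcf data/sv.vcf --out-newick out/tree.nwk
genodiag del-genotype --samples samples.tsv --locus locus.yaml --out-prefix out/del
```

Input formats: layout TSV (`name  length  autosome-flag`), dense
`samtools depth -aa`-style depth TSV, 3-column tagged-read TSV, VCF for
small variants (GT + DP) and SV deconstructions (one genotype column per
assembly), YAML for configuration and locus specs.  All in-memory
coordinates are 1-based inclusive; BED output is 0-based half-open.

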