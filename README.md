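# somavar

Somatic-variant discovery from paired tumor/normal RNA-seq-derived
callsets: a six-stage filter cascade, mutation-spectrum and Ti/Tv
characterization, coding-consequence classification with cross-sample
recurrence, and GO-term enrichment — plus a fully self-contained
synthetic-data generator with ground-truth labels for validation.

## The filter cascade

Per sample, in fixed order:

1. **min_quality** — drop calls with QUAL < 20.
2. **max_coverage** — drop calls above a per-sample depth cutoff trained
   as the 0.975 nearest-rank quantile of depths at known-database calls
   (removes PCR-duplicate-inflated sites).
3. **covered_in_both** — drop calls at positions covered in only one
   sample of the pair.
4. **known_db** — drop calls present in the known-variant database
   (allele-aware exact match on chrom/pos/ref/alt; positional matching
   available via config).
5. **shared_calls** — drop calls found in both members of the pair,
   leaving tissue-specific variants.
6. **local_mismatch** — drop calls with ≥ 2 other called variant sites
   (or a site rate ≥ 0.1) within ±10 bp, a proxy for indel-adjacent
   misalignment.

Every stage's in/out counts and the trained cutoffs are recorded in a
`FilterReport` TSV.

## CLI

```bash
# generate a synthetic paired dataset (VCFs, coverage TSVs, known DB,
# genome FASTA + GTF, ground-truth table)
somavar simulate --out sim/ --seed 1

# run the cascade on a pair
somavar filter --tumor-vcf sim/tumor.vcf --normal-vcf sim/normal.vcf \
    --tumor-cov sim/tumor.cov.tsv --normal-cov sim/normal.cov.tsv \
    --known-db sim/known.tsv --out-dir filtered/

# mutation spectrum / consequences / enrichment
somavar spectrum filtered/tumor_specific.vcf --out spectrum.tsv
somavar consequence filtered/tumor_specific.vcf \
    --gtf sim/genes.gtf --fasta sim/genome.fa \
    --out consequence.tsv --recurrence-out recurrence.tsv
somavar enrich --study genes.txt --out enrichment.tsv   # bundled mini-GO

# everything at once (simulates first when no --config is given)
somavar run-all --out run1/ --seed 1
```

`run-all` writes `filter_report.tsv`, `spectrum.tsv`,
`spectrum_stats.tsv`, `consequence.tsv`, `recurrence.tsv`,
`enrichment.tsv` and a `manifest.json` (config hash, version, seed);
reruns with the same seed/config are byte-identical.

## Layout

| module | contents |
| --- | --- |
| `somavar.variant_io` | VCF/coverage/known-DB readers & writers, core types |
| `somavar.filter_cascade` | the six filters, cutoff training, orchestration |
| `somavar.spectrum_stats` | spectrum classes, Ti/Tv, Fisher exact, rank-sum |
| `somavar.consequence` | gene models, codon-level consequence calls, recurrence |
| `somavar.go_enrichment` | OBO DAG, true-path propagation, hypergeometric test, BH |
| `somavar.synthetic_data` | deterministic paired-callset simulator + truth labels |
| `somavar.pipeline` / `somavar.cli` | end-to-end runner and `somavar` CLI |
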