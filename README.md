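# sensikit

Analysis toolkit for pooled shRNA drug-sensitizer screens combined with
triplex-labeled (phospho)proteomics, plus the supporting utilities such a
study needs end to end:

- **Synthetic data** (`sensikit.simulate`) — pooled-screen count matrices and
  indexed amplicon reads, triplex protein/phosphosite ratio tables and 4PL
  viability curves, all with planted, recoverable ground truth and
  bit-reproducible seeding.
- **Quantification** (`sensikit.quant`) — demultiplexing of 6-bp-indexed
  amplicon FASTQ reads and hairpin counting against a 21-nt library
  (0 or 1 mismatches, fixed offset or scan mode), with strict count/library/
  sample-sheet table types and TSV I/O.
- **Screen statistics** (`sensikit.screenstats`) — median-of-ratios size
  factors, method-of-moments NB dispersions with an a0 + a1/µ trend and
  conservative sharing, and a two-sided exact negative-binomial test
  conditioned on the pooled count (DESeq-v1 style).
- **Hit calling** (`sensikit.hits`) — the two-timepoint filter cascade
  (day-7 FC ≤ 0.66 and p < 0.05, day-4 FC < 1), dual-screen intersection,
  ≥ 2-hairpins-in-both-screens gene calls, and evidence integration with
  proteomic regulator directions.
- **Proteomics** (`sensikit.proteomics`) — one-/two-sample t-tests on
  replicate log2 ratios (M/L, H/L, H/M channels), |FC| ≥ 1.5 + p < 0.05
  regulation filters, volcano-ready tables, phosphosite localization
  filtering at probability ≥ 0.75, and a configurable table dialect for
  MaxQuant-proteinGroups-like exports.
- **Enrichment** (`sensikit.enrich`) — upper-tail hypergeometric
  over-representation with Benjamini–Hochberg adjustment.
- **Dose response** (`sensikit.doseresponse`) — control-anchored viability
  normalization and multi-start 4PL fitting with analytic ICx (IC20 = dose at
  80% residual viability).
- **Pipeline** (`sensikit.pipeline`, `sensikit.cli`) — orchestration behind a
  YAML config with a checksummed run manifest; every intermediate is plain TSV.

## CLI

All stages are exposed under one entry point:

```sh
sensikit simulate-screen --config screen.yaml --seed 1 --out-dir sim/ --reads
sensikit count --fastq sim/reads.fastq.gz --library sim/library.tsv \
    --samples sim/samples.tsv --max-mismatch 0 --out counts.tsv
sensikit screen-test --counts counts.tsv --samples sim/samples.tsv \
    --library sim/library.tsv --contrast treated_vs_dmso_day7:PLX --out plx_d7.tsv
sensikit call-hits --plx-day7 plx_d7.tsv --plx-day4 plx_d4.tsv \
    --sch-day7 sch_d7.tsv --sch-day4 sch_d4.tsv \
    --library sim/library.tsv --out hits.tsv
sensikit simulate-proteome --out-dir prot/
sensikit proteome-diff --table prot/proteins.tsv --phospho prot/phosphosites.tsv \
    --out-dir prot_results/
sensikit enrich --target target.txt --background background.txt \
    --terms terms.tsv --out enrichment.tsv
sensikit viability --plate plate.csv --out fit.tsv
sensikit run-all --config run.yaml
```

Read layout for simulated/quantified amplicons is fixed: bases 1–6 sample
index, bases 7–27 hairpin sense sequence, remainder constant.

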