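# ctdna-concord

Tissue–plasma ctDNA concordance evaluation, somatic-variant filtering, and
allele-aware cfDNA fragment-size (insert-size) analysis, with a seeded
synthetic-data generator so every stage runs end-to-end offline.

## Components

| Module | What it does |
| --- | --- |
| `ctdna_concord.simulate` | Seeded synthetic inputs: proper-pair alignments around a variant locus with allele-specific fragment-size distributions, annotated variant tables with exact per-criterion strata, paired tissue/plasma cohorts with a known detection probability. |
| `ctdna_concord.filtering` | Six-criterion somatic filter cascade (sample-type VAF threshold, caller hard-filter status, panel-of-normals flag, population frequency, ClinVar significance/origin, noncoding removal with splice/promoter exceptions), with first-failing-criterion accounting. |
| `ctdna_concord.concordance` | Mutation-level tumor-mutation detection rates with Wilson score CIs, patient-level per-gene positive rates, reference-material VAF panel evaluation, expected-VAF mixing arithmetic. |
| `ctdna_concord.fragmentomics` | Positional CIGAR-based mutant/non-mutant read-pair classification (SNVs and indels), per-fragment insert sizes from TLEN, sub-threshold fractions, mono-/di-nucleosome window summaries (50–220 / 221–400 bp), one-sided rank-sum shift test. |
| `ctdna_concord.fixtures` | Packaged cohort summary tables (reference panel, matched tissue/plasma calls, per-patient counts, actionable genes). |
| `ctdna_concord.cli` / `pipeline` / `config` | `ctdna-concord` CLI, strict YAML configuration, end-to-end orchestration with a JSON manifest. |

## CLI

```bash
ctdna-concord --version
ctdna-concord simulate reads    --seed 1 --out out/            # SAM + FASTA + truth table
ctdna-concord simulate variants --seed 1 --out out/ --stratum pass_all=10 --stratum fail_vaf=3
ctdna-concord simulate cohort   --seed 1 --out out/
ctdna-concord filter  --input out/variants.tsv --report filter.json --out filtered.tsv
ctdna-concord concord --tissue tissue_calls.tsv --plasma plasma_calls.tsv --key coordinate --out concord.json
ctdna-concord refeval --arm liquid_liquid --out refeval.json   # packaged reference panel
ctdna-concord fragsize --alignments out/reads.sam --variants loci.tsv --out frag/
ctdna-concord run --config config.yaml                         # full pipeline + manifest
```

A pipeline YAML may set `seed`, `out_dir`, `stages`, and `simulate` /
`cohort` / `filter` / `fragmentomics` / `reporting` blocks; unknown keys are
rejected before any stage runs. Example:

```yaml
seed: 5
out_dir: out
simulate:
  n_fragments: 2000
  mutant_fraction: 0.1
  variant: {chrom: chrS, pos: 2000, ref_allele: C, alt_allele: T}
cohort: {n_patients: 16, mutations_per_patient: 22, plasma_detection_prob: 0.734}
```

## Variant-table dialect

`filter` consumes tab-separated tables with logical columns `patient_id`,
`sample_type` (tissue|plasma), `chrom`, `start`, `end`, `ref_allele`,
`alt_allele`, `gene`, `variant_classification`, `hgvs_c`, `tumor_vaf`,
`filter_status`, `pon_flag`, `gnomad_exome_af`, `gnomad_genome_af`,
`clinvar_significance`, `clinvar_origin` (MAF-style 1-based inclusive
coordinates; empty cells are "missing", never zero). A column-name mapping
can be supplied programmatically via `read_variant_table(path, column_map=...)`.

## Notes

- Reported percentages use round-half-away-from-zero (81.25 → 81.3).
- The Wilson score interval is the default CI (it reproduces the reference
  bounds for 262/357 to 4 decimals; Wald and Clopper–Pearson are available).
- HGVS matching is exact string equality on `gene` + `hgvs_c`; no HGVS
  normalization is attempted. Coordinate-mode matching uses
  `(chrom, start, ref, alt)`.
- Fragments (read pairs / templates) are the counting unit everywhere in the
  fragment-size analysis; one |TLEN| per pair.
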