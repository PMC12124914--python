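# cfdeconv

Fragment-level cell-free DNA (cfDNA) methylation deconvolution. The package
takes Bismark-style bisulfite sequencing outputs, builds one record per cfDNA
fragment carrying the joint methylation state of all its CpGs, models marker
regions as per-class Beta(α, β) distributions, and infers

* the **tumor-derived cfDNA fraction** θ via a two-class fragment-likelihood
  mixture MLE (`cancer-detector`), and
* **multi-tissue cfDNA composition** with an explicit *unknown* class for
  ambiguous fragments (`cf-deconvolve`), assigned by a fold-change rule on the
  top-two class likelihoods.

The per-fragment class likelihood is the closed-form beta-Bernoulli marginal
`B(α + k, β + n − k) / B(α, β)` for a fragment with `k` methylated out of `n`
CpGs, computed in log space.

## Layout

| Module | Purpose |
| --- | --- |
| `cfdeconv.ingest` | BED6 read intervals + CpG_OT/CpG_OB call files → fragment-level methylation table (`merge_pe_reads` → `merge_cpgs` → `generate_frag_meth`) |
| `cfdeconv.markers` | Beta-shape fitting (method of moments, MLE behind a flag), the tab-delimited `α:β` marker file dialect, fragment–marker intersection |
| `cfdeconv.deconvolve` | Fragment likelihoods, tumor-burden grid MLE, N-class assignment with unknown class, reports and pie chart |
| `cfdeconv.simulate` | Ground-truthed synthetic datasets: fragment populations from known mixtures, reference beta-value matrices, round-trippable Bismark-dialect files |
| `cfdeconv.cli` | `cfdeconv` entry point with one subcommand per stage plus `demo`; every run writes a JSON manifest |

## CLI

```bash
# end-to-end demo on synthetic data (fraction table + pie chart + tumor burden)
cfdeconv demo --outdir out/ --seed 7

# generate a ground-truthed synthetic dataset from a key=value config
cfdeconv simulate --config sim.cfg --outdir sim/

# ingestion: BED + Bismark call files -> fragment table
cfdeconv frag-meth --input reads.bed --calls-ot CpG_OT.txt --calls-ob CpG_OB.txt \
    --output fragments.tsv

# fit per-marker per-class Beta(α, β) shapes from a reference beta-value matrix
cfdeconv marker-params --beta-matrix betas.tsv --sample-classes classes.tsv \
    --output markers.tsv

# tumor burden (two-class mixture MLE over a theta grid)
cfdeconv cancer-detector --fragments fragments.tsv --markers markers.tsv \
    --output burden.tsv

# multi-tissue fractions with an unknown class (fold-change threshold 2)
cfdeconv cf-deconvolve --fragments fragments.tsv --markers markers.tsv \
    --fold-change 2 --output fractions.tsv --pie fractions.png
```

All tabular outputs are UTF-8 TSV with a single `#`-prefixed header line.
Fraction tables always include the `unknown` component and sum to 1.

### File dialects

* **Fragment table** — `chrom start end length n_cpg methState cpgPositions
  fragmentId`; `methState` uses `1` = methylated, `0` = unmethylated. The last
  two columns make the table a lossless fragment serialization; 6-column
  foreign tables are accepted on read.
* **Marker file** — `chrom start end marker_id` then one `α:β` column per
  class, class names in the header; classes are matched by name.
* **Simulation config** — `key = value` lines; see
  `cfdeconv.simulate.parse_config` for the schema.

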