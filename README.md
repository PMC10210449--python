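# scsexbias

Decompose sex-biased gene expression measured by single-cell RNA-seq into an
**abundance-driven** component (the sexes differ in cell-type composition, so
tissue-level averages shift even without any within-cell regulation) and a
**regulatory** component (genes differentially expressed within a cell type).
The package also computes group-level coding-sequence divergence statistics
(aggregated dN, dS and dN/dS with bootstrap confidence intervals and
permutation contrasts) for the resulting gene categories.

Everything runs end-to-end on synthetic data with known ground truth, so the
whole pipeline is testable without any external downloads.

## What it does

1. **simulate** — generate gene-by-cell NB counts for a two-sex,
   multi-replicate, multi-cell-type tissue with configurable sex differences
   in cell-type proportions, within-type regulatory fold changes, lognormal
   library sizes and optional dropout; analytic truth (mixture-mean bulk
   log2 fold changes, regulatory/abundance-driven gene sets) comes along.
2. **qc** — read/write 10x-style MTX triplet directories or dense TSVs;
   filter genes detected in < 3 cells and cells with < 100 detected genes;
   report per-group Pearson correlation between per-cell depth and detected
   genes.
3. **abundance** — pooled two-proportion tests (Yates-corrected by default)
   per cell type with a pseudocounted (1e-10) log2 proportion ratio,
   called at p < 0.01.
4. **de** — pseudobulk aggregation of raw counts to the sample level (whole
   tissue and per cell type), median-of-ratios size factors, per-gene
   negative-binomial Wald tests (Cox–Reid adjusted profile-likelihood
   dispersion), BH correction; sex-biased at |log2FC| >= 1 and FDR < 0.05.
5. **classify** — combine bulk and per-cell-type calls into
   `bulk_only` / `bulk_and_cell` / `cell_only` / `unbiased` categories with
   direction and summary tables.
6. **divergence** — aggregated d_N = sum(DN)/sum(N), d_S = sum(DS)/sum(S) and
   omega per category after a dS > 2 saturation filter, with 1,000-replicate
   percentile bootstrap CIs, 1,000-replicate permutation contrasts and a
   compact-letter display.

## CLI

```bash
# one-command synthetic demonstration (all six stages)
scsexbias run --demo --outdir results/demo --seed 1
scsexbias report --artifact-dir results/demo

# individual stages
scsexbias simulate --outdir sim --seed 1 --n-genes 300
scsexbias qc --counts sim/counts --metadata sim/metadata.tsv --outdir qc
scsexbias abundance --metadata sim/metadata.tsv --out abundance.tsv
scsexbias de --counts sim/counts --metadata sim/metadata.tsv --outdir de --stratum all
scsexbias classify --bulk de/de_bulk.tsv --cell type0 de/de_type0.tsv --out categories.tsv
scsexbias divergence --records div.tsv --categories categories.tsv --out groups.tsv
```

A full run can also be driven by a flat YAML config
(`scsexbias run --config cfg.yaml`); every threshold used is echoed into
`manifest.json` together with sha256 hashes of all artifacts, and a repeat
run with the same config reproduces identical hashes.

## Library use

```python
import scsexbias as s

cfg = s.SimConfig(n_genes=500, n_cell_types=3, cells_per_sample=800,
                  regulatory_fraction=0.1, regulatory_lfc=3.0, seed=7)
counts, meta, truth = s.simulate_counts(cfg)
pb = s.aggregate(counts, meta)               # whole-tissue pseudobulk
de = s.nb_de_test(pb)                        # NB Wald test, BH, calls
ab = s.test_abundance(meta)                  # per-type abundance tests
```

## Input formats

- counts: MatrixMarket `matrix.mtx` + `features.tsv` + `barcodes.tsv`
  (genes x cells, integer), or a dense TSV (gene rows, cell columns);
- cell metadata: TSV with `cell_id, sample_id, sex, replicate, cell_type`;
- divergence: TSV with `gene_id, DN, DS, N, S` (per-gene `dN`, `dS` derived
  or validated). Converting codon-model output to this table is a one-liner
  per gene: extract the branch's `N`, `S`, `D_N`, `D_S` and write a TSV row.
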