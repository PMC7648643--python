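# kinchem

A toolkit for two desk-scale analysis chains on ancient-individual data:

1. **Pseudo-haploid population genetics** — EIGENSTRAT ASCII genotype I/O,
   outgroup-f3 / f4 statistics with weighted block-jackknife standard errors,
   pairwise mismatch-rate kinship with relatedness-coefficient interpolation
   and degree-of-relatedness classification, and X/Y read-count sex
   determination. A pedigree gene-dropping simulator (founders under
   Hardy-Weinberg, Poisson crossovers, exact realized-IBD tracking, and
   pseudo-haploid sampling with missingness/error/contamination) provides
   ground-truth synthetic data.
2. **LA-ICP-MS tooth chemometrics** — gas-blank subtraction with a 3-sigma
   limit of detection, one-point Ba calibration against NIST SRM 1486,
   line-scan georeferencing, Ca-normalised isotope-ratio maps, per-ROI
   percentile statistics, postnatal enamel layer-thickness estimation,
   crown-formation timing from prism lengths, and collagen C:N quality
   control. A phantom line-scan generator with known band structure provides
   ground truth.

## Package layout

| module                 | contents |
|------------------------|----------|
| `kinchem.genotype_io`  | `GenotypeMatrix`, EIGENSTRAT ASCII triplet read/write, overlap masks |
| `kinchem.popsim`       | founder models, pedigree templates, `gene_drop`, `pseudo_haploidize` |
| `kinchem.fstats`       | `compute_outgroup_f3`, `compute_f4`, `block_jackknife`, block schemes |
| `kinchem.kinship`      | `pairwise_mismatch`, baselines, `relatedness_coefficient`, `classify_degree`, `sex_from_counts` |
| `kinchem.toothchem`    | `reduce_scan`, `calibrate_ba`, `georeference_scan`, `roi_statistics`, `layer_thickness`, `crown_formation_time`, `collagen_qc`, `synth_scan` |
| `kinchem.cli`          | `kinchem` command-line interface and end-to-end runs |

## CLI

```bash
kinchem simulate --config sim.yaml --out-prefix out/matrix     # synthetic EIGENSTRAT triplet
kinchem f3 out/matrix OUTGROUP A B --min-snps 10000
kinchem f4 out/matrix A B C D --out f4.tsv
kinchem kinship --prefix out/matrix --pairs pairs.tsv --unrelated unrel.tsv
kinchem sexdet --counts counts.csv
kinchem tooth synth --config phantom.yaml --out-prefix out/ph
kinchem tooth reduce --scan out/ph.line0.csv --config geometry.yaml --out pts.csv
kinchem tooth roi --points pts.csv --rois rois.csv --ratio 138Ba/43Ca
kinchem tooth thickness --points pts.csv --config thick.yaml --out report.json
kinchem run genetics  --config gen.yaml  --out-dir out/gen  --seed 1
kinchem run toothchem --config tooth.yaml --out-dir out/tooth --seed 1
```

All commands are deterministic under a fixed `--seed`; `run` pipelines write
a `manifest.json` listing every output and the resolved configuration.

Example configs: a genetics run takes a `simulate` section
(`n_snps`, `templates: {first_cousin: 2, unrelated: 4}`, `sampling`) plus
optional `kinship`/`fstats`/`sexdet` sections; a toothchem run takes a
`phantom` section (`bands: [[dentin, 150, 0.30], [pre_nnl, 120, 0.20],
[post_nnl, 80, 0.42]]`, `noise_sd`) — see `tests/test_cli.py` for working
examples.

## Conventions worth knowing

- Pseudo-haploid samples carry call codes {0, 2, 9} only; code 1 in a
  pseudo-haploid sample is a validation error.
- Allele frequencies from a single pseudo-haploid sample are the sampled
  0/1 indicator; **no** small-sample bias correction is applied anywhere
  (the f-statistics are used as relative drift-sharing measures).
- The identical-pair mismatch baseline defaults to half the unrelated rate,
  the analytic pseudo-haploid expectation under Hardy-Weinberg; supply an
  observed identical/twin rate to override.
- Degree bins are arithmetic midpoints of the expected shares
  {1, 1/2, 1/4, 1/8, 1/16, 0}; ties go to the more-related class.
- Tests using fewer than 10,000 SNPs are reported but flagged `valid=False`
  / `qc_pass=False`, never dropped.
- LOD = 3 x the blank-window SD; blank-corrected values below the LOD are
  zeroed, and ratios with a zeroed denominator are undefined (excluded from
  statistics, not treated as 0).
- The supra-threshold layer-thickness run must be contiguous and
  surface-adjacent; interior spikes do not count.
- Crown-formation regression coefficients must come from configuration —
  none are built in.

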