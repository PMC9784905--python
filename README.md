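# translatome

Comparative analysis of paired Ribo-Seq and RNA-seq count data from two
cell populations — built around the kind of question asked of resting
B and T lymphocytes: which mRNAs are translated at exceptionally high
levels in each cell type, how strongly do those translatome sets overlap,
and which gene classes (notably 5'TOP mRNAs, the canonical translational
targets of mTORC1 via 4EBP) are translated more or less efficiently than
the rest of the transcriptome?

The package is aimed at analysts who already have gene-level counts from
paired ribosome-profiling and RNA-seq libraries (plus a sample sheet and a
gene effective-length table) and want a small, fully specified, testable
pipeline rather than a collection of one-off scripts.

## What it computes

* **TPM quantification** — `tpm_g = 10^6 (c_g/l_g) / Σ_h (c_h/l_h)` per
  library; replicate aggregation is the arithmetic mean of per-replicate
  TPM columns.
* **Highly translated sets** — a gene is called highly translated in a
  condition when its mean Ribo-Seq TPM lies strictly above the Tukey upper
  fence `Q3 + 1.5·IQR` of that condition's TPM distribution (quartiles by
  linear interpolation between order statistics).
* **Set overlap** — the two cell types' sets are partitioned
  (A-only/shared/B-only) and their intersection is scored with the
  upper-tail hypergeometric test `P(X ≥ k)` against the expressed-gene
  universe, evaluated in log space via log-gamma so p-values far below the
  double-precision underflow threshold remain exact as `log10_p`.
* **Translation efficiency** — `TE_g = (ribo_g + pc) / (rna_g + pc)` on
  mean TPM with a symmetric pseudocount `pc = 0.5`; differential TE
  between cell types is a Welch two-sample t-test on per-replicate
  `log2 TE` values (ribo/rna libraries paired by replicate index) with
  Benjamini–Hochberg adjustment; class-vs-background comparisons (e.g.
  TOP mRNAs) use a two-sided Mann–Whitney U on `log2 TE`.
* **Enrichment** — generic hypergeometric over-representation of any gene
  list against a GMT collection, clipped to the universe, BH-corrected.
* **Synthetic experiments** — a negative-binomial generator
  (`var = μ + φμ²`) that plants a cell-B-specific high-abundance gene
  block with neutral TE (an antigen-presentation/CD74-like signature) and
  a TOP class with suppressed TE in both cell types, and returns the full
  ground truth for recovery scoring.

## Worked example

Simulate a default two-cell-type experiment and run every stage:

```sh
cat > pipe.yaml <<EOF
simulation:
  n_genes: 2000
cells:
  a: B
  b: T
EOF
translatome pipeline --config pipe.yaml --seed 1 --outdir run1
```

The run logs each stage and writes 18 TSV tables plus a `manifest.json`
that records the version, parameters and seed. Key outputs:

```
$ cat run1/overlap.tsv
universe_n  n_a  n_b  n_shared  log10_p   p_value
1999        234  212  189       -191.285  5.18883e-192
```

234 genes are highly translated in cell B and 212 in cell T; 189 are
shared, an overlap that would essentially never occur by chance in a
1999-gene expressed universe (p ≈ 10^-191).

```
$ head -3 run1/class_te.tsv
class_name  cell_type  n_class  n_background  mean_log2_te_class  mean_log2_te_background  mean_difference  u_statistic  p_value
APC         B          20       1980          0.040409            -0.150227                0.190636         20578        0.762221
APC         T          20       1980          0.0255741           -0.0336483               0.0592223        18845        0.710306
```

The planted high-abundance "APC" block shows no TE difference from the
background (its high translation is abundance-driven), while the TOP rows
of the same table recover the planted −2 log2 TE suppression in both cell
types. `run1/recovery.tsv` scores the run against the simulation truth:
APC sensitivity 1.0 (all 20 planted genes fall in the cell-B highly
translated set) and a TOP-shift bias of +0.08 log2 units.

Every stage is also available as a standalone subcommand
(`simulate`, `tpm`, `highly-translated`, `overlap`, `te`, `diff-te`,
`class-te`, `rank`, `enrich`) operating on plain TSV/GMT files, and as a
plain Python API (`import translatome`).

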