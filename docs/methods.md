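# Methods

## Quantification

Counts are converted to TPM per library: `rate_g = count_g / length_g`,
`tpm_g = 10^6 · rate_g / Σ_h rate_h`. Effective lengths are user-supplied,
in nucleotides; the pipeline begins at gene-level counts and applies no
between-sample normalization beyond TPM. Counts must be exactly integral —
multimapping-weighted fractional counts are rejected rather than rounded,
which keeps the TPM and simulation contracts exact. A library with zero
total counts yields an all-zero TPM column and a warning instead of an
error.

Replicates are aggregated as the arithmetic mean of their per-replicate
TPM columns, not as TPM of pooled counts. The two conventions differ when
library sizes differ; the per-replicate mean keeps replicates exchangeable
and matches the "mean TPM" summaries the per-condition tables report.

The expressed-gene universe — the background N for every hypergeometric
test — is the set of genes with mean TPM ≥ `min_mean_tpm` (default 1) in
at least one supplied condition. The threshold is surfaced as a flag; the
universe is never assumed silently, and the overlap subcommand requires N
explicitly when run standalone.

## Highly translated sets

A gene is highly translated in a condition when its mean Ribo-Seq TPM is
strictly above the Tukey upper fence `Q3 + k·IQR` (default k = 1.5).
Quartiles use linear interpolation between order statistics at zero-based
position `(n−1)q` — the most common convention, and the one recorded in
every `OutlierResult` so written fixtures are self-describing. Strict
inequality decides boundary ties: a gene exactly at the threshold is not
called. By default the fence is computed over the condition's full TPM
distribution including undetected (zero-TPM) genes; `--nonzero-only`
restricts the fence (but not membership, which zeros can never reach) to
detected genes. Both behaviours are tested.

The overlap of two sets is an upper-tail hypergeometric probability
`P(X ≥ k)` for `X ~ Hypergeom(N, n_a, n_b)`. Real translatome overlaps
produce p-values far below the smallest normal double, so the tail is
summed in log space from log-gamma pmf terms (`scipy.special.gammaln` +
`logsumexp`) and reported as `log10_p`, alongside a linear p clipped at
the smallest positive subnormal. Tests cross-check the routine against
exact rational enumeration (`math.comb` / `Fraction`) for every
configuration with N ≤ 25 at relative error 1e-10.

## Translation efficiency

TE is the ratio of ribosome-bound to total mRNA abundance:
`te_g = (ribo_tpm_g + pc) / (rna_tpm_g + pc)` on condition-mean TPM, with
a symmetric pseudocount `pc` (default 0.5 TPM). The pseudocount bounds TE
for genes undetected in one assay; at `pc = 0`, genes with a zero
denominator or zero ratio are flagged undefined and excluded from all
downstream statistics. 0.5 TPM is small against the median TPM of a
typical expressed gene, so it perturbs well-measured genes negligibly
while regularizing the tail.

**Differential TE.** Per replicate r and cell c,
`l_{c,r,g} = log2((ribo_tpm + pc)/(rna_tpm + pc))`, with ribo and rna
libraries paired by replicate index within each cell type (a log-ratio per
replicate requires a pairing; replicate index is the natural one).
Each gene is tested with a Welch two-sample t on `{l_a,·}` vs `{l_b,·}`
(Welch–Satterthwaite degrees of freedom, two-sided), and BH q-values are
computed across all tested genes. Genes below the expression filter in
every involved (cell, assay) condition are excluded before testing — the
log-ratio of two near-zero TPMs is dominated by the pseudocount and its
discreteness breaks the t approximation. Degenerate genes (zero variance
in both groups, equal means) are assigned t = 0, p = 1. This statistic is
deliberately simple and fully specified: no shrinkage, no fitted
mean–variance trend, so every number is reproducible from the TPM matrix
alone. Under a simulated global null it holds the pointwise type-I error
near nominal (measured 0.034 at α = 0.05 with 3 replicates per group) and
BH keeps the empirical FDR under control; both are asserted in the test
suite.

**Class comparisons.** A gene class (e.g. TOP mRNAs) is compared to all
other defined genes with a two-sided Mann–Whitney U on log2 TE — exact
enumeration when either group has fewer than 8 members, the tie-corrected
normal approximation otherwise — and the mean log2 TE of class and
background are reported. Two-sided tests are used throughout; direction
is reported descriptively via the mean difference.

**Abundance ranking.** Condition-mean TPM is ranked densely in descending
order (ties share a rank, rank 1 = most abundant), with per-set membership
flags, to support "is this class highly translated because it is highly
transcribed?" questions.

## Enrichment

A generic over-representation test of a query list against a GMT
collection: each set is intersected with the universe before testing
(standard practice), query genes outside the universe are logged and
clipped, p-values come from the same log-space hypergeometric routine, and
BH correction runs across the collection (the field's convention for
GO-style analyses, rather than Bonferroni). Records are sorted by
ascending p with ties broken by set name. No ontology structure (DAG
propagation) is modelled; any set collection the user supplies is tested
as-is.

## Synthetic experiments

The generator emulates the statistical structure the analysis assumes in a
two-cell-type resting lymphocyte design, with defaults chosen as typical
desk-scale study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | genes simulated |
| `n_replicates` | 3 | libraries per (cell, assay) |
| `depth` | 5e6 | expected reads per library |
| `abundance_log_mean/sd` | 1.0 / 1.5 | baseline log-normal transcript abundance (natural log) |
| `nb_dispersion` | 0.1 | NB φ in `var = μ + φμ²` (typical bulk RNA-seq scale) |
| `n_apc_genes` / `apc_log2_boost` | 20 / 6 | cell-B-specific high-abundance block |
| `n_top_genes` / `top_log2_te_shift` | 200 / −2 | TOP class and its TE suppression in both cells |
| `te_log2_sd` | 0.25 | per-gene baseline log2 TE spread |
| `length_log_mean/sd` | ln 1500 / 0.4 | gene effective-length log-normal |

Baseline abundance is drawn once and shared by both cell types (a shared
quiescent transcriptome). The APC block multiplies cell B's *RNA*
abundance only and leaves TE neutral, so its translatome signal is purely
abundance-driven. The TOP shift is applied to *ribosome occupancy* only,
in both cell types, so RNA-level analyses are blind to TOP status — the
suppression is translational, not transcriptional. Expected counts are
`depth · abundance·length / Σ abundance·length` (read counts scale with
transcript length at fixed molar abundance), and counts are NB with shared
dispersion φ across genes (the minimal standard noise model; φ = 0
degenerates to Poisson). One `numpy` generator seeded from a single
integer drives every draw; identical config + seed reproduce bit-identical
outputs.

What the generator does **not** emulate: positional footprint structure,
5'TOP sequence features, multimapping, batch effects, library-preparation
biases, gene–gene correlation, or gene-specific dispersion. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to every artefact of real libraries.

`evaluate_recovery` scores an analysis against the planted truth: the
fraction of APC genes recovered in the cell-B highly translated set, the
false-discovery proportion of that set against the truth's own
fence-defined set (the same fence applied to noise-free TPM), the bias of
the class-comparison mean difference against the planted TOP shift, and
the empirical FDR of differential-TE calls at q < 0.05 against the true
per-gene TE differences.

## Numerical and design choices

* Quantile convention, strict fence inequality, and the
  fence-on-all-genes default are declared choices where the underlying
  procedure admits several conventions; each is recorded in the result
  objects or exposed as a flag, and both fence variants are tested.
* Differential TE is an authored, fully specified statistic rather than a
  wrapper around a count-model package, trading shrinkage efficiency for
  exact reproducibility and testability; its calibration is verified by
  simulation in the suite.
* p-values are clipped to the smallest positive subnormal instead of 0 so
  that `p ∈ (0, 1]` holds; the log10 value is authoritative in the
  extreme tail.
* Enrichment tie-order: ascending p, then set name — deterministic across
  GMT orderings.
* Problem sizes in the test suite (2000-gene default runs, 20 null
  simulations of 500 genes, a 400-gene end-to-end determinism run) are
  chosen so the whole suite completes in well under a minute while keeping
  every statistical assertion comfortably powered.

## Known limitations

* The differential-TE t-test assumes approximate normality of replicate
  log2 TE; with 2 replicates per group it is legal but weakly powered and
  its calibration is only verified at 3 replicates.
* TE compares two compositional (TPM) quantities; strong composition
  shifts between assays can displace all TEs by a common factor. Class
  comparisons against the within-cell background are insensitive to this;
  absolute TE values are not.
* The expressed-universe rule (mean TPM ≥ threshold in ≥ 1 condition) is
  one of several defensible choices; the overlap p-value depends on N, so
  the universe definition is always recorded in the outputs.
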