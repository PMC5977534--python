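# Methods

## Scope and data model

`ffpeseq` analyses gene-level count matrices from a factorial study design:
tumors × tissue preparation {FF, FFPE} × library chemistry {poly(A)
selection, ribosomal depletion} × RNA input amount. Per sample it also
carries the five-way read-mapping composition (exon, intronic/intergenic,
rRNA, multiple alignment, unmapped) and a 100-bin 5′→3′ meta-gene coverage
profile. Only exonic reads are assigned to genes; the other categories are
bookkept as totals because they determine how much of the sequencing budget
is usable, not what it measures.

## Synthetic study generator

The generator produces studies with the statistical structure the analysis
assumes, plus ground truth for recovery tests. It emulates gene-level
summaries only — no read sequences, alignment artifacts, GC effects,
UMI structure or chemical cross-linking chemistry — so passing tests
demonstrate correctness of the statistical machinery on data satisfying the
model's assumptions, not robustness to every failure mode of real FFPE
libraries.

**True expression.** Per-gene baseline log2 expression is
Normal(μ = 4, σ_s = 2); only relative abundances matter after
normalization, so μ is a label while σ_s sets the dynamic range (a log2 SD
of 2 spans ~13 log2 units over 23,000 genes). Each tumor perturbs a random
fraction (default 0.35) of genes by an additive Normal(0, 2.0) log2 effect,
recorded in a registry. Two different tumors therefore differ at ~58% of
genes — deliberately heavy inter-tumor heterogeneity, chosen so that
threshold-selected fold changes are dominated by true signal the way
comparisons between unrelated tumors are.

**Capture noise.** Each protocol draws one per-gene log2 offset
Normal(0, σ_p = 0.3), shared by all libraries prepared with that
chemistry: libraries of one protocol agree with each other better than
across protocols, and with no FFPE noise a matched FF/FFPE pair differs
only by counting noise. FFPE libraries add independent per-gene,
per-library noise Normal(0, σ_t). Because the protocol offset is shared
within a matched same-protocol pair, the FF/FFPE Pearson correlation on
the uncensored log scale follows the attenuation law
cc² = S/(S + σ_t²) with S = σ_s² + σ_p²; the default σ_t = 0.98 is the
closed-form solution for cc = 0.90 (`sigma_tissue_for_cc`). An optional
extra-noise SD for 100 ng inputs exists and defaults to 0 (input amount is
otherwise a pure label).

**Counts.** Category totals are integers: exonic reads are exactly
round(depth × f_exon) and the remainder is split by largest-remainder
allocation, so mapping fractions rebuild to 1 exactly. Default per-group
budgets are mean mapping percentages characteristic of these four sample
types (e.g. 58% exonic for FF poly(A), 29.2% for FFPE poly(A), 8.4% for
FFPE ribosomal depletion); the FF ribosomal-depletion defaults are
renormalized because the raw one-decimal means sum to 99.8%. Gene counts are one multinomial draw of the
exonic total with weights 2^(truth + noise); rRNA genes get weight 0
everywhere (their reads live in the rRNA category) and non-poly(A) genes
get weight 0 under poly(A) selection.

**Coverage.** Read positions on a 200-transcript panel: FFPE poly(A)
positions are truncated-exponential distances from the 3′ end with mean
λ = `frag_mean_bp` (default 500 bp — a modelling choice; real degradation
is reported only as RIN ≈ 2, which fixes no length scale, so λ is exposed
in the config). Ribosomal depletion is uniform; FF poly(A) applies a fixed
1.2× density tilt on the last quintile, reproducing the small 3′ bias
intact RNA shows under oligo(dT) capture. The exponential was chosen as the
simplest one-parameter survival model with a closed-form bin-mass formula,
which the tests use as an independent oracle.

**Reproducibility.** Every random stream is keyed
`default_rng([seed, stage, tumor, tissue, protocol, input])`, so studies
are byte-reproducible and adding tumors or samples never perturbs existing
libraries.

## Analysis choices

- **Normalization**: counts per million *total* fragments (library size
  includes non-exonic reads), no length/TPM correction — all comparisons
  are within-gene across samples.
- **Floor**: expression below 5 log2 units (32 CPM) is set to 5, not
  filtered, so fold changes and correlations are defined for every gene
  while sub-threshold noise vanishes. Zeros map to the floor directly; no
  pseudocount.
- **Detection**: a gene is detected at ≥ 1 exonic read by default
  (configurable); any fixed threshold yields the same saturation *shape*,
  and 1 read is the weakest defensible definition.
- **Saturation fit**: one shared curve across all libraries — protocol
  differences enter only through exonic fractions. The hyperbola is the
  default parametric form (smooth, monotone, saturating, two parameters,
  closed-form inverse); a shape-preserving monotone cubic through
  depth-averaged points (duplicate depths averaged, anchored at (0,0),
  bisection inverse) is available where the hyperbola fits poorly.
  Unreachable targets (t ≥ G_max) raise an explicit error. Depth ladder
  default: fractions {0.05, 0.1, 0.2, 0.4, 0.7, 1.0}, 3 thinning seeds
  each.
- **Meta-coverage**: transcripts are mean-pooled into 100 equal-width
  windows and averaged with equal per-transcript weight (each binned
  profile first normalized to mean 1) so highly expressed genes do not
  dominate; read-weighted averaging is available via `weight='reads'`.
  Transcripts shorter than the bin count are skipped (logged), not
  upsampled. Profiles are computed over transcript bodies, not
  intron-inclusive genomic spans.
- **Correlation filter**: genes floored in both compared samples are
  excluded (their equality is an artifact of the floor); genes floored in
  one sample stay in.
- **FC agreement**: the threshold is linear-scale ("2-fold"), applied as
  |log2 FC| ≥ log2(threshold); sign agreement is strict, an FF fold change
  of exactly 0 (both-floored) counts as disagreement, and at threshold 1
  genes with FC exactly 0 are excluded explicitly since the magnitude cut
  is vacuous there.
- **Differential expression**: Welch (unequal-variance) t-test per gene on
  log2 expression, BH adjustment, default q ≤ 0.001. "Expressed" means
  above the floor in ≥ 50% of at least one group's samples. Genes with zero
  variance in both groups get p = 1.

## Numerical notes

- Hyperbola fitting uses constrained least squares with tight tolerances
  (1e-14) and a data-driven initial guess (G_max ≈ 1.05 × max detection,
  K at half-saturation); noiseless points are recovered to better than
  1e-6 relative error.
- The 3′-bias index clamps its denominator at 1e-6 so fully
  3′-concentrated profiles remain finite.
- Binomial thinning at fraction 0 or 1 short-circuits to exact results.
- Mapping-stats readers accept row sums within 1e-6 of 1; the simulator
  produces exact integer category splits.

## Validation design

Tests check the implementation against independent oracles rather than
against itself: closed-form exponential bin masses for coverage, binomial
moments and the survivor form Σ(1 − (1−f)^c) for thinning and detection,
the attenuation law for FF/FFPE correlation (measured with the floor set
below the data range at −6 log2 CPM, since the default floor of 5
deliberately censors the low-expression regime and range restriction would
mix censoring with attenuation), a fresh-draw Monte-Carlo oracle for the
agreement sweep, brute-force step-up for BH, and the textbook formula for
the Welch statistic. End-to-end problem sizes (20,000–23,000 genes, 50
seeds for correlation recovery, 100 seeds for null FDR, 10⁵ reads per
coverage panel) were sized to keep the full suite under a minute while
leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

- Capture noise has constant log-scale variance across genes; real
  technical noise shrinks with expression, so the simulated correlation
  between matched samples is less expression-dependent than in real data.
- The floored correlation the pipeline reports on default-scale synthetic
  studies (~0.75–0.8) sits below the uncensored attenuation target (0.90)
  because most of a 23,000-gene CPM distribution lies near the floor;
  interpreting floored correlations requires the filtered gene count
  reported alongside.
- Coverage is positional only (point reads, no fragment length on the
  covered side) and the transcript panel subsamples the universe.
- The DE module is a plain t-test on log2 values, appropriate for the
  large-cohort arrays it mirrors and for panel definition on simulated
  data — not a count-model replacement for small-n RNA-seq designs.
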