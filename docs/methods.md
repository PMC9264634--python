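# Methods

## The occupancy model

For each ChIP-seq experiment the package explains the read counts of
*k* motif-aligned peaks with two log-linear signals sharing one feature
matrix **X** (*k × m*):

    log μ_f = X β_f          TF-specific signal
    log μ_b = X β_b          background signal
    log λ_c = X β_b + s_c                    expected control counts
    log λ_p = X β_b + X β_f + s_p            expected pulldown counts
    n_c ~ NB(λ_c, θ),  n_p ~ NB(λ_p, θ)

`s_c` and `s_p` are library-scale terms and θ is a single negative-binomial
dispersion shared by all observations (variance μ + μ²/θ).  The model is
fitted as one stacked GLM of length 2k, `n ~ X + t + X:t`, where `t`
indicates pulldown rows: main effects of X are β_b (they shape both
libraries), the X:t interactions are β_f (pulldown only), the intercept is
s_c and the t main effect is s_p − s_c.  Fitting both β_b and β_f jointly is
what lets the model separate, e.g., a sonication bias toward open chromatin
(background) from a genuine accessibility dependence of TF binding
(TF-specific).

## Feature construction

Peaks are aligned by the best log-odds match of the TF's known motif with
start within ±100 bp of the peak summit, scanned on both strands
(pseudo-frequency 0.01 against a uniform background; ties resolve to the
higher score, then '+' strand, then the smaller genomic start, with a 1e-9
score tolerance absorbing float summation-order differences between
strands).  Minus-strand peaks are reverse-complemented so position 1 of
every view is the motif's 5′ end.  Peaks with an N inside the motif, an
out-of-bounds window, or overlap with an optional repeat mask are dropped
and counted per reason.

The blocks of **X**:

- **A** (11 columns): mean accessibility in five 200-bp bins upstream of
  the motif start, the motif interval itself, and five bins downstream,
  mirror-ordered on the minus strand; log-transformed after adding a
  dataset-wide pseudocount of 1% of the smallest strictly-positive bin
  mean.  A trained model stores its pseudocount and reuses it when applied
  to a new context so transferred features stay on one scale.
- **M** (L columns): per motif position, the methylation fraction of the
  CpG whose C maps there, 0 when the peak has no CpG at that position.  The
  coefficient therefore reads as the effect of full methylation at a
  CpG-bearing site.  Methylated/unmethylated WGBS counts of the two
  strands of one CpG (the C, and the G position one base downstream) are
  summed before the fraction is computed — CpG methylation is symmetric and
  merging maximizes coverage.  Peaks whose mean coverage over motif CpG
  positions is below 10 are removed; CpG-free peaks are exempt (the filter
  is meaningless without CpGs, and dropping them would destroy the sequence
  signal).
- **S** (3L columns): binding-site sequence, contrast-coded — three
  indicators per position for the non-reference bases, the reference being
  the motif consensus.  Full one-hot plus an intercept is rank-deficient;
  contrast coding makes identifiability explicit instead of delegating it
  to the fitting routine's aliasing.
- **RS** (3) and **RM** (1): flank base composition (C, G, T fractions over
  the 40 flanking bp; A is the reference) and mean flank CpG methylation.

## The GLM engine

A purpose-built NB engine (log link, offsets) alternates IRLS for the
coefficients at fixed θ with a bounded one-dimensional ML update of θ until
the relative log-likelihood change falls below 1e-8 (at most 50 outer
iterations).  Numerical choices that matter:

- IRLS starts from μ₀ = y + 0.5 (the standard GLM data start); a cold
  β = 0 start can take one enormous first step when a single count is very
  large and θ small, landing on the linear-predictor clip plateau.
- The linear predictor is clipped at ±30 (e³⁰ ≈ 10¹³, far above any count
  mean); steps are halved whenever they would decrease the likelihood, and
  the inner loop stops on a likelihood plateau.
- θ is initialized by method-of-moments from the Poisson-fit residuals
  (floored at 0.1) and pinned to 10⁸ when the profile likelihood increases
  monotonically (under-dispersed data; the Poisson limit), which keeps the
  outer loop convergent.
- Linearly dependent columns are detected by pivoted QR, dropped with a
  warning and reported as NaN — near-constant sequence indicators at
  conserved motif positions make this routine, not exceptional.
- Standard errors come from the observed information at fixed θ.

Wald tests are z = β̂/SE against the normal; likelihood-ratio tests
re-estimate θ in the full and the reduced model independently and refer
2·Δll to χ² with df = number of dropped columns.  Per-position methylation
LRTs drop *both* the background and TF-specific copies of the column — the
conservative nested test of whether that position's methylation is
informative at all (dropping only the interaction is available as an
option).

## Evaluation, classification and QC

The observed per-peak binding ratio is
log((n_p + 0.5)/(n_c + 0.5)) − log(Σn_p/Σn_c); the pseudocount keeps
zero-count peaks finite, the second term absorbs the library-size ratio.
Ten-fold cross-validation partitions peaks by a seeded permutation, fits on
9/10 and predicts X·β_f out of fold; Pearson r (and r²) of pooled
out-of-fold predictions against the observed ratio is the headline quality
number, reported alongside the same quantity in-sample when a trained model
is transferred to a new context.

Methyl-preference calls: for every motif position where at least 10% of
peaks carry a CpG (the prevalence rule making "no-CpG" precise), the
TF-specific methylation coefficient is tested by Wald and
Benjamini–Hochberg-corrected across those positions within the model.  At
q < 1e-5: at least one negative and no positive effect → methyl-minus;
positive only → methyl-plus; both → mixed-effect; none → no-effect; no
qualifying position → no-CpG.

Model QC applies four criteria: (i) ≥ 10,000 training peaks,
(ii) cross-validated r > 0.2, (iii) Pearson r > 0.3 between the TF-specific
sequence coefficients and the centered log frequencies of the known motif
(computed over all position × base entries, both centered per position so
the comparison is contrast-invariant), and (iv) mean |background sequence
coefficient| / mean |TF-specific sequence coefficient| < 0.4 — our concrete
reading of "low contribution of sequence to the background signal"; the
statistic is exposed so other readings can be substituted.

## Differential binding

Peaks from multiple samples are merged by single linkage of summits within
100 bp (merged summit = rounded mean).  Each merged peak's replicated
counts are modeled as `~ sample + t + c:t`: the categorical sample term
absorbs library size and cell-line main effects, `t` is the
pulldown-to-control log-ratio in the reference cell, and the `c:t`
interaction — divided by log 2 — is the log2 fold change of differential
binding with its SEM; per-library median-of-ratios size factors enter as
fixed offsets.  Fold changes are raw MLEs (no shrinkage): the downstream
SEM < 1.28 filter presumes unshrunk values.

One dispersion is shared across peaks.  With 2+2 replicates each per-peak
model spends 6 of 8 observations on mean parameters, so a free per-peak θ
collapses toward Poisson and destroys Wald calibration; pooled ML has the
same bias.  θ is instead estimated by a residual-df-corrected Pearson
estimating equation, Σ (y−μ)²/(μ+μ²/θ) = Σ residual df, iterated with
per-peak refits at the current θ, then held fixed in every per-peak fit.
The test suite checks this calibration on a null two-cell simulation
(fraction of q < 0.1 calls bounded near the nominal level).

Model-based prediction of differential binding is (X_B − X_A)·β_f/log 2
over matched peaks, optionally with the accessibility block zeroed to
isolate methylation/sequence-driven predictions; agreement with observed
fold changes is summarized over the SEM-filtered peaks, over the q < 0.1
subset, and as sign accuracy on the significant subset.

## The synthetic-data generator

The generator emulates every input the pipeline reads, from known truth:

- Motif instances sampled from the PFM, with CpG-capable positions forced
  to CG with probability 0.6 (defaults: a 12-bp motif, consensus
  `TACGTAAACGGT`, CpGs at positions 2/3 and 8/9).
- Methylation fractions from the bimodal WGBS-like mixture
  0.7·Beta(0.5, 8) + 0.3·Beta(8, 0.5); per-CpG coverage NB(mean 30, θ 5),
  split binomially between strands, methylated counts binomial in the
  latent fraction.  An optional peak-level latent state correlates nearby
  CpGs, reproducing the known difficulty of deconvolving adjacent
  positions.
- Accessibility as log-normal bin means around a peak-center bump with a
  shared per-peak level.
- Counts drawn NB(λ, θ = 5) from the exact model equations, control depth
  ≈ 20 (≈ 50 in differential runs, matching a deeply sequenced
  comparison), pulldown enrichment e² at a consensus site.  True
  TF-specific coefficients default to −1.2 per non-consensus base, an
  accessibility profile peaked at the motif bin, −0.3 for regional
  methylation, and per-experiment planted intra-motif methylation effects.

The in-memory path stops at the design matrix; the file path embeds each
peak in a synthetic chromosome and writes FASTA, a summit/count table,
bismark-format coverage (both strand positions per CpG; motif and flank
windows covered) and a bedGraph whose intervals align exactly with the 11
accessibility bins.  The file writer guarantees the planted motif instance
is the unique best scan hit near the summit by redrawing the scan-window
background (for a hopelessly weak sampled instance, the peak); this is what
makes the round-trip invariant — pipeline-built design matrix equal to the
generator's internal features — exact rather than approximate.  Same seed,
byte-identical files.

What the generator does not emulate: realistic genome composition, repeat
elements, correlated occupancy between nearby peaks, fragment-level read
placement, and mapping artifacts.  Passing tests therefore demonstrate the
statistical machinery — identifiability, calibration, recovery — under the
model's own assumptions, not robustness to real-data violations of them.

## Validation problem sizes

Chosen for single-CPU runtimes: coefficient recovery at k = 20,000;
likelihood-ratio calibration over 1,000 replicates at k = 2,000 on a
compact five-column design (the calibration stresses the GLM layer, not
the feature extraction); classification cohorts at k = 4,000 × 8 runs per
class (the planted |effect| = 2 saturates the q < 1e-5 call well below
that size); the differential pipeline at k = 1,500 peaks with 2+2
replicates.

## Known limitations

- Methylation fractions enter X as point estimates; WGBS sampling noise at
  low coverage attenuates methylation coefficients toward zero (the
  coverage-10 filter bounds, but does not remove, this).
- One motif hit per peak; multi-instance peaks and gapped motifs are out of
  scope.
- The normal Wald reference for per-peak differential tests is approximate
  at very low replicate counts even with a shared dispersion.
- Direct competition with methyl-CpG readers is not modeled; methylation
  coefficients read as preferences *relative to* whatever else binds
  methylated sites in the cell.
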