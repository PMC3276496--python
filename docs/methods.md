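# Methods

## The analysis model

`transdiv` analyses digital expression profiles: a genes × conditions
table of non-negative integer read counts, where each column is one
sequencing library and the number of reads mapping to a gene is taken as
a measure of its transcript abundance. One condition is designated the
untreated control. The package treats each library as a single
multinomial sample — N_j reads drawn from an unknown frequency vector
p_·j over G genes — which is the natural sampling model for tag-count
data (SAGE, EST and 454-style cDNA counting) where each read is one draw
from the mRNA population.

All downstream statistics operate on the plug-in frequencies
p̂_ij = x_ij / N_j.

### Fold-change differential expression

For treatment j, the expression ratio of gene i against the control c is

    r_ij = p_ij / p_ic

and gene i is called **up** when r_ij ≥ 2.0, **down** when r_ij ≤ 0.5
(both inclusive), and **unchanged** otherwise. Ratios are taken on
library-size-normalized frequencies, not raw counts: with unequal library
depths this is the only choice that makes calls invariant to sequencing
effort (a raw-count mode is retained behind `ratio_on="counts"` for
sensitivity analysis, and demonstrably changes calls when depths differ).

Two guards handle the pathologies of count ratios:

* **Zero in the control.** Default policy `sentinel`: the ratio is
  reported as +inf (the limit as p_ic → 0⁺) and the gene is called up if
  it clears the read filter. Alternative policy `pseudocount` adds a
  configurable pseudo-frequency (1/N_j by default) to numerator and
  denominator, keeping all ratios finite at the cost of shrinking the
  ratios of low-abundance genes.
* **Read filter.** A gene enters the comparison only if it has at least
  `min_count` (default 3) reads in one of the two compared libraries.
  A 2-fold call from 1-vs-0 reads is sampling noise; three reads is the
  smallest count for which a 2-fold ratio is more likely signal than
  Poisson fluctuation at these depths. The filter intentionally operates
  on raw read evidence, so it is depth-dependent: deeper libraries admit
  rarer genes. (For this reason the scale-invariance property of
  frequency ratios is exact only with the filter disabled.)

Per-gene calls across a chosen treatment set are collapsed into **sign
patterns** — one symbol of {+, −, 0} per treatment — and genes are
partitioned by pattern. The partition is complete: every gene with no
excluded call lands in exactly one pattern (the all-zero pattern collects
the unresponsive majority), and excluded genes are tallied separately, so
the bookkeeping from input genes to reported overlap counts is auditable.
The rendered table has an upregulated block (patterns over {+, 0}) and a
downregulated block (patterns over {−, 0}), the fully-concordant pattern
first.

### Diversity, specificity, specialization

With t conditions and uniform condition weights 1/t:

    H_j  = −Σ_i p_ij log2 p_ij                      (diversity, bits)
    p̄_i  = (1/t) Σ_j p_ij
    S_i  = (1/t) Σ_j (p_ij/p̄_i) log2 (p_ij/p̄_i)     (gene specificity)
    δ_j  = Σ_i p_ij S_i                             (specialization)

0·log 0 ≡ 0 throughout. H_j ∈ [0, log2 G] measures how evenly a
transcriptome spreads its reads over genes; S_i ∈ [0, log2 t] is 0 for a
gene expressed at identical relative frequency everywhere and log2 t for
a gene confined to a single condition; δ_j is the expression-weighted
mean specificity of what condition j actually expresses. The three are
tied by the mutual information between gene identity and condition under
a uniform condition prior:

    MI = (1/t) Σ_j Σ_i p_ij log2(p_ij/p̄_i) = Σ_i p̄_i S_i = (1/t) Σ_j δ_j.

The identity is algebraic; the implementation evaluates both residuals on
every run as a numerical self-check (they must vanish to ≤ 1e-12, and the
test suite verifies this on a thousand random matrices).

Design choices here:

* **Log base 2 (bits) by default**, configurable; every statistic scales
  by 1/log2(base), so distances in the (H_j, δ_j) plane are
  base-dependent.
* **Uniform condition weights** for p̄_i, because the MI decomposition
  holds under a uniform condition prior; a depth-weighted mode is
  available but breaks the clean "average over conditions" reading.
* **Plug-in estimation.** H_j and δ_j are maximum-likelihood plug-in
  statistics, biased at finite depth: E[Ĥ_j] − H_j ≈ −(G−1)/(2 N_j ln 2)
  bits to first order, and δ̂_j has a *positive* null bias equal to the
  plug-in MI bias, ≈ (G−1)(t−1)/(2 t N ln 2) bits when all conditions
  share one distribution. The Miller–Madow correction is available behind
  a flag (default off, so the default output is the plain plug-in value);
  `bootstrap_stats` provides percentile intervals by multinomial
  resampling of each library at its observed depth.
* **Gene-order-independent arithmetic.** Sums over genes use exactly
  rounded summation (`math.fsum`), so permuting input rows reproduces
  H_j, δ_j and MI bit-for-bit — a property the pipeline tests rely on.

### Condition geometry

Each condition is embedded as the point (H_j, δ_j); similarity between
transcriptomes is the Euclidean distance between their points. Distances
are computed on the raw axes (both in bits; no standardization, since the
two axes are on comparable scales in this application — a z-score mode
exists behind a flag). The proximity summary reports each condition's
nearest neighbour and a single-linkage merge order with groups at a
configurable cut; single linkage was chosen as the simplest reading of
"which conditions cluster together", is labelled as a presentation
device, and is deterministic with ties broken by condition order.

## The synthetic data generator

`synthetic_data` emulates the study design the package targets: six
multiplexed libraries (control C plus five treatments E, JA, W, F, S)
with ~44,156 genes and ~159,000 reads per library (~955k total) by
default.

* **Baseline abundances**: log-normal frequencies (σ = 2.0 on the
  natural-log scale), normalized. Heavy-tailed abundances are the norm in
  cDNA tag libraries — a few transcripts absorb much of the read mass and
  a long tail sits near or below the detection limit — and they stress
  the entropy estimators realistically. A Zipf alternative sits behind
  `baseline_model="zipf"`.
* **Treatment effects**: per treatment, 0.5% of genes induced 10-fold and
  0.5% repressed 10-fold by default (multiplicative fold factors followed
  by renormalization — a closed transformation whose renormalization
  constant Z_j is recorded, so the realized treatment/control ratio of a
  module gene is exactly fold/Z_j and every downstream recovery test has
  a closed-form truth). The ~1% DE fraction per treatment mirrors the
  few-hundred-DE-genes-out-of-tens-of-thousands regime typical of these
  designs; fold 10 reflects strongly induced signalling genes.
* **Sampling**: one multinomial draw per library; column sums equal the
  requested depths exactly. A single global seed expands into per-stage
  substreams (`numpy.random.SeedSequence.spawn`), so truth generation and
  sampling are individually reproducible.

What the generator does **not** emulate: read-level artefacts (homopolymer
errors, chimeras, mapping ambiguity), biological replicate variability
(each condition is one library, as in the target design), correlated
induction across related treatments, and assembly-induced gene
fragmentation. Passing recovery tests therefore demonstrate correctness
of the estimators under multinomial sampling, not robustness to
upstream artefacts.

`recovery_experiment` closes the loop: draw truth → sample libraries →
run the estimators → score. It reports per-condition bias and RMSE for
Ĥ_j and δ̂_j against the truth and a DE confusion summary (sensitivity,
specificity, false-discovery proportion, plus sensitivity restricted to
genes with control frequency ≥ 1e-4 — below that, a 150k-read library
expects < 15 control reads and the fold-change rule is power-limited, so
the overall FDP among calls is dominated by borderline low-count genes).

## Numerical and degenerate-input conventions

* Thresholds must satisfy up > 1 > down > 0; boundary ratios are
  inclusive (≥, ≤) exactly as stated.
* Genes with zero counts in every library are retained through I/O and
  excluded from DE by the read filter; they carry NaN specificity and
  contribute nothing to δ_j.
* Empty libraries (zero column total) are rejected at input validation.
* Frequency columns must sum to 1 within 1e-12; the distance matrix must
  satisfy the metric axioms within 1e-9 (both tested).
* Single-gene libraries give H = 0 with zero-width bootstrap intervals.

## Problem sizes used in the shipped studies

The recovery study bundled with the tests and the acceptance script runs
at 5,000 genes × 6 conditions × 150,000 reads/library × 20 replicates —
a deliberate desk-scale miniature of the target design chosen so the full
loop (truth, sampling, estimation, scoring) stays in the seconds range
while keeping N large enough that first-order bias theory applies. At
this scale the measured plug-in diversity bias (≈ −0.024 bits) matches
−(G−1)/(2N ln 2) = −0.0240, and the null specialization
(≈ 0.0199–0.0203 bits across conditions and seeds) matches its theoretical
mean (G−1)(t−1)/(2tN ln 2) = 0.0200 — worth knowing when interpreting
small δ̂_j values on real data of comparable depth: values at or below
the bias floor are indistinguishable from no specialization.

## Known limitations

* The fold-change rule is a deterministic threshold, not a test: no
  p-values, no dispersion modelling, no multiple-testing control. That is
  the method being implemented, and the recovery study quantifies its
  operating characteristics instead.
* Plug-in entropies are biased at finite depth (see above); comparisons
  between libraries of very different depths should use the bootstrap
  intervals or the Miller–Madow flag.
* The (H_j, δ_j) embedding reduces each transcriptome to two numbers;
  conditions can coincide in the plane while differing gene-by-gene. The
  sign-pattern partition is the complementary, gene-resolved view.
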