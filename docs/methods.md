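# Methods

## The two-library exact test

The unit of data is a gene's tag count in each of two sequencing
libraries: `x` tags in library A of total depth `N₁`, `y` tags in library
B of depth `N₂`. Counts are modelled as independent Poisson draws, the
standard model when each condition is sequenced once and every tag is an
independent sample from the mRNA pool. Following Audic & Claverie's
derivation, the distribution of `y` conditional on `x` under equal
per-tag expression is

    p(y|x) = (N₂/N₁)^y · (x+y)! / ( x!·y!·(1+N₂/N₁)^(x+y+1) )

equivalently the negative binomial NB(x+1, N₁/(N₁+N₂)) — the Poisson
posterior predictive under a flat prior on the rate. The implementation
evaluates `log p(y|x)` through `scipy.special.gammaln` and accumulates
tails with `logsumexp`; the lower tail is summed exactly over its `y+1`
terms when `y` is at or below the conditional mode, otherwise the upper
tail is summed directly until additional terms no longer move the total
at double precision (their decay is geometric past the mode). The test
suite checks both routes against exact `fractions.Fraction` arithmetic
for `x+y ≤ 30` and against `scipy.stats.nbinom` tails at larger counts.

**Sidedness.** The two-sided p-value is `min(1, 2·min(P(Y ≤ y|x),
P(Y ≥ y|x)))`, with the observed `y` included in both tails. Including
the observed point keeps the discrete test valid (conservative). At a
per-gene mean of 100 tags the exact type-I error at the nominal 5% level
is 0.0460 (computed by enumeration over the Poisson lattice and confirmed
by 10⁶-draw Monte Carlo); the shortfall from 0.05 is the usual
discreteness cost.

**Asymmetry.** Conditioning on the library-A count makes the test not
exactly symmetric under swapping (x, y): at equal depths, (x=0, y=1)
gives p = 1 while (1, 0) gives p = 0.5. This is a property of the
conditional (posterior-predictive) construction itself, not of the
implementation; the discrepancy between the two orientations vanishes as
counts grow (the suite asserts convergence), and the probability mass
function itself is exactly symmetric. Library A is therefore always the
conditioning side; swapping the libraries maps up-regulated calls to
down-regulated ones, which the suite verifies on decisive calls.

## Quantification and the DEG rule

RPKM is `10⁹·C/(N·L)` with `N` the recomputed library total. The
reported effect size is `log2(RPKM_B/RPKM_A)`; when exactly one RPKM is
zero the ratio is a signed-infinity sentinel, unless a pseudocount is
supplied (`pseudo > 0` adds the same constant to both RPKMs). No default
pseudocount is imposed: published tables of this kind sometimes print
finite ratios for zero-count genes, implying an undocumented floor, and
guessing one silently would change every borderline call.

A gene is called **up** when `FDR ≤ fdr_max` (default 10⁻³) and
`log2 ratio ≥ min_abs_log2` (default 1), **down** symmetrically, **ns**
otherwise. FDR is Benjamini–Hochberg step-up (via
`statsmodels.stats.multitest`) over all testable genes. Genes with zero
counts in both libraries carry no information under the conditional law
(their p-value is identically 1), so they are excluded from the
multiple-testing family and reported with `p = FDR = 1`; leaving them in
would inflate the BH denominator by an arbitrary amount of dead weight.

Report columns round half-away-from-zero (1.55 → 1.6, −1.55 → −1.6),
the convention of the published tables this mirrors, rather than
banker's rounding.

## Term enrichment

For one namespace (GO or KEGG, handled independently): the universe `N`
is every gene with at least one assignment in that namespace, `n` the
DEGs among them, and for each term `M` / `m` its genes and DEG members.
The enrichment p-value is the exact upper tail `P(X ≥ m)` of
Hypergeometric(N, M, n), delegated to `scipy.stats.hypergeom.sf(m−1, …)`
and cross-checked in the suite against brute-force rational summation.
Including the observed `m` in the tail is what reproduces published
contingency-table p-values exactly; the strict tail `P(X > m)` does not.
Q-values are BH across the namespace's terms. GO terms are flagged on
raw `p ≤ 0.05` and KEGG pathways on `q ≤ 0.05`, mirroring the two
different gates in common pipeline practice; both thresholds are
arguments, and both p and q are always reported so the gate is auditable.
Terms with no DEG member are reported with `p = 1`, never dropped.

## qPCR quantification

`2^−ΔΔCt` with `ΔCt = Ct_target − Ct_reference` per sample and
`ΔΔCt = ΔCt_sample − ΔCt_calibrator`. Replicate Ct values are averaged
arithmetically before differencing (the Livak convention; averaging
folds instead would bias the estimate upward), and the replicate SD
propagates into a `delta_ct_sd` column as the root-sum of the target and
reference variances. The calibrator is a required argument — it is an
experimental design choice, not something to infer from data — and its
own fold is exactly 1. Amplification efficiency is assumed to be a
perfect doubling per cycle; no Pfaffl-style efficiency correction is
applied.

## The synthetic generator

`simulate_pair` emulates the data structure the exact test assumes:

* **Baseline abundance** — relative abundances drawn from a gamma with
  shape 0.7 and normalised to sum to 1. The small shape gives the
  long-tailed profile of a real transcriptome, where a minority of genes
  carries most of the tags; `expression_shape=None` switches to a flat
  profile (every gene equal), the right null for calibration studies
  because each gene then has identical, moderate coverage.
* **Depths** — defaults of 10⁶ tags over 5,000 genes keep the per-gene
  coverage (~200 tags) of the tens-of-millions-of-tags libraries this
  mirrors, at a scale where a full simulate–test–enrich round trip takes
  seconds.
* **Planted signal** — a `de_fraction` subset of genes (default 5%) gets
  `±log2_fc_magnitude` (default 2, i.e. four-fold) applied to its
  library-B abundance, signs equiprobable. Library B is deliberately not
  renormalised afterwards: non-DE genes stay exactly null, while the
  realised depth drifts a few percent from nominal — absorbed downstream
  because library totals are always recomputed from counts.
* **Noise** — independent Poisson per gene per library, matching the
  test's own model; an `overdispersion` knob (gamma–Poisson mixing)
  exists for robustness experiments but defaults off, because the first
  question is whether the test behaves under its own assumptions.
* **Lengths** — uniform in 200–3,000 bp, used by RPKM but, by default,
  not in count means (a tag count model); `length_weighted=True` switches
  to length-proportional sampling.
* **Terms** — 50 terms with sizes uniform in 40–160 genes, members drawn
  without replacement; planted terms (default 2) sample members with
  10:1 odds on DE genes, giving an expected DE share of
  `odds·f/(odds·f+1−f)` ≈ 0.34 at f = 0.05. The 40-gene lower bound is
  the realistic pathway-size scale and matters for recovery: planted
  terms much smaller than that cannot show reliable enrichment once the
  undetectable low-abundance DE genes are discounted.

One integer seed drives everything; count and term generation use
independent child streams (`default_rng([seed, k])`) so each operation
is individually reproducible.

### What passing the synthetic suite does and does not show

The generator matches the test's assumptions (independent Poisson, known
lengths, exhaustive annotation). Real libraries violate them in known
ways: biological replicates show overdispersion, tag-to-gene mapping is
ambiguous, annotation is incomplete and structured (GO terms are nested,
which this flat model ignores), and library composition shifts can
masquerade as differential expression. Recovery and calibration results
here therefore validate the implementation, not the biology: they show
the chain computes its model correctly, not that the model is adequate
for any particular data set.

## Problem sizes and numerical choices

Calibration runs in the suite use 20 seeds × 10,000 null genes at depth
10⁶ (200,000 p-values pooled); recovery uses 10 seeds of the default
5,000-gene configuration, with sensitivity measured over planted genes
whose mean count is at least 50 — below that, a four-fold change is not
reliably distinguishable from Poisson noise at an FDR of 10⁻³, and no
test could recover it. Tail sums terminate when the next term falls
17 orders of magnitude below the accumulated total; normalisation of the
conditional law is asserted to 10⁻¹², oracle agreement to 10⁻¹⁰
relative. Ties in enrichment output order are broken by term id, and no
stage uses randomness outside the generator, so every pipeline run is
byte-reproducible from its config.

## Known limitations

* No replicate-aware inference: one library per condition is the design
  this targets; with replicates, use a negative-binomial framework
  (DESeq2, edgeR) instead.
* No GO DAG propagation; terms are flat sets.
* The Audic–Claverie conditional test is asymmetric at very small counts
  (above); results tables always state which library was A.
* RPKM only; no TPM/TMM alternatives.
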