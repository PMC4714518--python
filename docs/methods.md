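# Methods

This note records the models, conventions and numerical choices behind the
package, in the order a user meets them.

## Experimental design model

The unit of analysis is a 12-generation temperature-shift experiment:
generations `15C-G1..G3` (15 °C), `23C-G1..G6` (23 °C) and `p15C-G1..G3`
(back at 15 °C), for two genotypes (wild type and the *hrde-1* mutant,
which lacks the germline nuclear Argonaute of the nuclear RNAi pathway).
Generation labels are a closed vocabulary and determine the temperature.
mRNA-seq is available in two biological repeats, antisense small-RNA-seq
in one, and Pol II / H3K9me3 ChIP-seq for six profiled generations
(`15C-G3`, `23C-G2/G4/G6`, `p15C-G1/G2`).

For differential calling between temperatures, generations within a
temperature block act as replicates (`G15 = 15C-G1..G3`,
`G23 = 23C-G2..G6`). This is a deliberate simplification: successive
generations are not i.i.d. biological replicates, and any genuinely
transgenerational signal inflates the within-block variance estimate,
making the calls conservative rather than anti-conservative. `23C-G1` is
excluded from the heat block because those animals experienced both
temperatures (the shift happens during embryogenesis); the `p15C`
generations are excluded to avoid carry-over from the heat exposure.

## Quantification

RPKM = count / (library total / 10⁶) / (feature length / 10³). RNA
libraries (mRNA, small RNA) are normalized by summed exon length; ChIP
libraries by full gene length. Small-RNA counting is strand-aware and
antisense to the gene; mRNA counting is sense. A tag overlapping k genes
increments all k — the data give no basis for fractional assignment, so
the simplest reproducible rule is used and documented. All internal
coordinates are 0-based half-open (BED convention); GFF3 input is
converted on read.

## Differential expression

The NB machinery is a from-scratch implementation of the classic
exact-test workflow:

* **Size factors** — median over all-positive genes of the ratio to the
  per-gene geometric mean, rescaled so the geometric mean of the factors
  is 1 (fixes the arbitrary common scale; makes worked examples
  deterministic).
* **Dispersion** — per-gene method of moments within each group,
  `α̂ = (v − m)/m²` on size-factor-normalized counts, pooled across groups
  by degrees of freedom; then `α = max(α̂, trend(μ))` where the trend is
  the parametric form `α(μ) = a₀ + a₁/μ` fitted by least squares to the
  **unclipped** gene-wise estimates with one outlier-trimmed refit
  (±4 robust SD). Fitting unclipped estimates matters: they are roughly
  unbiased at every mean, whereas flooring before fitting bends the trend
  upward at high means and silently destroys power for exactly the
  highly expressed genes. The conservative `max` sharing rule means no
  gene's dispersion is shrunk below its own estimate. Floor: 10⁻⁸.
* **Exact test** — conditional on the total `K = k_A + k_B` of the two
  group sums; the p-value sums the probabilities of all splits no more
  likely than the observed one, normalized by the probability of the
  condition. Group sums are NB with mean `q·S_g` (pooled per-unit mean ×
  summed size factors) and variance `μ_g + α q² Σ_j s_j²` — the sum of the
  per-sample NB variances, so the effective dispersion of a group sum
  scales like α/n. Enumeration is exhaustive up to K = 20,000 and windowed
  (±12 conditional SD) beyond, where the excluded mass is far below the
  precision of any reported p. α = 0 degenerates to Poisson.
* **FDR** — Benjamini–Hochberg step-up, `q₍ᵢ₎ = min_{j≥i} m·p₍ⱼ₎/j`,
  capped at 1.
* **Calling** — heat-induced: fold(G23/G15) ≥ 2 and q ≤ 0.1; heat-repressed
  mirrored; computed per biological repeat and intersected ("in both
  repeats"); a union mode exists behind `require_both_repeats=False`.
  Fold changes at zero means add a 0.5 pseudocount to both means (ratio
  only); raw means are reported alongside.

### The gene-set cascade

NHG = heat-induced in the mutant minus heat-induced in WT. High-stringent
NHG = NHG with ≥2-fold mutant-over-WT expression at 23 °C in both repeats;
the FDR threshold is applied there too by default for symmetry with every
other call (`hs_require_fdr=False` gives the raw fold filter — the
published description mentions only the fold requirement, so both are
provided). HRDE-1-repressed sets are computed per temperature block, and
the 23 °C-unique set removes genes shared with either 15 °C block. The
set identities (`nhg = mut \ wt`, `hs ⊆ nhg`,
`unique = 23C \ (15C ∪ p15C)`) hold by construction and are asserted in
tests on every run.

## Interval statistics

* **Overlap fraction** F: a query region counts as overlapping if it
  shares ≥1 bp with any annotation interval extended by the flank
  (0/500/1000 bp) and clipped at chromosome ends. Annotation intervals are
  merged first, so F is invariant to interval order and overlap structure.
* **Monte Carlo null**: random regions of fixed length 2,920 bp (the mean
  NHG size; an empirical-length mode samples query lengths instead) with
  the chromosome drawn proportionally to its length and the start uniform
  in `[0, L − len]` — regions never cross chromosome ends, avoiding length
  bias. Default 100,000 draws. The reported p is the plain frequency
  `(# null F ≥ F_obs)/n_sims`, printed as `< 1/n_sims` when zero; no
  pseudocount is added. Assembly gaps, GC and mappability are deliberately
  not modeled.
* **Calibration device**: for a discrete statistic the plain frequency p
  is super-uniform and lumpy under its own null (with 30 regions F takes
  31 values), so uniformity checks use the standard tie-randomized
  add-one p, `(# beyond + U·(1 + # tied))/(n+1)`, exposed as
  `randomized_empirical_p`. Analyses always report the conservative plain
  frequency; the randomized form exists only to make calibration testable.
* **Arm/center partition**: autosome arms are the outer quarter on each
  end, the center the middle half; the X chromosome is split in two at 1/6
  of its length (which of its two parts is "arm" is left unlabeled — the
  package reports both occupancies). Genes are assigned by midpoint,
  boundaries half-open toward the chromosome start, so a midpoint exactly
  on the quarter boundary belongs to the center. Expected counts are
  proportional to all-gene occupancy; the test is chi-square with
  regions − 1 degrees of freedom.
* **Chromosome depletion**: fold = expected/observed fraction of set genes
  on the chromosome (∞ reported when the observed count is zero — a lower
  bound); p is the fraction of same-size uniform draws with a count at or
  below the observed one, which converges to the hypergeometric lower
  tail (asserted in tests at three simulation sizes).

## Rank tests and trends

The one-sided Wilcoxon rank-sum test uses exact enumeration of all
`C(n, n_x)` midrank assignments when the combined sample size is ≤ 16
(always available via `exact=True`), and otherwise an Edgeworth-corrected
normal approximation: the 2nd–4th central moments of the midrank sum are
computed exactly from finite-population sampling identities (ties
included), and skewness/kurtosis feed a two-term Edgeworth correction on
top of the continuity-corrected normal CDF. Worst absolute error against
exhaustive enumeration is ≈0.006 for group sizes 4–8, versus ≈0.015 for
the plain continuity-corrected normal.

"Cumulative" transgenerational activation is not formalized in the source
experiments; the operationalization here is scale-free monotonicity plus
an effect-size guard: Spearman rank correlation of expression against the
generation index over `23C-G1..G6`, one-sided p < 0.05 (exact permutation
p for n ≤ 8), **and** a ≥2-fold span from the first to the last heat
generation (pseudocount 0.1). Persistence at a post-stress generation
means expression ≥ 2× the 15 °C baseline mean — the same fold convention
as the DE cutoff. Both thresholds live in `TrendConfig`.

Gene-set shift tests (e.g., Pol II ratios of NHGs vs all genes) use the
one-sided Wilcoxon on per-gene generation ratios
`(RPKM_num + c)/(RPKM_den + c)`, c = 0.1 RPKM. The background defaults to
all genes outside the set; whether an expression floor should restrict the
background is left to the caller.

## siRNA phases

Phases I–IV are the consecutive 3-generation blocks of the design. Phase
means are size-factor-normalized means over the block; per-phase
mutant-vs-WT calls reuse the NB exact test with the block's three
generations as replicates (2-fold, FDR ≤ 0.1; a Wilcoxon fallback is
available). Cross-tabulation against mRNA-level calls reports the 2×2
table, overlap fractions in both directions, and an upper-tail
hypergeometric enrichment p. Box summaries for user-supplied target lists
(e.g., coIP-derived target sets, which are consumed as plain gene-id text
files and never bundled) use numpy's linear-interpolation quantiles.

## Synthetic data generator

The generator emulates the structure — not the sequence content — of the
real experiment. Defaults: 2,000 genes on six chromosomes (~8.5 Mb, one
chromosome flagged X), gene length ~N(2920, 600²) bp clipped to
[800, 8000], NB counts with constant dispersion α = 0.1 (variance
μ + αμ²) and a per-library lognormal depth factor (σ = 0.2). Baseline
expression is lognormal (median 60, σ_log = 1.2); genes carrying a planted
effect have their baseline floored at 50 counts so that class recovery
measures the caller, not the sequencing depth. Planted classes (fractions
of the 2,000): WT-heat-inducible 1.5 % at 8-fold, heat-repressed 1 %,
plain NHG 3.5 % (expressed in WT, mutant silent at 15 °C and activated
8-fold at 23 °C — mutant/WT ≈ 1 at 23 °C, so they are *not*
high-stringent), high-stringent NHG 1.5 % (silent in WT throughout;
mutant 8-fold at 23 °C, hence mutant/WT ≈ 8 there, matching the reported
median ΔmRNA of 8.0 vs 1.0), cumulative NHG 0.3 % (×1.5 per heat
generation, decaying ×0.5 per post-stress generation — the expected means
cross the 2-fold persistence threshold at exactly p15C-G1 and G2),
constitutive HRDE-1-repressed 1 % (4-fold at both temperatures),
siRNA-loss 2.5 % (5-fold antisense siRNA loss in the mutant from the
first heat generation onward, placed off the X chromosome to emulate the
X-depletion of siRNA-responsive loci). The transition generation 23C-G1
gets half of any temperature effect on the log scale. LTR intervals cover
0.4 % of the genome; 35 % of NHG-family genes get an LTR planted inside
the gene body, the rest of the budget is placed uniformly. Pol II means
track mRNA means (×0.25, floored); H3K9me3 is high on nuclear-RNAi target
classes, HRDE-1-dependent, with a mild (×0.7) reduction at 23 °C.

One RNG stream per output file is derived from the master seed by stable
hashing of the file's role, so adding an output never perturbs existing
ones; equal seeds give byte-identical trees.

What the generator does **not** model: read-level data, positional
coverage, mean-dependent dispersion, batch effects, correlated
generations, partial penetrance of effects, or gene-length biases in
counting. Passing recovery tests therefore demonstrates the correctness
and calibration of the calling machinery under its own assumptions, not
performance on real libraries.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the full synthetic
experiment (2,000 genes), 20 (suite) or 5 (script) null-only simulations
for false-call rates, 100,000-draw Monte Carlo association nulls,
500 × 2,000 calibration draws, and 200 trend replicates — sizes chosen so
the complete set finishes in minutes on one CPU while keeping every
assertion comfortably away from its sampling noise.

## Known limitations

* No numerical parity with any specific DESeq release is promised; parity
  is at the level of the calling rules and set arithmetic.
* Treating generations as replicates (above) is a modeling convention, as
  in the original analysis design.
* The Monte Carlo association null ignores assembly gaps and
  sequence-composition matching.
* The high-stringent filter's FDR requirement is a package default where
  the published rule is ambiguous; both behaviors are available.
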