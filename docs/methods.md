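# Methods

## Scope and model overview

`lepcodon` implements a desk-scale analysis chain for coding-sequence
evolution under the joint action of mutation bias, GC-biased gene
conversion (gBGC) and codon usage preferences. Bases are partitioned into
strong (S = G/C) and weak (W = A/T); every substitution or mutation is
S→W (GC-decreasing), W→S (GC-increasing) or GC-conservative (S→S and W→W
pooled). The standard nuclear genetic code is the default everywhere and
is injectable (`GeneticCode(table_id)`), since the target taxa are
nuclear CDS.

## Alignment QC

The filter cascade operates on in-frame codon alignments: (1) discard
alignments with non-terminal stop codons or gap runs whose length is not
a multiple of 3; (2) remove codon columns with strictly more than 50%
gap codons across lineages (whole codons, preserving frame); (3) after
trimming, reject alignments where any lineage has >50% missing codons
(gap or fully ambiguous, codon units), where the mean per-sequence gap
fraction exceeds 25% (nucleotide units — the two rules are stated in
different units deliberately), or shorter than 300 bp; (4) after rate
estimation, drop genes with dS > 30 (saturation) or ω ≥ 999 (no
synonymous changes). The length rule is applied to the trimmed
alignment, since the filter targets what is actually analyzable.
Filtering is idempotent and column order is preserved; both properties
are tested.

## Codon usage statistics

RSCU(codon) = k·n_codon/Σ_family n with k the family size; families with
zero usage yield NaN (flagged, not dropped silently). ENC_obs follows
Wright's homozygosity formulation; for short genes a missing 3-synonym
class (Ile) is imputed as (F̄₂+F̄₄)/2 and any other missing class as the
mean of estimated classes, Wright's convention. Genes where some F̄ ≤ 0
(e.g. a single family observed as counts (1,1)) are undefined and
excluded rather than producing divergent 1/F̄ terms. ENC values are
clamped to [20, 61] after evaluation.

The ENC_exp curve is a + GC₃ + b/(GC₃² + (c−GC₃)²). The default
constants (a = 6, b = 34, c = 1.025) are simulation-optimized for the
lepidopteran composition range; with them the unclamped curve exceeds 61
over mid-range GC₃, so the clamp is active there — ENC_diff is then
measured against the ceiling, which preserves ranking of bias strength
though not its absolute scale. Wright's classic constants (a = 2,
b = 29, c = 1) are available via `ENCConfig.wright_classic()` and are
used in the null test that composition-only genes have mean
ENC_diff ≈ 0, because the classic curve is the one that tracks the
composition-only expectation across the GC₃ range. Per-lineage usage
tables pool counts before computing frequencies (not means of per-gene
frequencies).

## Substitution-category counting

The heavyweight approach to category-specific rates is probabilistic
mapping under a codon model; `lepcodon` instead uses a transparent
counting approximation, chosen so every number is checkable against
enumeration oracles:

* ancestral codon states by Fitch parsimony on the fixed topology;
  ties broken uniformly at random under an explicit seed (recorded), or
  masked in strict mode;
* columns with any gap/ambiguous/stop leaf codon are masked entirely
  (the mapping tools this approximates do not handle missing data
  either);
* parent→child codon changes decomposed over all stop-free orderings of
  single-base steps, averaged with equal weights (Nei–Gojobori pathway
  convention); pairs whose every ordering crosses a stop are skipped;
* opportunities: each of a codon's nine single-base neighbors
  contributes 1/3 site to its (effect × direction) cell; changes to
  stops are excluded from counts and opportunities alike;
* d_c = N_c/L_c per cell, dN/dS/ω from the syn/nonsyn margins, computed
  per branch and aggregatable over genes.

This estimator is accurate at low divergence (multiple hits at one site
are collapsed by parsimony) and its absolute scale is not comparable
with codeml- or mapping-based estimates; only relative and ordinal
patterns are. Simulation tests bound the regime: at branch lengths
≤ 0.1 subs/site the recovered totals track the generator's event ledger
and a planted 3:1 S→W mutation bias is recovered as a median synonymous
rate ratio within [2.7, 3.3].

## gBGC–mutation–drift equilibrium fit

The expected unfolded SFS at sample size n for a class with scaled
mutation intensity θ and conversion coefficient B (semidominant, fixed
across sites) is

    E_i(θ,B) = θ C(n,i) ∫₀¹ x^i(1−x)^{n−i} · (1−e^{−B(1−x)})/((1−e^{−B}) x(1−x)) dx,

with the analytic neutral limit θ/i taken below |B| < 1e−8. W→S derived
alleles experience +B, S→W −B, conservative 0. The public
`expected_sfs` evaluates each bin by adaptive quadrature
(`scipy.integrate.quad`, epsrel 1e−10); the fitting loop uses a cached
256-node Gauss–Legendre grid (`sfs_shape`), which agrees with the
adaptive path to ~1e−15 relative for these smooth, bounded integrands
(asserted in tests). B is restricted to |B| ≤ 10 in the fit; `expm1` is
used throughout for numerical stability.

Likelihood: independent Poisson bins, three classes sharing per-bin
distortion nuisances r_i (demography/ascertainment absorption),
normalized to mean 1. The conservative class has B = 0, so it anchors
the r_i; θ and r carry a joint scale degeneracy that the normalization
fixes (B and λ are invariant to the choice; θ values are reported under
mean(r) = 1). Optional polarization error e mixes each expected
spectrum with its frequency-reversed image, (1−e)E_i + eE_{n−i}.

Optimization is coordinate ascent with every step monotone: closed-form
θ updates (θ̂ = Σc/Σ r·shape), closed-form r updates, and a profiled
bounded 1-D search over B (and e when requested); convergence when the
log-likelihood changes by < 1e−10 relative, typically < 10 iterations
and ~30 ms at n = 20. Two starts (B₀ = ±0.5) guard against sign ridges.
On noise-free expected counts the fit recovers the generating (B, λ, θ)
exactly (tested to 1e−3), i.e. the estimator is unbiased at the MLE
level and residual test error is sampling noise.

λ is defined per site: λ = (θ_SW/L_S)/(θ_WS/L_W), with L_S/L_W the
monomorphic strong/weak site counts of the degeneracy class, computed
from the reference CDS by default (a genome-wide normalization is a
caller choice — pass different L values).

Bootstrap: segregating sites are resampled with replacement jointly
across classes (multinomial over all bins at fixed total), L fixed;
percentile CIs at 95%; seed recorded; >5% failed refits sets a warning
flag.

Polarization uses two outgroup alleles and parsimony: the ancestral
allele must match both outgroups (or the single available one in
relaxed mode); discordant or non-matching outgroups leave the site
unpolarized and counted. Site degeneracy is taken from the ancestral
codon context; only 0-fold and 4-fold sites enter the bias analysis
(2- and 3-fold sites are excluded, as their S/W content is entangled
with the amino acid). Sites with missing genotypes are hypergeometrically
projected to the common n (seeded); sites below n are dropped.

## tRNA repertoire

tRNAscan-SE 2.x tables are parsed tolerantly (header block, minus-strand
rows given as inverted coordinate pairs, "pseudo"/"trunc" notes);
malformed rows are skipped and counted. RAIT uses family size = number
of synonymous codons of the amino acid, mirroring RSCU's expectation,
not the number of represented anticodons. Anticodon→codon equivalence is
the plain reverse complement; wobble pairing is not modeled (noted in
outputs). GC3 of codon equivalents is copy-weighted by default with a
per-unique-anticodon alternative, and outlier anticodons (single
anticodons exceeding twice the next-largest copy number, e.g.
repeat-driven expansions) can be excluded via a toggle.

## Synthetic data: what it emulates and what it does not

The generators define the study conditions:

* **Alignments** — 8 taxa on a fixed tree with branch lengths
  0.04–0.09 subs/site, 300-codon genes, root composition GC₁ = 0.51,
  GC₂ = 0.39, GC₃ = 0.47 (butterfly-like). Evolution is a per-codon
  Gillespie process with per-cell rate multipliers and stop avoidance;
  site-independent, no indels, no codon autocorrelation, no
  composition heterogeneity along the gene. Passing tests therefore
  demonstrate correctness of the counting machinery, not robustness to
  alignment error or rate heterogeneity in real data.
* **Polymorphism** — spectra drawn Poisson-per-bin from the model's own
  expected SFS (no coalescent, no linkage); this tests estimator
  self-consistency and calibration, not robustness to demography — the
  r_i terms absorb demographic distortion by construction, and a planted
  shared distortion is verified to leave B and λ recoverable. 4-fold
  conditions: 1e6 sites, GC 0.45, per-weak-site W→S intensity 0.01
  (≈1% synonymous diversity), B = 0.46, λ = 2.96. 0-fold conditions:
  6e6 sites (0-fold sites outnumber 4-fold ≈2× in CDS), intensity
  0.002 (≈5× reduction by constraint), B = 0.56, λ = 2.73. Sample size
  n = 20 chromosomes (10 diploids). Site counts are set at the scale of
  a genome-wide resequencing data set, which is what such analyses use.
* **VCF/GFF/FASTA fixtures** — a miniature single-chromosome genome
  whose emitted files re-parse into the identical planted site table
  (round-trip property, including a minus-strand gene and full
  polarization inversion at e = 1).
* **tRNA tables** — planted copy numbers with pseudo/truncated decoys
  and an optional outlier.

Identical seeds give byte-identical fixtures; every generator's truth
ledger is sufficient to verify the downstream estimates without hidden
state.

## Numerical and design choices

* Degeneracy convention: a position with no synonymous alternative is
  reported as 0-fold (not 1); Ile's 3-fold class is kept distinct and
  excluded from 0-fold/4-fold contrasts.
* Gap/ambiguous codons are masked (not errors) in GC and usage
  computations, matching alignment-trimming semantics.
* ENC family homozygosity requires n ≥ 2 per family; scale invariance
  holds to <0.1 ENC units for family counts in the hundreds (the
  (n−1)⁻¹ correction decays as 1/n).
* Parsimony tie-breaks, bootstrap draws and genotype projection all
  consume explicit seeds; reruns are bit-identical.
* The sw-ratio summaries exclude (and count) branches with a zero or
  undefined W→S denominator.
* The pipeline (`report.run_pipeline`) persists every intermediate as
  TSV/JSON so all reported numbers are recomputable from artifacts.

## Known limitations

* Parsimony counting underestimates multiple hits; do not compare its
  absolute dN/dS with codon-model estimates (two published scales
  already disagree with each other for the same data; this is a third).
* The equilibrium SFS model assumes a stationary base composition and a
  single B per class; GC-stratified or nonequilibrium variants are out
  of scope, as are demographic inference and DFE estimation beyond the
  r_i absorption.
* ENC_diff under the default constants saturates where the clamp binds;
  cross-composition comparisons of its absolute value should use the
  classic curve.
* The wobble-free anticodon→codon map overstates the specificity of the
  tRNA pool; RAIT comparisons across families with heavy wobble use are
  correspondingly coarse.
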