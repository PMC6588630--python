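# Methods

This note records the models, the parameter choices that matter, what the
synthetic generators do and do not emulate, and the numerical decisions a
maintainer would want to know.

## Gene mining

The search stage is a self-contained translated homology search: six-frame
translation of each contig, exact amino-acid 4-mer seeds against the query
panel, diagonal clustering of seeds, and gapped Smith–Waterman extension
(BLOSUM62, gap open 11 / extend 1) over the clustered window. E-values use
the Karlin–Altschul gapped parameters for BLOSUM62-11-1 (λ = 0.267,
K = 0.041) with search space m × n (query length × total translated
length). The default cutoff is 1e-10; externally produced 12-column
tabular hits can be imported instead and are filtered at the same cutoff.

Hits on the same contig and strand merge when they overlap or lie within
`max_gap = 5000` bp; merged loci shorter than 200 nt are discarded. Gene
models extend the locus by `flank = 10000` bp per side (clipped at contig
ends) and align the best query to the oriented DNA with a frame-aware
dynamic program: per query residue the path consumes 3 nt (codon; an
in-frame stop scores −10 and is recorded as a nonsense disruption), 2 or
4 nt (frameshift, penalty 15, recorded), or 0 nt (query deletion, linear
penalty 11, as are extra codons in the DNA). Consecutive frameshifts
within 3 codons merge into one event. Gene models are intronless by
design; spliced real-genome models should be imported. Classification:
any disruption → pseudogene; else coverage ≥ 0.9 of the query with no
contig-edge evidence → intact; else truncated. The contig-edge flag is
set when the aligned CDS ends within two codons of a contig boundary.
`max_gap`, `flank`, and the 0.9 completeness threshold are configurable;
they are reasonable spans for intronless teleost receptor loci and are
echoed in output headers.

Family verification accepts a protein only when its best-scoring
reference under the same local aligner carries the target-family label;
score ties are rejected.

## Phylogenetics

Distances are Poisson-corrected protein distances, d = −ln(1 − p), with p
the mismatch fraction over columns where neither sequence is gapped
(pairwise deletion). p = 1 flags the pair saturated; neighbor joining
refuses saturated matrices unless overridden. NJ is the classical
algorithm with Q-matrix ties broken by the label-sorted smallest pair (so
topology is input-order invariant) and negative branch lengths clamped to
zero. Bootstraps resample alignment columns; support is the percentage of
replicates containing each split of the point tree. The default is 100
replicates (configurable), a desk-scale compromise; published analyses
commonly use 1000.

Column information content is IC = log₂20 − H over the 20-letter
alphabet, gaps excluded from column counts and no small-sample
correction (one is deliberately not applied by default because the
choice materially shifts absolute IC; comparisons between gene sets are
unaffected). Subfamily assignment walks rootward from the query on the
combined NJ tree to the first pure reference neighborhood; mixed
neighborhoods fall back to the nearest reference by distance, with ties
left unassigned.

`project_to_reference` is a deliberately lightweight alignment for
synthetic pipelines: each sequence is globally aligned to one reference
(end gaps free) and projected onto the reference's columns, dropping
insertions. It is not a substitute for a multiple aligner on deeply
diverged data.

## Duplication–loss reconciliation

The LCA mapping embeds the gene tree in the species tree; a gene node is
a duplication iff a child maps to the same species node, and losses are
counted from mapping-path depth differences, each loss attributed to the
species branch where the lineage died. A duplication mapped to species
node s counts as a gain on the branch leading to s. Copy numbers
propagate from a single lineage entering the embedding root, so
`child = parent + gains − losses ≥ 0` holds on every branch by
construction; species nodes above the embedding root carry count 0.
Duplication and loss costs default to 1/1 (configurable); rooting can be
fixed or chosen to minimize total cost over all gene-tree rootings, ties
broken by the lexicographically smallest root edge. Correctness is
checked against an independent exhaustive species-labeled dynamic program
on random instances (≤ 6 species, ≤ 10 genes). Support-threshold
rearrangement of weak gene-tree edges is out of scope.

## Gene conversion

Monomorphic and gap-containing columns are removed; per pair the
statistic is the maximal run of identical polymorphic sites (the default
infinite mismatch penalty; a finite penalty switches to maximal-scoring
segments under +1/−penalty). The null permutes the condensed columns
jointly across sequences; pairwise p-values use the (x + 1)/(n + 1)
correction and the global p is the permutation tail of the across-pair
maximum, which handles multiplicity exactly under the shared null.
Because an integer run-length statistic ties heavily at the permutation
maximum (making the test strongly conservative), the comparison statistic
adds the fragment's physical span scaled into [0, 1) as a deterministic,
permutation-exchangeable tie-breaker; reported fragment scores remain the
plain run lengths. Null calibration at nominal 5% lands near 4–5%
rejection over tract-free star-tree simulations.

## Repertoire–ecotype statistics

- χ² on the 2×2 table uses the Pearson statistic without continuity
  correction by default — the convention consistent with the printed
  p = 0.0009 for the 53/25412/21/23021 table — with Yates available.
- The family-size ratio test is a two-sided one-sample *t* of the ratio
  distribution against a reference value, also reporting where the
  reference sits empirically.
- PCA is centered (not scaled) SVD; variance explained sums to 100% and
  loadings expose which subfamilies drive separation.
- ANOSIM rank-transforms all pairwise Euclidean distances (mean ranks on
  ties); R = (r̄_between − r̄_within)/(M/4), M = n(n−1)/2; p by label
  permutation with the +1 correction (default 999 permutations). Verified
  against scikit-bio's implementation in the test suite.
- Ecotype grouping treats species without the fright reaction —
  ostariophysan or not — as one "lacking" group, overridable.

## Phylogenetic logistic regression

The response is the binary ecotype, the predictor the intact-gene count
(the cited binary-trait framework requires the binary variable as the
response, so that orientation is implemented). The mean is logistic in
the standardized predictor; phylogenetic dependence enters as a working
correlation exp(−α·d) in patristic distance with the tree scaled to unit
height. β is estimated by GEE-style Fisher scoring (lightly ridged) at
each α on a profile grid {0.25 … 64}; α maximizes the Gaussian
pseudo-likelihood of standardized residuals. Large α gives the identity
correlation, so on a star tree the estimates coincide with ordinary
logistic regression (verified against statsmodels). The slope p-value is
a parametric bootstrap of the fitted intercept-only null: binary data are
drawn through a Gaussian copula with the null mean and correlation and
the full model is refit per draw — this keeps the test calibrated at 13
species, where Wald asymptotics are unreliable (type-I error ≈ 5% in the
suite). Complete separation falls back to a strongly ridged fit with a
flag. The reported AIC is the independence binomial log-likelihood at the
estimates plus 2(k + 1) — a pseudo-AIC, comparable across fits of this
package only.

## Codon models

The GY94 generator assigns rate π_j × {1, κ, ω, ωκ} to single-nucleotide
{synonymous transversion, synonymous transition, nonsynonymous
transversion, nonsynonymous transition} changes. Codon frequencies
default to F3X4 from the alignment (F1X4/F61/uniform available, +1
pseudocount on position-specific nucleotide counts). Transition matrices
come from the eigendecomposition of the reversible symmetrization, cached
per (κ, scale, ω) — which makes mixing-proportion updates nearly free
during optimization.

Branch lengths are taken from the input tree up to one free scale factor;
class rate matrices are normalized against the ω = 1 matrix at the
current κ, preserving relative rates between site classes while the
overall rate is absorbed by the scale. The scale is estimated under M0
and then fixed for the other models (re-estimation available). Site
likelihoods mix over classes (M7/M8 use K = 10 equal-probability beta
bins represented by bin means); optimization is L-BFGS-B on transformed
parameters (log/logit; ω₂ = 1 + e^x enforces the ≥ 1 bound) with random
restarts, relative lnL tolerance 1e-9, and warm starts embedded from the
nested null model — which also guarantees the nesting inequality
lnL(alt) ≥ lnL(null) numerically. Branch-site model A has the standard
four classes with ω₂ on the foreground branches; the null fixes ω₂ = 1
and the alternative starts ω₂ at 1.5.

NEB conditions site-class posteriors on the MLEs. BEB averages them over
a uniform 10-point grid per free mixing proportion, weighted by each grid
point's data likelihood, with the ω parameters held at their MLEs — the
grid covers the mixing parameters, which dominate the posterior
uncertainty that NEB ignores.

The simulator draws a class per site and evolves codons down the tree;
with a foreground branch set, foreground matrices share the background
normalization so elevated-ω classes genuinely accelerate the foreground
branch rather than being re-scaled away. On boundary data (e.g. M8 fit to
M8a-simulated alignments) the (p₀, ω_s) profile is a ridge: the ω_s point
estimate is weakly identified even at 5000 codons, and the meaningful
recovery statement — made by the tests — is that the M8-vs-M8a LRT stays
non-significant.

## Expression statistics

FPKM = count × 10⁹/(length × library size) with library size = total
counts and effective length = annotated length (no fragment-length
correction). The activity filter keeps genes with FPKM > 1 in at least
⌈half⌉ of the samples. TMM trims 30% of M and 5% of A against a
reference sample (most-typical upper quartile), weights by inverse
approximate variance, and renormalizes factors to geometric mean 1.
Rank-sum tests are exact for m + n ≤ 20 without ties, otherwise normal
with tie and continuity corrections. The published differential-expression
call (edgeR's NB test at fold change ≥ 2, adjusted p < 0.05) is
approximated by |log2FC| ≥ 1 plus BH-adjusted rank-sum p < 0.05; the
headline contrasts (receptor set vs rest, on levels and on absolute
before/after changes) are rank-sum tests implemented exactly.

## Synthetic data: what it does and does not emulate

Generators are pure functions of seed and parameters and always emit
machine-readable truth. Planted genes are back-translated (uniform codon
choice, avoiding codon-bias confounds) amino-acid-mutated copies of a
seed protein; pseudogenes get one nonsense substitution (sparing the
terminal codons, where a stop disrupts nothing detectable) or a 1–2 bp
indel; truncated genes hang off a contig end; intergenic background is
uniform random sequence. Real assemblies differ in ways the generator
deliberately ignores: introns, repeats, base composition, segmental
duplications, assembly gaps and sequencing error — so passing recovery
tests demonstrates the pipeline's logic, not robustness to real-genome
artifacts. Family evolution is a per-branch birth–death process recording
realized events, so the per-branch conservation identity holds by
construction; same-branch duplication-loss pairs are invisible to
parsimony, which bounds recovery at low rates. Expression counts are
negative-binomial with log-normal baselines and a planted fold change.

## Problem sizes

Default test and acceptance runs use desk-scale sizes chosen as the
package's own study conditions: 100 mining seeds at 4 kb contigs with
1.5 kb flanks, 200 reconciliation oracle instances, 500 tract-free
gene-conversion simulations (100 permutations each), M0 recovery at 5000
codons on 4 taxa, 50 branch-site null simulations at 300 codons on 5
taxa, 500 phylogenetic-regression replicates at 13 tips with 99 bootstrap
draws, and 200 ANOSIM null simulations. The acceptance script uses the
same conditions at moderately reduced replicate counts.

## Known limitations

- No maximum-likelihood tree search; the NJ engine plus an import path
  for externally built ML trees.
- Gene models are intronless; splice-aware prediction is out of scope.
- GENECONV's outer-sequence fragments and bit-exact output are not
  reproduced; nor is codeml bit-compatibility — likelihood-level
  equivalences are tested instead.
- The duplication/loss cost ratio and rooting policy change real-data
  event counts; defaults (1/1, minimize) are stated in every output.
- The phylogenetic regression's working-correlation form exp(−α·d) is a
  modelling choice; other decay families would give similar but not
  identical fits.
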