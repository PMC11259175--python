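# Methods

This note documents the statistical procedures, the synthetic-data
generator, the numerical choices, and the limitations of `ohnoscope`.

## Collinear block detection

Homology hits are first restricted to the standard filter: self-hits
removed, (query or subject coverage > 50 %) and E ≤ 10⁻⁵, and at most five
subjects per query (ties in E broken by higher bitscore, then subject id).
Anchors — homologous gene pairs mapped to (rank_a, rank_b) gene-order
coordinates per scaffold pair — are chained by dynamic programming. A chain
extends between anchors when ranks advance strictly monotonically on both
sides (increasing/increasing for same-orientation blocks,
increasing/decreasing for inverted) and the rank gap on each side is at most
`max_gene_gap` (default 25). The chain score is the anchor count minus a gap
penalty of one per skipped gene beyond the first (on the worse side of each
link). Overlapping chains are resolved greedily by descending score,
removing assigned anchors; equal scores prefer same orientation, then the
lexicographically smallest chain, making results deterministic and directly
comparable to the exhaustive-search oracle used in the tests. Chains shorter
than `min_block_genes` (default 5) are discarded.

Duplication categories are assigned by precedence: WGD/segmental (block
anchor) > tandem (a homolog at the adjacent rank) > proximal (a homolog with
fewer than 20 intervening genes) > dispersed (any remaining homolog) >
singleton. The precedence order follows the established duplicate-gene
classifier conventions; intervening-gene counts are rank differences minus
one.

## Ka/Ks estimation

Pairs are aligned at the protein level (global alignment, match +1,
mismatch −1, gap open −2, extend −0.5) and back-translated to codons; gap
columns are excluded. The Nei–Gojobori counting method is used: per-codon
synonymous site fractions (changes to stop codons count as nonsynonymous),
sites averaged over the two sequences, differences averaged over all
minimal mutation paths (paths through stops excluded unless all paths hit
one), and Jukes–Cantor correction `K = -3/4·ln(1 - 4/3·p)` applied to both
proportions. Estimates with p ≥ 3/4 are flagged saturated and excluded from
the mixture fit; ω = Ka/Ks is reported as missing (neither 0 nor ∞) when
Ks = 0. The counting method replaces maximum-likelihood codon models
deliberately: it is dependency-free, exactly checkable against a
path-enumeration oracle, and adequate at the low divergences where a recent
WGD peak lives. ML estimates would differ slightly at high divergence,
which is outside the window used below.

The redundant pairwise Ks values within each homologous cluster are
consolidated by average-linkage hierarchical clustering on Ks distance;
each merge node contributes one value (the merge height, i.e. the mean Ks
of the pairs it joins), so a cluster of n genes yields n−1 values.

## Ks mixture model

Gaussian mixtures with k = 1..4 components are fitted by EM (k-means
initialization, 10 restarts, fixed seed) to Ks values inside
[0.001, 3.0] — the conventional window that excludes near-zero alignment
artefacts and saturated estimates. Model selection minimizes
AIC = 2(3k−1) − 2·logL; at least 50 usable values are required. The
detected WGD peak is the dominant low-Ks component.

## Differential expression

The experiment is a 2×2 design (lifestyle × temperature) with ≥ 2
replicates per condition; the four contrasts are symbiotic-vs-free at each
temperature (L-28, L-34) and 34-vs-28 within each lifestyle (T-Fr, T-Sy).
The engine is a self-contained re-implementation of the standard NB GLM
approach:

- size factors by median-of-ratios (reference = per-gene geometric mean
  over samples, genes with any zero excluded; library-size fallback when no
  such gene exists);
- genes pre-filtered to ≥ 5 reads in ≥ 25 % of samples;
- per-condition means fitted by Newton iteration on the log scale with
  size-factor offsets (a cell-means parametrization — the four condition
  means are the parameters, so every contrast is a difference of two
  coefficients);
- gene-wise dispersion by Cox–Reid adjusted profile likelihood (the 0.5·log
  determinant of the information, which factorizes over conditions),
  maximized on a 25-point log grid over [10⁻³, 10], then shrunk 50/50 on
  the log scale toward a lowess trend of dispersion on mean — the usual
  compromise between per-gene noise and a common trend at n = 3;
- Wald tests on the contrast with a t reference at the residual degrees of
  freedom (samples − conditions), a small-sample correction that keeps the
  null type-I rate near nominal at three replicates;
- BH correction across genes within each contrast. A gene is DE when
  FDR < 0.01 and |log₂FC| > 1.

Pairs enter the group classification only if both copies have ≥ 10 raw
reads in ≥ 50 % of all samples. Group rules, applied in order on the sets
D(g) of contrasts where each copy is DE: both empty → 1; exactly one
empty → 2; a shared contrast with opposite directions → 5; a shared
contrast with the same direction → 3; otherwise (both DE, disjoint
contrasts) → 4. Opposing behaviour outranks parallel behaviour because a
single opposing comparison is the defining event; group 4 requires strictly
disjoint contrast sets. Pair expression correlation is Pearson's r on
log₂(FPKM+1) across all samples.

## Expression specificity (τ)

FPKM = count / (effective library / 10⁶) / (length in kb), with effective
library = size factor × mean raw library size. τ is computed on condition
means of log₂(FPKM+1) (replicates averaged; four conditions):
τ = Σᵢ(1 − xᵢ/x_max)/(N−1), 0 for uniform expression, 1 for expression
confined to one condition. Genes qualify when max log₂(FPKM+1) > 1.
Category comparisons use Kruskal–Wallis and pairwise Wilcoxon rank-sum
tests (normal approximation with continuity correction) under Holm
adjustment. Preference of categories for discrete levels (e.g. coexpression
modules, peak conditions) uses Pearson's chi-square with per-cell
standardized residuals (obs − exp)/√(exp(1−row/N)(1−col/N)) and
Bonferroni-adjusted two-sided normal p-values per cell.

## Differential exon usage

Gene models are flattened into disjoint counting bins split at every
distinct exon boundary across isoforms. Relative usage (bin reads / gene
reads, per sample) is compared between the two conditions of a contrast
with a quasi-binomial score test: pooled proportions per condition, score
statistic on the binomial scale divided by a per-gene overdispersion factor
estimated from within-condition Pearson residuals, referred to
F(1, df_within). Per gene, the minimum bin p is Šidák-combined
(1 − (1 − p_min)^m) and BH-corrected across genes; a bin is flagged only
when its gene passes (default 0.05) *and* |Δusage| > 0.1 — the effect-size
floor avoids flagging trivially small shifts in high-count genes. Per-pair
summaries report overall DEU (Σ|Δusage_A − Δusage_B| over matched bins) and
the proportion of DEU (significant matched bins over all bins of the pair;
unmatched bins enter the denominator only).

## Splice-junction conservation

Junctions live at different loci in the two copies, so identity is defined
by sequence, not coordinates: the 300-bp upstream and downstream flanks of
each event are extracted (truncated flanks flagged), and a junction in one
copy is conserved with one in the other only when *both* flanks align
significantly (local alignment; E ≤ 10⁻⁵ from the Karlin–Altschul formula
E = K·m·n·e^(−λS), λ solved from the ungapped stationary equation for the
+1/−2 nucleotide scoring and K fixed at 0.1 — a deliberately conservative
constant, since only the threshold crossing matters). Candidates resolve
one-to-one by best combined score. The both-flank rule is what prevents
spurious matches between neighbouring junctions that share one exon of
sequence. Binary presence/absence profiles over the union of junction
identities feed Kendall's τ-b (undefined and flagged for constant
profiles) and an exact two-sided binomial test with k = junctions only in
copy A, n = junctions in exactly one copy, p₀ = 0.5 — one admissible
reading of "diverged in total junctions", chosen because it is symmetric
and exact at small n.

## Pathway retention

An enzyme identifier within a pathway is uniquely retained as ohnolog
(singleton) when every gene encoding it is WGD/segmental (singleton); mixed
enzymes count to neither. Per isolate, each pathway's unique-ohnolog vs
unique-singleton split is tested one-sided (Fisher exact, equivalent to the
hypergeometric tail) against the genome-wide counts of annotated ohnolog
and singleton genes, BH-corrected across pathways. A pathway is *retained
in duplicate* only when it has ≥ 5 uniquely retained enzymes and FDR < 0.05
in both isolates; with a single isolate the verdict is withheld.

## Synthetic-data generator

The genome generator emulates a haploid genome after a recent WGD: each
ancestral scaffold is duplicated wholesale, duplicated copies survive with
probability `wgd_retention` (default 0.85; losses are deleted outright with
rank compaction — no pseudogene remnants, matching what a gene-level
pipeline can observe), and surviving pairs are mutated so their synonymous
divergence concentrates at Ks ~ N(0.30, 0.05) — a narrow, recent peak.
Synonymous and nonsynonymous substitutions are planted at distinct codon
positions with expected counts given by the Jukes–Cantor forward formula,
so the counting estimator recovers the target without tuning (Ka = 0.2·Ks).
Small-scale duplicates (tandem/proximal/dispersed, default 2 % per gene
each) diverge at background Ks ≈ 1.5. Genes default to 420 codons in 3–4
exons of ≥ 310 bp with 120-bp introns; exons are kept longer than the
300-bp junction flank so that flanks of neighbouring junctions do not share
sequence, keeping junction identity well defined in the generator (real
genomes violate this; see Limitations). Synthetic homology hits cover every
within-family pair with scores passing the standard filter.

The expression generator draws NB counts (dispersion 0.05, library factors
log-normal with σ = 0.15, 3 replicates per condition, base mean 100) with
planted per-condition mean shifts of |log₂FC| = 3 implementing the five
groups: a shift in one condition cell induces DE in the two contrasts that
involve that cell; group 4 uses the two diagonal cell pairs, whose induced
contrast sets are disjoint. Default group fractions
(0.35/0.35/0.12/0.12/0.06 for groups 1–5) reflect the observed dominance of
no-DE and one-copy-DE pairs after WGD. A fraction (default 0.1) of
non-pair genes is made strictly condition-specific (τ → 1); 30 % of pairs
receive an exon-usage swap of 0.5 relative usage in one copy in the
symbiotic/34 °C cell; each ancestral intron yields a junction shared by
both copies with probability 0.7, otherwise present in exactly one.

Everything is driven by a single `numpy` Generator per simulator, so equal
seeds give byte-identical outputs.

### What the generator does not emulate

Read-level noise (mapping ambiguity, positional bias), isoform-level
quantification, genuinely overlapping gene models, repeat content,
pseudogene remnants of lost copies, GC/codon-usage heterogeneity,
correlated expression noise between conditions, and junction flanks that
share sequence across neighbouring junctions. Passing the recovery tests
therefore demonstrates correctness of the statistical machinery under the
stated model, not robustness to the full messiness of real RNA-seq and
real gene structures.

## Problem sizes used in the test suite

The recovery tests run at the scales the analyses are designed for while
staying desk-sized: ~240-gene genomes for shared fixtures, a 600-ancestral-
gene genome (~500 surviving pairs) for group-label and junction-conservation
recovery, 2000 genes for the DE null/power simulation, and 100 seeded
repeats for mixture-model selection. Percent-level thresholds in those
tests (≥ 90 % pair recovery, ≥ 80 % group recovery, ±0.05 junction
conservation, type-I within 0.03–0.07) are the generator's study
conditions, fixed before measurement.

## Known limitations

- The NB Wald test with t reference is a pragmatic small-sample correction,
  not an exact likelihood-ratio or quasi-likelihood F test; at n = 2
  replicates it will be less well calibrated than at n = 3.
- The DEU score test treats bins within a gene as independent given the
  per-gene dispersion; strongly negatively correlated bins (few bins per
  gene) make the Šidák combination conservative.
- Karlin–Altschul significance uses ungapped λ with a fixed K; absolute
  E-values are approximate, only the threshold behaviour is relied on.
- The mixture model uses plain Gaussians on Ks; log-normal or gamma
  components can fit long right tails better when the background of old
  duplicates dominates.
- ω aggregates are reported per pair with their mean; no branch-specific
  or site-specific selection inference is attempted.
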