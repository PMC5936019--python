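# Methods

## Coordinates and domain types

All loci are 1-based inclusive intervals (the GFF/GTF convention of the
input files); lengths are `end − start + 1`. A lncRNA must be ≥ 200 nt,
the defining cutoff of the class. Strandless records are rejected at
parse time rather than guessed: antisense classification is meaningless
without a strand. FPKM values are accepted as given — the package does
no re-normalization, and FPKM estimation is out of scope.

## Differential expression and symbol calling

For a contrast (numerator, denominator) the fold change is

    log2FC = log2((mean_treat + c) / (mean_ctrl + c)),   c = 1 FPKM

computed on the raw FPKM means. The pseudocount bounds the fold change on
zero-expression features; it also implies that a true multiplicative
effect on a weakly expressed feature appears compressed (see the
generator notes below). The calling rule is exactly the three-way
partition: `+` iff log2FC ≥ 1 and q ≤ 0.05, `−` iff log2FC ≤ −1 and
q ≤ 0.05, else `=`; both thresholds inclusive and configurable.

**Significance testing.** Three routes, all ending in per-contrast
Benjamini–Hochberg correction (delegated to
`statsmodels.stats.multitest.multipletests`):

- *Moderated t (default).* With two replicates per treatment a
  per-feature test is hopeless: the Welch statistic at n = 2 has ~1
  effective degree of freedom, and in our reference simulation fewer than
  5% of genuine 4-fold effects survive BH at q ≤ 0.05. The standard
  remedy in small-n expression analysis is to share variance information
  across features. We implement the empirical-Bayes moderated t of the
  limma lineage: per-feature residual variances s²_g (pooled, d_g = n₁ +
  n₂ − 2 df) are shrunk toward a scaled-F prior (d₀, s₀²) fitted by
  method of moments on log s², and the t statistic uses the shrunk
  variance with d₀ + d_g degrees of freedom. The implementation is
  cross-checked against Bioconductor limma (`lmFit`/`eBayes`) in the test
  suite to rel. 10⁻³.
- *Welch t* on log2(FPKM + c), available per feature (`test_feature`) and
  as `method="welch"`; kept for designs with more replicates.
- *Supplied q.* An external table (`feature_id`, `q`, optional verbatim
  `log2fc`) overrides internal testing; the package then contributes only
  the thresholding and symbol logic. This is the recommended route when a
  dedicated DE engine has already been run.

Degenerate variance — every replicate identical in both groups — yields
p = 1 when the means agree (no evidence of change) and p = 0 when the
data are noise-free but shifted.

## Annotation

Antisense: same chromosome, opposite strand, overlap ≥ 1 bp
(`overlap = min(ends) − max(starts) + 1`); adjacency is not overlap.
Flanking: a non-overlapping gene within the window (default 2000 bp,
inclusive), labelled upstream/downstream relative to the *gene's* strand,
the upstream side being the 5′ promoter side; the lncRNA's own strand is
ignored. Distances use the coordinate-difference convention
(`gene boundary − nearest lncRNA boundary`, i.e. gap + 1), matching the
"located N bp upstream" phrasing used when such relations are reported;
`distance_convention="gap"` switches to pure gap counting. Same-strand
overlap is recorded as `overlapping_sense` but belongs to no accounting
class.

For class accounting each annotated lncRNA is assigned to exactly one
class with precedence **antisense > flanking**, making the class counts
disjoint so they sum to the annotated total (the published per-class
totals sum exactly, implying disjointness). Gene counts are unique per
class; the overall target-gene total is the sum of the two per-class
counts, so a gene targeted both ways is counted in each class. All pair
records — including flanking records of antisense-class lncRNAs — are
retained in the detailed output.

The production path uses per-chromosome sorted gene lists with a bisect
window; the test suite checks it against a literal all-pairs restatement
of the rules on random fixtures, plus shift-invariance and
window-monotonicity properties.

## Duplex model

The duplex stage nominates interacting regions of an antisense pair; it
does not reproduce Turner-parameter thermodynamics or accessibility. Two
strands pair antiparallel; each GC, AU or GU pair scores −3, −2, −1
(user-overridable); consecutive pairs may be separated by a bulge or
internal loop of at most `max_loop = 15` unpaired bases per strand,
costing `loop_open (4) + loop_extend (1) × unpaired`; stacked pairs cost
nothing extra; intramolecular structure is forbidden. Energies are
therefore in declared arbitrary units, not kcal/mol, and published
figure-caption energies are treated as format illustrations only (their
units are unstated and the sequences unavailable).

`hybridize` minimizes total energy by DP over "last pair = (i, j)"
states; the affine loop cost separates as
`E + open + ext·((i−i′−1) + (j′−j−1))`, so each row's predecessor minimum
reduces to a windowed minimum over a transformed matrix `G = E − ext·i +
ext·j`, giving O(n·m·max_loop) with vectorized rows. Reported intervals
are the outermost pairs of one optimal duplex, ties broken toward the
smallest (gene_start, lnc_start) among traced optima. The independent
oracle `brute_force_hybridize` enumerates every legal pair set
(unmemoized recursion, guarded to n·m ≤ 200) and must agree exactly on
energy; interval swap-symmetry under exchanging the strands is asserted
on instances whose optimum is unique (verified by counting optimal pair
sets), because lexicographic tie-breaking is not swap-invariant when
distinct co-optimal duplexes exist.

## Memory typing

Typing reads exactly two contrasts, (D1, C1) and (D2, D1) — the second
stress is compared against the first, not against the control. The nine
(s1, s2) pairs map onto the eight named classes plus `none` for (=, =);
features differentially expressed in neither contrast are excluded from
the eight classes. Percentages are reported against the memory-class
total for the four memory classes (matching the way the dominant
`[+/−]` share is quoted) and against all typed features for the
non-memory/late-response classes. Rounding is half-up at the printed
precision (two decimals for headline expressed-fractions, one decimal
elsewhere).

## Synthetic-data generator

The generator emulates the study conditions: 18 chromosomes (paired
a/b naming), a gene set with ~10% never-expressed members, 200 lncRNAs
by default with length 200 + Exp(300) nt capped at 2000 (skewed short),
~28% of lncRNAs annotated (13% antisense, 15% flanking) and the rest
unlinked, two replicates per treatment, planted effects of
±2 log₂-units applied at the C1→D1 and D1→D2 steps according to a memory
mix in which `[+/−]` dominates the memory classes and half the lncRNAs
are null, R1 returning to baseline, and multiplicative log-normal
replicate noise `FPKM × 2^ε`, ε ~ N(0, 0.2) — the conventional bulk-FPKM
noise approximation. Baselines are log-normal (log₂ mean 4, sd 1.5).

Geometry is slotted: one gene per 12-kb slot, genes 1–3 kb, flanking
lncRNAs placed at a uniform-random planted distance in [1, 2000] on the
planted side, antisense lncRNAs fully inside their partner gene on the
opposite strand, unlinked lncRNAs in gene-free slots. The wide margins
guarantee the annotator recovers every planted relation exactly and that
no accidental relation can arise. Antisense transcript pairs carry an
embedded 40–80 nt reverse-complementary window, so their duplex energy is
strictly negative.

Planted-effect lncRNAs draw their baseline from the same log-normal
*truncated below*: under the 1-FPKM pseudocount, the hardest pattern — a
second consecutive down-step, b·2^−e → b·2^−2e — only shows
|log₂FC| ≥ 1 when b ≥ 2^e/(1 − 2^{1−e}) (8 FPKM at e = 2). Planted
effects are thereby at or above the calling threshold by construction;
at effect size exactly 1.0 no baseline satisfies this, so repeated-down
effects sit on the calling boundary and are not guaranteed recoverable.

What the generator does **not** model: read-level sampling (no FASTQ),
splice isoforms, mean–variance trends (noise sd is constant across
features, which flatters the moderated t's variance pooling relative to
real data), gene-level treatment effects, correlated replicates, or
polyploid subgenome structure beyond chromosome naming. Passing recovery
tests therefore demonstrate correctness of the calling/typing logic under
the declared noise model, not performance on real libraries.

## Recovery baselines

With noise-free replicates and ground-truth q-values the pipeline
recovers 100% of planted memory types (including `none`). At the
reference conditions — 200 lncRNAs, rep_sd 0.2, effect 2.0, seed 1 —
internal moderated testing recovers 95%, frozen as the regression
baseline; the residual misses are down-steps whose truncated baseline
lies near the detectability floor, where replicate noise can push the
observed fold change just inside ±1. Recovery is monotone non-increasing
in rep_sd and non-decreasing in effect size (checked on a 3×3 grid at a
fixed seed). A per-feature Welch test at the same conditions recovers
~50%, which is why it is not the default.

## Determinism and problem sizes

Every stochastic component is driven by one integer seed through
`numpy.random.default_rng`; fixture writing includes sha256 checksums and
re-runs are byte-identical. Stage outputs are sorted by feature or
(lnc_id, gene_id) keys. The shipped test and acceptance problem sizes —
≤ 200 lncRNAs, oracle sequences of 3–12 nt, 50 random annotation
fixtures — were chosen so the exhaustive oracles stay exact while the
full suite runs in seconds.
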