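# Methods

This note documents the models and algorithms implemented in `mitopop`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## The comparability problem and the core reference

Yeast mitogenomes (20–90 kb, circular) resist whole-molecule multiple
alignment for two reasons: intergenic spacers are repetitive and almost
pure AT (uninformative and unalignable), and gene/pseudogene content
varies between strains. The package's central object is therefore a
*core reference*: the protein-coding regions present in every genome of
a panel, concatenated in reference-coordinate order.

Presence is decided generously: a gene counts as present if the genome
annotates it **or** if a similarity search finds its sequence. The
search is seed-and-extend — exact 11-mer seeds voted onto diagonals on
both strands, with the best diagonal windows refined by affine-gap local
alignment (match +1, mismatch −1, gap open −2, extend −1; the extension
stage runs on Biopython's C pairwise aligner with exactly this scoring).
A hit is accepted at ≥80% query coverage and ≥70% identity; ties go to
the leftmost start, then the + strand. The thresholds are deliberately
permissive — the search exists to rescue genes hidden by sparse
annotation, while genes whose DNA is truly absent must fail. Both
thresholds are exposed in `RunConfig`. k = 11 keeps seeding cheap at
mitogenome scale while tolerating the divergence seen between strains.

Regions are fixed by the reference CDS extents (exons only; intronic
columns never enter the core). Minus-strand genes are
reverse-complemented into the concatenation, so the core is uniformly
coding-strand. Overlapping CDS extents keep both genes with the overlap
trimmed from the downstream one. 3′-variable gene ends are *not*
trimmed: length variation shows up as ordinary alignment variation or
N-fill. Circular genomes are linearized at the annotated origin;
origin-spanning features carry a wrap flag.

## Alignment, missingness, imputation

Each sample's core material is aligned to the reference per region with
a global affine aligner (match +1, mismatch −1, open −4, extend −1; N
neutral) and projected onto reference columns: sample insertions are
dropped from the matrix (and counted in a side report), reference
deletions appear as `-`. This replaces progressive multiple alignment
deliberately — coding regions are conserved, and column identity with
the reference is what every downstream coordinate needs. A sample whose
projected row matches the core at under 50% identity (gaps counting
against) is excluded with a warning.

Missingness semantics: `N` (unread) is missing; `-` is an observed
deletion and is **not** missing. Samples with missing fraction *strictly
greater* than 10% are dropped — exactly-10% survives; the strict reading
of "more than 10%" is asserted in tests.

Remaining `N`s are imputed from an NJ guide tree built on pairwise
p-distances (pairwise deletion). For each `N`, the 5 nearest non-N
leaves by tree path length vote; a strict majority base is imputed, and
ties or fewer than 3 informative neighbours leave the `N` in place.
Gap-majority votes never overwrite an `N` (a deletion is not a base
call). Neighbour count and quorum are configurable; 5/3 balances local
phylogenetic signal against noise at desk-scale sample sizes.
Imputation never changes an observed cell.

## Diversity and neutrality statistics

Conventions follow the classic treatment of haploid, phased mitotypes:

* a column is polymorphic iff ≥2 distinct bases of {A,C,G,T} are
  observed (N and `-` ignored); each unordered allele pair is classified
  transition (A↔G, C↔T) or transversion, so a triallelic A/G/T site
  contributes one transition and two transversions;
* haplotyping uses complete deletion (columns with any N or `-` removed
  before comparing rows); k and π use pairwise deletion. Both choices
  are documented because neither is canonical; they interact only in the
  presence of missing data.
* gene diversity `Hd = n(1−Σp²)/(n−1)` with Nei's sampling variance; the
  variance of k is Tajima's total variance `b₁k + b₂k²`,
  `b₁ = (n+1)/(3(n−1))`, `b₂ = 2(n²+n+3)/(9n(n−1))`; π's standard error
  is sd(k)/L.

Tajima's D uses the 1989 constants. Two p-values are computed: the beta
approximation on `[D_min, D_max]`, and (given a seed) the conditional
simulation p from neutral fixed-S coalescent replicates at the observed
n and S (default 10,000). The calibration experiment in the acceptance
suite measures both on 1,000 neutral datasets (n = 50, θ = 5): the
simulation p rejects at close to nominal rates, the beta p is mildly
conservative — consistent with that approximation's known behaviour.

Fu's Fs: `S′ = Pr(K ≥ k_obs | θ = k)` under the Ewens sampling formula,
computed exactly with unsigned Stirling numbers of the first kind in
rational arithmetic for n ≤ 200 (beyond that, by the sequential Ewens
construction), and `Fs = ln(S′/(1−S′))`. The p-value simulates 1,000
neutral coalescent replicates at θ = k and recomputes Fs on each
replicate with its own estimated θ, exactly as on data. The test is
anti-conservative at face value — the conventional 5%-level rejection
region is `p < 0.02` (rejecting at `p < 0.05` has roughly twice the
nominal size). The package reports the raw p; the calibration
experiment applies the conventional 5%-level region.

Hudson's Fst between groups is `1 − Hw/Hb` with Hw the unweighted mean
of the two within-group mean pairwise differences (sample-size weighting
by flag) and Hb the between-group mean, pairwise deletion throughout.
Negative estimates are reported as computed; they are clamped to zero
only when a matrix feeds NJ tree building, which needs distances.

## LD, blocks, Rm, and the recombination landscape

Phase is known (homoplasmic isolates), so haplotype counts are direct.
Sites enter LD/structure analyses if biallelic with minor-allele
frequency *strictly above* 10% (multiallelic sites are first reduced to
their two most frequent alleles; others become missing).

For a site pair, D, D′ = |D|/D_max and r² use the textbook formulas on
jointly non-missing samples. The 90% interval on D′ comes from a
0.001-grid scan of the multinomial likelihood of |D′| (allele
frequencies fixed at their estimates), reading the cumulative 5% and
95% bounds; the interval is widened, if necessary, to contain the point
estimate (the 5% quantile of |D′| can exceed an ML estimate of exactly
zero). Blocks follow confidence-interval rules — strong LD: CI low
≥ 0.70 and high ≥ 0.98; strong recombination: CI high < 0.90; a
candidate span needs a strong-LD outermost pair and ≥95% strong-LD
informative pairs inside, accepted greedily by decreasing span.

Rm is the Hudson–Kaplan bound: four-gamete-incompatible site pairs
define open intervals; the sort-by-right-endpoint greedy scan yields a
minimal disjoint set of intervals whose count is Rm. On simulations the
bound never exceeds the logged number of realized recombination events
(tested), and is typically far below it.

The relative recombination landscape replaces an MCMC-based
per-interval rate estimator with a composite likelihood. A two-locus
sampling-probability table is simulated once per (n, rho-grid): for each
rho in {0, 0.5, 1, 2, 4, 8, 16, 32, 64}, two-locus coalescent replicates
conditioned on one mutation per locus yield haplotype-configuration
frequencies, stored by canonical configuration (invariant to allele
relabelling and locus exchange) with add-half smoothing. Table sample
size defaults to n = 24 with 20,000–40,000 replicates per grid point —
small enough that the configuration space is densely estimated, the
binding constraint on the table's usefulness.

A design lesson is recorded here because it shaped the estimator: the
likelihood of a *single* pair's configuration is nearly flat in rho (its
argmax lands on the top grid values a fifth of the time even at rho = 0),
so a per-adjacent-pair argmax cannot rank intervals reliably. The
implemented estimator therefore pools: for each adjacent-SNP interval,
every pair within 14 sites and 1,000 bp that crosses the interval
contributes its table likelihood evaluated at a candidate per-kb
intensity scaled by the pair's physical distance (geometrically rounded
onto the table grid); configurations are subsampled to the table's n and
averaged over 5 seeded draws. The per-interval estimate is the argmax
per-kb intensity, and λ is that estimate over the genome-wide median
(unnormalized if the median is zero). Because the analysed columns are
coding-only, an intergenic hotspot falls inside the single interval
between its flanking genes' SNPs — matching the real pipeline, where
spacers never contribute columns, and explaining why haplotype blocks
end at gene boundaries.

## Population structure

Genotypes are 0 (major) / 1 (minor) — mitotypes are homoplasmic, so
haploid coding is the honest encoding. At exact 50/50 frequency ties the
alphabetically later allele is minor.

PCA: per-site centering by the observed frequency and scaling by
√(p(1−p)) (plain centering by flag); missing entries become 0 after
centering; coordinates are the SVD projections and variance fractions
the eigenvalue shares over all sample-space components (they sum to 1).
The outlier pass flags samples beyond 6 SD on any of the top 3 PCs,
removes them and reruns once — mirroring the single outlier-exclusion
rerun such analyses conventionally show; both the threshold and the
PC count are arguments.

Ancestry: one-hot-expanded frequencies (missing mean-imputed) are
factorized by minimizing `‖X − QG‖² + α‖Q‖²` with Q rows on the simplex
and G ≥ 0, α = 10. Both block updates are solved *exactly* by
active-set enumeration over supports (K ≤ 6 keeps that cheap): the Q
update is a simplex-constrained ridge least squares per row, the G
update a nonnegative least squares per column. Exact block minimization
makes the loss provably non-increasing, which a post-hoc projection
would not. Best of 5 seeded restarts, 200 iterations or relative change
< 1e-6. Limitation: on *unstructured* data the factorization still
splits within-population variance into archetypes, and the α penalty
favours uniform rows — one-hot "truth" is only a meaningful target for
well-separated populations.

Neighbor joining implements the Studier–Keppler Q-criterion with ties
broken by the smallest (row, col) index pair, standard branch-length
formulas, and negative lengths clamped to zero with a warning. NJ is
exact on additive matrices — the module's strongest oracle, exercised on
random additive trees. Group-Fst trees clamp negative Fst to zero and
exclude groups with fewer than two samples.

## The synthetic-data generator

The generator is first-class code, not a fixture file. Its coalescent
engine is a hand-written Hudson-style ancestral recombination graph:
lineages carry ancestral-material segments annotated with descendant
sample sets, a symmetric island model moves lineages between demes, and
a piecewise-constant rate map concentrates recombination where asked
(hotspot multipliers on intergenic intervals). Every recombination event
is logged with its breakpoint — the truth for Rm-bound and hotspot sign
tests. Time is scaled so one within-deme pair coalesces at rate 1;
mutations are infinite-sites at rate θ/2 per unit material-time, thinned
to at most one per base pair (two when triallelic sites are requested).
The engine is cross-checked against closed forms (Watterson's E[S],
Ewens' E[K]) and against msprime's island model via branch-mode
diversity ratios.

Migration is calibrated analytically: for two demes,
`E[Fst] = 1/(1 + 4m)` with per-lineage migration rate m, so a target Fst
maps to `m = (1 − Fst)/(4 Fst)`. The acceptance experiment verifies the
calibration empirically at targets 0, 0.05 and 0.15.

Realized genomes emulate what makes real mitogenomes hard: coding
composition A 30.95%, T 41.33%, C 13.09%, G 14.63% by default; spacers
as tandem 8-mer repeats at 99% AT; per-genome gene deletion (sequence
removed, coordinates shift) and annotation dropout (sequence kept,
feature dropped — the rescue case); admixed individuals built per site
from donor populations according to a known Q row; unread positions
injected as independent Bernoulli Ns with the mask returned for scoring.
The default gene layout (8 genes totalling 5,475 coding bp) matches the
scale of a real concatenated core; defaults for θ (38.6, the scale of
the observed mean pairwise differences) and background rho (20, high
recombination) reflect the data regime the methods target.

What the generator does **not** emulate: realistic mutational spectra
beyond a transition bias, indel evolution, selection, gene-order
rearrangement, sequencing-error structure, or non-equilibrium
demography. Passing the validation suite therefore demonstrates
correctness of the estimators under the stated models — not robustness
to every artefact of real sequencing data.

## Validation problem sizes

The acceptance experiments (also exported by `scripts/acceptance.py`)
use: brute-force agreement on ≤10×50 fixtures; neutrality calibration on
1,000 neutral replicates (n = 50, θ = 5; 300 inner replicates per
p-value); Fst recovery with n = 50/group, ~500 SNPs at high rho (150)
so the check measures estimator accuracy rather than single-genealogy
noise, averaged over 20 seeds per target; 100 random additive trees of
10–30 leaves; two-population fixtures with migration 0.005 (effectively
fully diverged — the regime where "0 PC1 errors" and one-hot ancestry
truth are well-posed); 50 hotspot replicates (n = 100, θ = 80,
background rho 16, one 10× spacer) against an n = 24 table with 40,000
replicates per grid point; and a 50×2000 coding alignment with 5%
injected Ns for imputation scoring. These sizes were chosen to keep the
full validation run to minutes on a single core while leaving each check
statistically meaningful.
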