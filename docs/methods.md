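# Methods

This note documents the models and procedures implemented in
`clonaltracer`, the assumptions behind them, the parameters that matter,
and the design choices made where the problem admitted several reasonable
answers.

## Data model

The central object is a cells × target-sites ternary genotype matrix:
1 = mutant call, 0 = reference call, NA = missing. Sites carry chromosome,
1-based position, uppercase ref/alt alleles, gene symbol, SNV/INDEL class
and an optional bulk VAF; cells carry a tissue label in
{paratumor, tumor, metastasis, other}. All somatic mutations are treated
as heterozygous and copy number is ignored: the analysis is purely about
presence/absence of each variant in each cell. Multi-allelic sites,
phasing, and calling genotypes from reads are out of scope.

## Noise model and ADO estimation

Single-cell whole-genome amplification loses alleles. We model dropout
per allele, independently, at rate `d`:

- true genotype 1 (het mutant): both alleles drop with probability `d²`
  (entry missing); the mutant allele alone drops with `d(1−d)` (observed
  0); otherwise observed 1. Note the reference allele dropping alone
  leaves the mutant observable, so among non-missing mutant entries the
  1→0 flip fraction is `d(1−d)/(1−d²) = d/(1+d)`.
- true genotype 0: observed 1 with false-positive probability `f`.
- afterwards, every non-missing entry is masked missing with probability
  `m` (site-level failures such as low coverage).

This is the simplest generative model consistent with the QC quantities
the data support (single-allele fractions at control sites, mutated-cell
fractions, missingness); amplification bias, doublets and read-level
error are deliberately not modelled.

ADO is estimated from a separate control matrix of sites known to be
heterozygous germline in every cell, where each call is an
allele-presence summary (`both` / `ref-only` / `alt-only` / `NA`). Under
the model the single-allele fraction among non-missing calls is
`h = 2d(1−d)/(1−d²) = 2d/(1+d)`, inverted as `d̂ = h/(2−h)`. Estimating
from control sites rather than somatic sites avoids circularity with
clone calling. `d̂` is monotone in `h` and lies in [0,1) for `h` in [0,1);
`h = 1` (every informative call single-allele) is outside the model's
support and returns the boundary value 1. At 10⁴ control observations the
estimator's bias is below 0.001 and its spread well inside ±0.02 (checked
in the test suite at d ∈ {0.05, 0.1, 0.2}).

VAF concordance is the Pearson correlation (Spearman available as an
option) between per-site tumor mutated-cell fractions and bulk VAF; under
purity 1 and the heterozygous diploid assumption the noiseless relation
is fraction = 2 × VAF exactly.

## Germline/artifact filtering

Paratumor cells are negative controls: sites whose mutated-cell fraction
among paratumor cells exceeds `max_paratumor_fraction` (default 0.1) are
removed as germline variants or recurrent artifacts. With very few
paratumor cells the threshold is granular (one positive call among nine
observed already exceeds 0.1), so negative-control panels of a few dozen
cells are recommended; the simulated scenarios use 10–50.

## Clone calling

No standard exists for grouping cells by "mutation combination" at panel
scale, so the package uses an explicit, auditable procedure: the distance
between two cells is the fraction of discordant calls among co-observed
(both non-missing) sites; pairs sharing fewer than `min_overlap` (default
5) sites are flagged unreliable and set to the maximal distance 1. Cells
are clustered by average linkage and the dendrogram is cut so that
clusters merge only at height strictly below `tau`; `tau = 0` therefore
yields singletons. Clusters with at least `min_cells` (default 5) members
become clones; smaller clusters are reported unassigned rather than
forced into a clone.

The default `tau = 0.1` comes from the noise model, not from tuning: at
`d = 0.1` two cells of the same clone disagree at a true-mutant site with
probability `2q(1−q) ≈ 0.165` where `q = d/(1+d)`, so with ~15–20 mutant
sites on a 60-site panel the expected within-clone distance is ≈ 0.05–0.06,
while clones separated by ≥ 6 private mutations sit at ≥ 0.1 before noise.
The threshold is exposed because panels and noise levels vary.

Clone consensus per site is the majority of non-missing member calls,
requiring at least `min_site_coverage` (default 0.5) of members observed;
ties and low coverage call reference, which deliberately biases against
inflating clone mutation sets with false positives.

## Perfect phylogeny, conflicts and virtual ancestors

The clone tree assumes every site's ancestral state is reference and each
mutation is acquired exactly once and never lost (no back mutation) —
adequate for a small somatic panel over one tumor's clones. Two sites are
incompatible with such a tree iff the clone consensus vectors show all
three patterns (1,0), (0,1), (1,1); noisy consensus calls can produce
such conflicts even though the idealized truth cannot. Conflicts are
resolved by greedily removing the site in the most conflicting pairs
(ties: lower mutated-cell fraction, then lexicographic site id) until
none remain; removals are logged, not silently absorbed, and the
alternative of probabilistic genotype correction was rejected as harder
to audit.

Construction threads each clone's consensus set through a prefix trie
from the empty root, with sites ordered by carrying-clone count
(descending, site id as tie-break) — a valid perfect-phylogeny order
because conflict-freeness makes the carrier sets of any one clone's sites
a containment chain. Chains of unobserved single-child trie nodes
collapse into multi-mutation edges, so the unobserved nodes that survive
are exactly the points where ≥ 2 sibling subtrees share mutations absent
from their parent: these become **virtual ancestor** nodes (an inferred
clone never sampled, such as a metastasis founder). A virtual node with a
single child is never created by construction, and the result is
invariant to clone input order. Every build is validated against the tree
invariants (single root, cumulative set = union of acquired sets along
the root path, disjoint acquired sets per path).

Mutation classification is pure set logic over observed clones, each
labelled by its majority tissue: trunk = carried by all clones;
tissue-private clonal = all clones of exactly one tissue and none of any
other (only defined when ≥ 2 tissues are present); tissue-shared =
carried in ≥ 2 tissues but not everywhere; subclonal = proper subset of
one tissue's clones; sites absent from the tree are unassigned.

## Substitution spectra

SNVs collapse onto the six pyrimidine-reference classes (COSMIC
convention); purine-reference pairs are reverse-complemented (A>T → T>A),
so classification is strand-invariant. INDELs and undefined pairs are
excluded and counted. Spectra are tabulated per clone-tree edge over the
mutations acquired on that edge, i.e. new relative to the most recent
ancestor. Trinucleotide (96-class) context is deliberately omitted: a
targeted panel carries no flanking-sequence information, and signature
decomposition is outside this package's scope.

## Maximum-parsimony cell tree

Cells become pseudo-sequences over the panel's SNV sites (alt base for 1,
ref base for 0, N for missing; INDEL sites are excluded since they have
no single-base state). Cells with more than `max_missing_fraction`
(default 0.8) N are excluded and logged. N is treated as the full state
set {A,C,G,T} in Fitch scoring, so missing data never forces a change —
the standard wildcard treatment rather than a fifth state.

Identical sequences are collapsed before the search and re-attached to
their representative afterwards as zero-length polytomy children. With at
most 9 unique sequences every unrooted binary topology is enumerated
(stepwise addition; (2k−5)!! trees) and a global optimum returned, ties
broken first-found in the fixed enumeration order. Above that, the search
is steepest-descent nearest-neighbor-interchange from a neighbor-joining
start tree on p-distances (pairwise deletion of N; scikit-bio's NJ), plus
seeded greedy stepwise-addition restarts (20 restarts up to 16 unique
sequences, 2 up to 40, none beyond — restarts matter most in the
weak-signal small-n regime, and the larger regime is where NJ is
informative). The seed controls only exploration order; the heuristic
score can never undercut the exhaustive optimum and matched it on ≥ 90%
of hard random 8-taxon instances in testing.

Branch lengths come from one deterministic most-parsimonious ancestral
reconstruction (lowest-state tie-break in the Fitch traceback):
length = changes assigned to the edge / alignment columns, i.e. the
nucleotide substitution rate per site, and edge lengths × columns sum
exactly to the parsimony score.

## Simulated study conditions

The generator's defaults emulate a targeted panel study: a 60-site panel,
a planted clone tree with a 10-mutation trunk and 3–5 mutations per other
edge, 50 cells per observed clone plus paratumor cells, `d = 0.1`,
`f = 0.005`, `m = 0.05`, 10% INDELs, and a T>A-dominant substitution bias
(0.08, 0.04, 0.14, 0.60, 0.08, 0.06 over C>A, C>G, C>T, T>A, T>C, T>G) —
the aristolochic-acid-like exposure pattern reported in liver tumors.
The noise rates are plausible mid-range values for targeted single-cell
genotyping rather than measurements of any particular sample. Tree shapes:
`linear` (a chain), `star` (either all clones off the root, or — when a
trunk is present — an observed founder hub from which the other clones
derive), `bifurcating` (observed clones as leaves of a balanced binary
tree whose internal ancestors are unobserved), and `custom` (explicit
edge list; node names starting with `anc` are unobserved). A single seed
drives named independent sub-streams per stage (tree, cells, noise,
control, bulk), so each stage is individually reproducible and a whole
run is bit-deterministic.

The two-tissue metastasis scenario fixes the quantities of interest —
trunk 10, metastasis-private clonal 3, one unobserved metastasis
ancestor — and gives the free private branches 5–7 mutations each so that
true clones are separated by more than the default `tau` at panel scale;
25 cells per clone and 30 paratumor cells.

What the simulation does *not* emulate: copy-number events and
loss-of-heterozygosity, doublets, amplification bias correlated across
sites or cells, site-specific error rates, and read-level artifacts.
Passing recovery benchmarks therefore demonstrates correctness of the
inference under the stated noise model, not robustness to everything real
data can do.

## Benchmarks and numerical choices

`evaluate_recovery` / `recovery_benchmark` score, per simulated dataset:
clone-assignment adjusted Rand index over all tumor cells (unassigned
cells count as singleton clusters, so abstention is penalized, not
rewarded), exact trunk-set recovery, virtual-ancestor-family recovery,
full topology recovery (equality of the families of cumulative mutation
sets), and ADO-estimator error. At the default conditions (4 planted
clones, 50 cells each, 50 seeds) mean ARI is ≈ 0.97 and trunk/virtual
recovery 100%; the acceptance script re-derives these at run time.
Problem sizes in the test suite (25 oracle alignments of 6 taxa × 20
columns, 100 random clone configurations of ≤ 8 clones × ≤ 30 sites,
25–50 simulation seeds) are chosen to exercise every code path while
keeping the whole suite around half a minute.

Degenerate inputs have defined behavior throughout: all-missing sites
report an undefined fraction; zero-variance concordance returns
undefined rather than a number; fewer than 4 unique sequences return a
degenerate star tree with a warning; an empty clone list is a warning,
not a crash; configuration errors (mutation totals exceeding the panel,
missing tissue assignments, invalid probabilities) fail fast with named
errors.
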