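# Methods

## The problem

Obligate bacterial endosymbionts of insects (and similar host-restricted
lineages) evolve fast and their genomes drift toward extreme A+T
richness. In multi-gene phylogenies both properties are poison:
accelerated evolution produces long branches, and the shared AT shift
produces convergent character states (homoplasy) across unrelated
lineages. Parsimony, distance methods and homogeneous likelihood models
then tend to pull the long AT-rich branches together — long-branch
attraction (LBA) with a compositional engine. `phylostrip` implements
the data-side countermeasures: site exclusion and character recoding
transforms that remove exactly the substitution classes this artifact
feeds on, plus a simulator and a small exact inference harness to
demonstrate, on known-truth data, which transforms break the artifact.

## The AT/GC site filter

The central transform classifies each nucleotide state into two
composition categories, A/T versus G/C. A column that contains states
from both categories could owe its pattern to a convergent G/C -> A/T
replacement in independently AT-shifted lineages; a column whose states
all sit inside one category cannot. The strict filter therefore removes
every column containing both categories; every substitution left in the
matrix is a within-category transversion (A<->T or G<->C), a class that
compositional convergence cannot generate.

Category membership: A, T and the IUPAC code W (A or T) count as A/T;
G, C and S (G or C) count as G/C. Every other ambiguity code, `N`, gap
and missing is uncategorized and can never trigger removal — the rule
concerns observed states only.

Because the strict rule discards a lot of signal, a relaxation series
re-admits columns whose *minority* category is carried by at most `k`
taxa, for k = 0..10 (11 matrices by default). Exceptions are counted as
minority-category taxa whoever they are — no taxon whitelist — which
makes k = 0 coincide exactly with the strict rule and makes retained
column sets nested in k. Under the equal-frequency assumption within
categories (see the simulator model below) the retained sites are
compositionally symmetric, so distances and parsimony scores computed
from them are free of the AT-convergence signal.

## Recoding transforms

* **RY**: A,G -> R and C,T -> Y. Only the within-class IUPAC codes R
  and Y pass through; any code straddling the purine/pyrimidine
  boundary (W, S, K, M, N, ...) carries no class information and maps
  to `?`. The `first_second` scope recodes first+second codon
  positions and removes third positions (output length 2/3 of input),
  the pairing in which the two treatments are conventionally applied.
* **dayhoff6 / dayhoff4 / hp**: amino acid residues are collapsed into
  the published groups — dayhoff6 (AGPST)(DENQ)(HKR)(FYW)(ILMV)(C);
  dayhoff4 the same with FYW+ILMV merged and C mapped to missing; hp
  the two-class hydrophobic/polar split (ACFGILMVW)(DEHKNPQRSTY). The
  target symbol of each group is its first-listed residue, keeping
  recoded files readable and NEXUS-declarable; the tables ship as a
  plain-text data file users can extend.

A recoding merges states, so per-column state diversity never
increases and constant columns stay constant. Note that the
*parsimony-informative* count can legitimately increase: two singleton
states falling into one class form a shared state. Property tests
assert the true monotone quantities, not the informative count.

## Slow-fast site stripping

Given a priori "unambiguously monophyletic" taxon groups, each column
gets an integer rate proxy: the sum over groups of (number of distinct
counted states within the group − 1). This equals the minimum possible
number of changes within each clade when the clade's internal topology
is unresolved and its ancestral state free; changes on the unresolved
background polytomy belong to no group and are deliberately not
counted (whole-tree parsimony on the star-with-clades tree would add
them). The oracle test therefore checks each group against exhaustive
parsimony over the group's own topologies. Stepwise exclusion at
descending integer thresholds (default: every integer from max−1 down
to 0) yields a nested series of matrices.

## Simulation model

Sites evolve independently on a rooted tree under Tamura's (1992)
two-parameter process: equilibrium GC content `theta` (pi_A = pi_T =
(1−theta)/2, pi_G = pi_C = theta/2) and transition/transversion factor
`kappa`, normalized to one expected substitution per site per unit
branch length. Crucially, `theta` and `kappa` are *per branch*, so the
process is nonhomogeneous and nonstationary: a lineage with a low
branch theta drifts toward AT richness exactly the way symbiont
genomes do. T92 is the minimal model with a per-branch GC equilibrium,
the same mechanism the Galtier–Gouy family of nonhomogeneous models
parameterizes. Transition probabilities are computed by matrix
exponential of the exact generator (machine precision; verified
row-stochastic to 1e-12 and Chapman–Kolmogorov-consistent to 1e-10 in
tests), and the root sequence is drawn i.i.d. from the theta_root
equilibrium. Optional per-position rate multipliers tiled over codons
(third positions faster) let the third-position-exclusion transform be
exercised; there is no site-rate heterogeneity otherwise and no
indels. Because pi_A = pi_T under T92, an AT-shifted lineage is
symmetric between A and T — the composition signal lives entirely in
the AT-vs-GC contrast, which is the contrast the filter operates on.

## The LBA benchmark fixture

Four taxa with true topology ((A,B),(C,D)) and a designated non-sister
"attracted pair" (A, C). Three styles:

| style         | A, C tips                     | B, D tips | internal |
|---------------|-------------------------------|-----------|----------|
| felsenstein   | long (0.4), theta 0.5         | 0.1       | 0.1      |
| compositional | moderate (0.3), theta 0.2     | 0.1       | 0.1      |
| combined      | long (0.4), theta 0.2         | 0.1       | 0.1      |

Background theta 0.5, kappa 2.0, root at the midpoint of the internal
edge. Branch lengths are expected substitutions per site. The combined
style is the endosymbiont regime: fast AND AT-shifted.

The long-branch default (0.4, four times the background tips) was
chosen so that the artifact in the combined fixture is attributable to
the compositional mechanism: at these lengths the felsenstein control
(same lengths, uniform composition) is recovered correctly by
parsimony, while the combined fixture is majority-attracted — so the
attraction is driven by the AT shift, the component site filtering can
actually remove. With substantially longer branches (≳0.5) parsimony
enters the classical Felsenstein zone where the attraction is
saturation-driven and *no* site treatment can rescue it; that regime is
reproducible by passing `long_length` explicitly.

The experiment simulates `replicates` alignments (replicate r uses
seed base+r), applies each requested transform, infers by exhaustive
maximum parsimony (default) or neighbor joining on p-distances, and
records two frequencies per transform: replicates where the true
topology is the *unique* optimum, and replicates where *every* optimal
tree contains the attracted pair (ties count toward the artifact).
NJ uses p-distances inside the benchmark because the Jukes–Cantor
correction can hit its p ≥ 3/4 singularity on saturated AT-biased
pairs; the distance model remains user-selectable.

At the default conditions (100 replicates × 5 kb, seed 1) the
benchmark prints: untransformed parsimony groups the attracted pair in
0.74 of replicates (true topology 0.26); after the strict AT/GC filter
0.23 (true 0.75); after RY recoding 0.03 (true 0.97). Numbers move
within a few hundredths across seeds.

## Inference harness

Deliberately small and exact rather than heuristic: neighbor joining
with lexicographic tie-breaking (bit-reproducible across platforms;
negative branch lengths clamped to zero), parsimony lengths by
Hartigan's generalization of the Fitch algorithm (exact on
multifurcations, vectorized over columns with state bitmasks; missing
data contributes the universal state set and hence no cost), maximum
parsimony by exhaustive enumeration of all (2n−5)!! unrooted
topologies for n ≤ 10, Robinson–Foulds distances by normalized
bipartition sets (cross-checked against dendropy in tests). NJ on
additive matrices recovers the generating tree exactly; this is
property-tested up to 12 taxa.

## What the synthetic data does and does not show

The generator reproduces the mechanism — branch-wise compositional
nonstationarity plus rate inequality — not the texture of real
alignments: no indels, no selection, no among-site rate variation (by
default), no codon structure beyond position-specific rates, four
taxa rather than fifty. Passing the benchmark demonstrates that the
transforms remove composition-driven attraction under the model that
generates it; it does not certify performance on real matrices, where
heterotachy, alignment error and model misspecification add further
artifact sources.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere user-facing (NEXUS
  charset convention); partition maps rescale through every filter.
* Gap `-` and missing `?` are distinct and preserved on round trip;
  both are uncounted for all statistics, as are `N`/`X` and nucleotide
  ambiguity codes.
* Internal stop codons translate to `*` with a warning count rather
  than an error (trimmed alignments may retain stops); `*` recodes to
  missing.
* Relaxed sequential PHYLIP (long names, whitespace-delimited) rather
  than strict interleaved, which would truncate realistic taxon
  labels.
* Pipeline outputs are a pure function of (inputs, config, seed): run
  directories are stamped with a config hash, not a timestamp, so
  reruns are byte-identical instead of clobbering divergent results.
* Sizes used by the shipped checks — 5 kb × 100 replicates for the
  benchmark, ≤20 × ≤500 random matrices for filter oracles, ≤12 taxa
  for tree-recovery properties — are the package's own defaults,
  chosen to make the full suite run in seconds while keeping binomial
  error bars far smaller than the effects asserted.

## Known limitations

Exhaustive MP stops at 10 taxa by design. The simulator is
nucleotide-only (amino acid fixtures must come from translation). The
slow-fast rate proxy ignores between-group changes, so it
underestimates rates for columns whose variation lies across groups —
a property inherited from the group-based definition, not a bug. The
AT/GC filter assumes the within-category frequencies are roughly
symmetric; data violating pi_A ≈ pi_T inside the A/T category would
leave residual signal the filter cannot see.
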