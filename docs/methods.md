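# Methods

## Model and assumptions

The package treats a metabolic network as a bipartite metabolite–reaction
graph derived from the sign pattern of the stoichiometric matrix S.
Coefficient magnitudes are deliberately discarded (the sign function
flattens them): partitioning is about connectivity, not flux magnitudes.
Reaction nodes can never be external — splitting always acts on metabolite
nodes, which keeps every reaction intact and uniquely interpretable in some
subnet. The method assumes the structure typical of metabolic networks: a
sparse backbone of mostly linear or weakly branched pathways, crosslinked by
a small number of highly connected currency metabolites (water, cofactor
pairs, CoA esters) whose mass balances are the cheapest to sacrifice.

Reversible reactions are expanded into opposed directed pairs for all graph
work (adjacency construction and structural-external detection), while S
keeps a single column per reaction. A reversible link must carry probability
both ways; treating it one-way misclassifies sinks and sources. The
expansion flag is exposed because the alternative one-way reading is
defensible for networks whose reversibility annotations encode a preferred
direction.

## Walk matrices and numerical choices

- **Self-loop coefficient 0.25.** Keeps walks of every length in the
  potentiation and guarantees aperiodicity (so repeated squaring cannot
  alias a periodic chain). Sink/source classification is insensitive to the
  value; a test sweeps [0.1, 0.5] and asserts identical partitions.
- **Convergence.** P₁ is potentiated by repeated squaring (P, P², P⁴, …)
  with the Frobenius-norm criterion ‖P₂ₖ − Pₖ‖F < 10⁻¹⁰ and a budget of 60
  squarings (2⁶⁰ steps — far beyond any practical mixing time; exceeding
  the budget raises with the last norm).
- **Zero tolerance 10⁻⁸.** A P∞ entry below this absolute floor counts as
  zero when classifying columns and binarising the truncated matrix. The
  floor is a package choice (floating-point limits force one) and is a
  parameter.
- **Null-space tolerance.** Bases come from SVD with relative cutoff 10⁻¹⁰
  of the largest singular value; a reaction is active when any basis vector
  carries a relative entry above the same cutoff. A sweep over 10⁻¹⁰…10⁻⁶
  leaves active counts unchanged on all fixtures.

## Blocking and cutoff search

Binary dissimilarities follow the two-coefficient family
d = (n₁₀+n₀₁)/(n₁₀+n₀₁+a·n₁₁+b·n₀₀); Sokal–Sneath (a = ½, b = 0) with
single linkage is the default because it gives the strongest block contrast,
with the Matching, Jaccard, Rogers–Tanimoto and Dice variants selectable.
Two all-zero vectors get d = 0 by convention. Consolidation reclusters the
combined (fractional) matrix with the Bray–Curtis distance.

Trial cutoffs are midpoints of the merged, sorted row+column intercluster
distance list, truncated to [0.2, 0.7]; the same cutoff is applied to both
dendrograms, and ties in Q resolve to the smaller cutoff. When no merge
midpoint falls in range, a single fallback cutoff of 0.45 is used (with a
warning) — this occurs for degenerate matrices such as an all-ones block.
The quality score sums the *combined* matrix (the column-blocking variant is
selectable); W counts exact zeros of that matrix. Sharing one cutoff between
the axes deliberately trades some flexibility for balanced row/column
cluster counts: on planted-block fixtures the restricted search typically
lands in the top decile of the exhaustive two-cutoff scan, occasionally just
below it — a known, accepted cost of the restriction.

Clustering determinism comes from operating on condensed distance matrices
with scipy's deterministic agglomerative implementation; leaf order follows
the standard dendrogram traversal. Rows or columns that are all zero after
earlier deletions are dropped before clustering with a warning.

## Separator selection

The grey threshold is the largest distinct value t < 1 of the combined
matrix such that at most 2·J cells satisfy 0 < s ≤ t (J the column count;
the multiple is configurable); cells equal to 1 are never candidates. The
minimum-cover problem is solved exactly: iterative forcing of sole-candidate
vertices, then König's theorem via maximum bipartite matching, wrapped in a
lexicographic refinement that returns the identifier-sorted smallest optimal
cover. A scipy MILP backend implements the same program as a cross-check.
Block recognition uses exact bipartite connected components, which provably
satisfy the rectangular-block definition (clusters never mix separated
components because cross-component dissimilarity is 1, above the cutoff
range). Single-row/column separated blocks and orphan sinks are removed
from play each round and restored in post-processing.

The round loop is controlled by a pluggable controller; the default accepts
every proposal not on a veto list (vetoes are permanent), an interactive
controller prompts per proposal. Stopping: no grey cells, an empty accepted
set, a round budget (default 50), or every block at or under an optional
target size. The stopping defaults are package choices — how fine-grained a
split should be is inherently a user decision.

## Post-processing

Reincorporation runs to a fixpoint in a fixed scan order (original
metabolite order; order affects only intermediate states). Only externals
*created by the algorithm* — threshold or explicit-list reclassifications
and separators — are eligible. Structural externals and a-priori boundary
species are not: a pure source or sink made internal would acquire a
zero-flux constraint the original model never imposed. Orphans are absorbed
in two steps: promotion to block-external when a neighbouring external is
absorbed, then promotion to internal only if no reaction link in either
direction reaches another block's internals. The one-off blocking pass
between the two reincorporation passes recomputes the DAG with the full
external list simultaneously, removing dependence on the order in which
separators happened to be accepted. Overlap merging (the shared-reaction
case) is reported but applied only on request.

## Efficacy

Effort is the power law f(n) = nᵖ (the prefactor cancels in E). Total
effort F = f(k) + W·Σ f(nᵢ) uses W = 1/k by default (the single-subnet-of-
interest reading, algebraically simplest); W = 1 is available. The lower
limit is F = 2·f(√N) at the optimum k = nᵢ = √N, the upper limit f(N). The
unsplit network (k = 1) is defined to have F = f(N) — no metanetwork term —
so E = 0 exactly; the literal one-subnet value f(1)+f(N) is available as an
option. The calibration p = 0.25·√N (floored at 1.05 to keep f concave up)
reproduces the published per-network exponents (2.1 at N = 71, 7.6 at
N = 924); N is the internal-metabolite count after structural-external
removal, before any algorithmic reclassification. Efficacy is a post-hoc
score only; nothing in the selection loop optimises it.

Occupancy p = Σ(CR·RC)/(z·N) is a percolation-style diagnostic. The
coordination number z is not operationally pinned down by the theory; the
default takes the mean degree of the metabolites-only graph (each link
counted at both endpoints), with max-degree and user-constant alternatives.
It is reported, never used for control.

## Synthetic generator

`generate_synthetic` plants k pathway modules (default two modules of ten
internal metabolites, linear topology, with a midpoint-branched variant),
joined pairwise only through bridge metabolites constructed as shared
products that drain to the boundary — which makes each bridge a sink fed by
both modules, the configuration the grey-cell cover provably isolates.
Currency metabolites attach to reactions as alternating co-substrates/
co-products with probability 0.5 and are topped up to at least 10
participations so they always clear the default connectivity threshold, as
real carrier metabolites do. A 0.2 fraction of interior chain steps is
reversible (terminal steps are kept irreversible so each module retains its
sink). Everything is deterministic given the spec and seed.

What the generator does *not* emulate: heterogeneous stoichiometric
coefficients, multi-substrate backbone reactions, dense cross-pathway
cofactor coupling below the threshold, compartments, and the heavy-tailed
degree distributions of real genome-scale models. Passing the planted-
recovery tests therefore shows the machinery is correct on networks whose
modular structure is real and recoverable — it does not certify subnet
quality on networks whose structure is ambiguous, where the interactive
controller and the user's biochemical judgement matter.

## Problem sizes

The test suite and acceptance checks run on planted networks of 2–4 modules
with 8–10 internal metabolites each (up to ~70 metabolites × ~75 reactions
after currency attachment), cover instances with ≤ 12 candidate metabolites
against brute-force enumeration, and closed-form efficacy checks up to
N = 1000. These sizes exercise every code path; the implementation itself
is dense-matrix based and comfortable at genome scale (a few thousand
metabolites).

## Known limitations

- Mutually connected sink groups ("supersinks") are grouped by top-square
  connectivity when blocks are read off, but the top square is otherwise
  not processed; a supersink pair fed by nothing becomes its own fragment.
- The walkthrough tests on the published demonstration models require the
  original SBML supplements (see `data/README.md`); without them those
  tests fail by design rather than silently passing.
- Subnet merging beyond the single overlap-pair case is out of scope.
- Interactive, user-steered runs — the mode in which the published
  genome-scale partitionings were produced — are supported but inherently
  not reproducible by automated tests; automated runs use the auto-accept
  controller.
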