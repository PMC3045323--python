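# netsplitter

Split a genome-scale stoichiometric metabolic network into coherent
subnetworks by converting a **minimal** set of internal metabolites into
externals.

## The problem

A metabolic network is specified by its stoichiometric matrix **S**
(*n* metabolites × *m* reactions) together with the internal/external status
of each metabolite: internal metabolites carry a steady-state mass-balance
constraint, externals form the network's periphery. Genome-scale networks
are too large to interpret whole, and structural tools such as elementary
mode analysis explode combinatorially with network size. The natural
partitioning operation is not edge deletion but **node splitting**:
reclassifying an internal metabolite as external splits it into a sink copy
in one subnet and a source copy in another, at the cost of one mass-balance
constraint. Selecting separators by connection degree alone fragments the
network badly; this package implements a global, random-walk-guided
selection that keeps the set of sacrificed constraints small.

## The method

1. **Random-walk DAG.** From the sign pattern of S, two binary adjacencies
   are built: CR = ½(|sign S| − sign S) (metabolite is substrate of
   reaction) and RC = ½(|sign S| + sign S)ᵀ (reaction produces metabolite),
   restricted to internal metabolites. The one-step walk matrix is
   P₁ = RowNorm(RowNorm(CR)·RowNorm(RC) + 0.25 I); repeated squaring
   converges it (Frobenius criterion 10⁻¹⁰) to P∞, whose zero columns are
   *sources* and nonzero columns *sinks*. The (sources × sinks) submatrix is
   the working object.
2. **Blocking transformation.** Rows and columns of the binarised matrix
   are ordered by single-linkage clustering under the Sokal–Sneath
   dissimilarity d = (n₁₀+n₀₁)/(n₁₀+n₀₁+½n₁₁); each row entry is replaced
   by the fraction of the row's mass in its column cluster (and dually for
   columns), and the two grey-scale matrices are averaged. A shared
   dendrogram cutoff in [0.2, 0.7] is chosen to maximise the blocking
   quality Q = (Σs/(IJ−W))²·(W/IJ), where W counts white cells; a final
   Bray–Curtis reordering consolidates split bands.
3. **Separator selection.** Light-grey cells mark weak overlaps between
   latent blocks. Covering all of them with the fewest metabolites is a
   bipartite minimum vertex cover — *minimise* **b**·**x** *s.t.*
   **A**·**x** ≥ **b** over binary **x** — solved exactly by a
   König/maximum-matching reduction with deterministic lexicographic
   tie-breaking. Accepted separators are deleted and the cycle repeats until
   no grey remains.
4. **Post-processing.** Externals whose entire reaction neighbourhood lies
   in one block are reincorporated; a one-off blocking with the full
   external list removes order dependence; a second reincorporation pass
   follows. Each block's reactions and S-submatrix are then extracted so
   that every internal metabolite keeps exactly its full-network mass
   balance.
5. **Scoring.** With effort f(n) = nᵖ and p = 0.25·√N, the efficacy
   E = 100·(log f(N) − log F)/(log f(N) − log 2f(√N)) places a partitioning
   between the unsplit network (E = 0) and the optimum of √N subnets of
   size √N (E = 100). A null-space comparison verifies that active
   reactions of the full network stay active in the subnets.

## Worked example

Generate a planted three-module network (30 internal pathway metabolites,
three bridge metabolites joining the module pairs, two ubiquitous currency
metabolites) and split it:

```sh
$ netsplitter synth --modules 3 --size 10 --seed 7 --out demo
44 metabolites x 42 reactions -> demo.*

$ netsplitter split demo.S.tsv --outdir run
3 subnets (sizes [10, 10, 10]), 3 separators kept: ['B01_0', 'B02_0', 'B12_0']
efficacy E = 87.7% (p = 1.48)
```

The three kept separators are exactly the planted bridge metabolites, and
the three blocks are exactly the planted modules: the currency hubs were
reclassified by the connectivity threshold (default 8) but reincorporated
afterwards because the separation never needed them. `run/` contains one
SBML file per subnet, `partition_summary.tsv`, a per-round `rounds.jsonl`
log and `partition.json` with the full efficacy report. The three dropped
reactions listed there are the bridge-to-waste steps that involve only
external metabolites after splitting — the expected, minimal flux-space
loss.

Scoring a hypothetical split directly:

```sh
$ netsplitter efficacy --sizes 10,10,10 --n 32
E = 84.1%  (k=3, p=1.41, F=30.68, range [23.19, 134.5])
```

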