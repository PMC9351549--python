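# Methods

## Model and data structure

A knowledge graph here is a directed graph with a node-type map φ and
edge labels drawn from a schema of typed relations (|types| > 1; every
edge's (label, φ(source), φ(target)) must be declared or inferred).  Node
identity is the pair *(concept id, type)*: a concept id appearing with two
semantic types yields two distinct nodes, which keeps φ a function even
though real UMLS concepts can carry several semantic types.  Edges are
unweighted and deduplicated — the adjacency between two types under one
relation is binary — and inverse relations are never materialized;
backward traversal uses a second hash index over incoming edges.  Both
indexes are keyed by (node, relation, neighbor type), giving
average-constant-time typed neighborhoods; this dictionary design, rather
than a graph database or matrix algebra, is what the scoring routines'
performance rests on.

## HeteSim

For a metapath P of length l, the score is the cosine of two
reach-probability vectors over the central entities: propagate mass 1 from
the source through the left half (splitting each node's mass uniformly
over its eligible typed out-neighbors), mirror the computation backwards
from the target over in-neighbors, and take the cosine over the union
support.  Mass reaching a node with no eligible continuation is dropped,
so each half profile sums to at most 1 (equality iff no dead end is
reachable).  Odd lengths are handled without mutating the graph: the
central entities are the edge instances of the middle relation, each
node's arriving mass splitting uniformly over its middle-relation edges.
This is provably the same as materializing a bridge node per middle edge
(each bridge has in- and out-degree exactly 1); the test suite checks the
equivalence against an explicit materialization.

Degenerate case: if either profile is empty the score is defined as 0 and
flagged undefined, so that "no shared reachable concepts" ranks below any
positive score.  Floating point is double precision throughout; sums use
`math.fsum`; test comparisons use absolute tolerances of 1e-12 for
dual-route equivalences and 1e-9 for closed-form values.

A dense reference implementation (`hetesim.reference`) computes the same
quantity literally as a product of row-normalized adjacency matrices and
serves as the second route in equivalence tests and for annotating
generated fixtures with ground truth; it is quadratic in type sizes and
not meant for large graphs.

## Dead ends and pruned HeteSim

A node is *dead at step i* (relative to a fixed source, target and
metapath) when it is reachable at that step from the relevant endpoint
but no walk through it can complete the half-metapath to the central
layer.  Dead ends are found by two deterministic passes per side: a
forward reachability sweep and a backward completability sweep; the
per-step dead sets are the differences.  The central layer itself is
never pruned.  This operational definition is the one the walk algorithm
itself discovers (a walk only ever strands where no continuation exists)
and is the one under which the length ≤ 4 equivalence PHS = HS holds: for
short metapaths all dead ends sit directly adjacent to an endpoint, their
removal rescales that side's reach vector by a single factor, and the
cosine is invariant to per-side scaling.  A stricter reading — dead iff
the node reaches no *shared* central entity — would break that
equivalence (pruning a branch that ends at a central entity seen from one
side only changes the cosine even at length 4) and is therefore not used.

Pruned propagation restricts every step's neighbor sets to non-dead
nodes; since every surviving node has a surviving successor, no mass is
lost and each pruned profile sums to exactly 1 whenever the side can
complete at all.  When the two sides share no central entity the pruned
score is 0 and flagged undefined.

## Randomized pruned HeteSim

The estimator takes n completed random walks per side on the pruned walk
space and returns the cosine of the empirical central-entity frequency
vectors.  The sample size is the closed form

    n = floor( c(ε)/ε² · k · ln(4k/(1−r)) ) + 1,

with k that side's reachable-central count (obtained from the same
deterministic pass that marks dead ends — the analysis assumes k known,
and reachability is linear-time and exact) and c(ε) as in the README;
c is monotone increasing with limit 8C² ≈ 56.78 at ε→0 and supremum
c(1) ≈ 70.22 ≤ 71.

Two implementation choices matter:

* Dead ends are marked *before* walking rather than discovered online
  with backtracking.  After full marking the two schemes sample the same
  distribution — every walk completes, drawing from the pruned transition
  law, which is exactly the regime the concentration analysis addresses —
  but pre-marking removes the transient in which early walks can still
  strand, and the open question of how stranded walks count toward n does
  not arise.
* Because completed walks are i.i.d., the ensemble is simulated exactly
  by per-node multinomial splitting of walk counts layer by layer (the
  per-layer counts are a sufficient statistic).  A run's cost is then
  proportional to the traversed subgraph, independent of n, which is what
  makes hundred-run verification experiments at n ≈ 4·10⁵ essentially
  free.  A single seeded generator (NumPy PCG64) drives all draws, nodes
  processed in sorted order, so identical seeds give bitwise-identical
  estimates.  A configurable safety cap (default 100× the required walk
  count) bounds the walk budget and raises a resource error when it
  cannot be met.

Dead-end marks and walk budgets are scoped to a single (s, t, P)
computation; dead ends are relative to the query, so nothing is shared
across metapaths.

## Aggregation and ranking

The relatedness of a source to the target is the arithmetic mean of its
scores over *all* metapaths enumerated for the query (union over
sources, deduplicated type signatures of walks of length ≤ the bound,
node revisits allowed — the same walk semantics as the transition-matrix
product).  A source lacking an instance of some metapath contributes 0
for it, and undefined scores enter as 0 with their count recorded.  The
approximate mean samples m metapaths uniformly *with replacement*
(independence is what the bounded-differences argument needs), with

    m = ceil( 1/(2ε²) · ln(2|S||T|/(1−r)) ),

falling back to the exact mean when m reaches the collection size.  The
combined budget for "sampled metapaths, each scored by randomized walks"
splits the failure probability r_fail between the stages as
r1 = r_fail·x/(x+ε²) with x = 4·ln(2|S||T|/r_fail)·k_max (under this
allocation a larger k_max shifts budget toward the walk stage and the
metapath sample size grows only logarithmically in k_max), then
m = ceil(2/ε²·ln(2|S||T|/(r_fail−r1))) and per-metapath walk counts
4c(ε/2)·k/ε²·ln(4m|S||T|k_max/r1).  All public interfaces take *success*
probabilities and convert internally.

Ranking sorts descending by mean score with ties broken ascending by
(id, type), yielding a strict total order with 1-based ranks that is
invariant to input ordering.  Default approximation parameters are
ε = 0.1, r = 0.9.

The ULARA demonstrator implements the exact optimum of the rank
aggregation objective: with a_i the summed squared deviation of ranking
function i from the mean rank, the objective Σ w_i a_i is linear on the
simplex, so the optimum puts all weight on argmin a_i (uniform over ties
— the original formulation leaves the tie case unspecified).  This
degeneracy — selection, not aggregation — is why the ranking pipeline
uses the mean instead; gradient-descent fitting of ULARA is deliberately
not implemented.

## Synthetic data

Fixture generators reconstruct the worked examples exactly: the 10-node
length-4 example (12 edges, one metapath, four instances, node `b` the
single dead end, profiles (1/3, 1/6, 1/6) and (1/4, 1/4, 1/2)); the
single-shared-central family with m1−1 and m2−1 dead ends whose score is
1 for all m1, m2; and a length-6 two-branch family whose m−2 dead ends
dilute one branch, with closed-form score (m+2)√2 / (2√((m+1)²+1)) —
(3/4, 1/4) vs (1/2, 1/2) and 2/√5 at the dead-end-free m = 2 — while the
pruned score stays 2/√5 for every m.  The two-branch topology is only
partly determined by its published description; this reconstruction is
the minimal one satisfying every stated constraint (the m = 2 profiles,
"pruning recovers the m = 2 member", and the printed m = 3 and m → ∞
scores), and its annotations are recomputed by the matrix reference at
build time rather than stored.

Random layered graphs draw Bernoulli(edge_prob) edges between
consecutive typed layers, optionally delete all outgoing edges of a
non-endpoint node with probability `dead_end_bias` to seed dead ends, and
reject-resample until a full source-to-target instance exists.  They
emulate the *structure* that matters to the algorithms — typed sparsity,
branching, dead-end density — but not the scale, degree skew, predicate
semantics or redundancy of a real predication database; passing tests
demonstrate algorithmic correctness and calibration, not retrieval
quality on real literature graphs.

The three verification graphs for the estimator experiment are
deterministic layered graphs with nontrivial dead-end structure
(including a cascading dead end, where a branch dies two steps below its
root) and per-side central counts of 2–3, with closed-form exact pruned
scores 2/√5, 2√3/√14 and 2/√5.  The repeated-run experiment (100 seeded
runs per graph at ε = 0.05, r = 0.95) consistently observes maximum
errors near 3·10⁻³, reflecting how conservative the union-bound-based
sample size is.

## Problem sizes and limitations

Tests run on graphs of ≤ ~50 nodes and metapaths of length ≤ 6, where
exhaustive walk enumeration is a feasible second route; the data
structure supports much larger graphs, but metapath *enumeration* is
exponential in the length bound in the worst case (path counting is
#P-hard), so long-metapath queries on dense graphs remain out of reach —
the enumeration bound defaults to 2 and warns nothing beyond the length-4
equivalence boundary.  The sample-size constants are upper bounds, not
calibrated operating points; tightening them is possible in principle but
out of scope.  Persistence layers, database back ends and ingestion of
full predication databases are likewise out of scope for the test suite,
though `load_triples` streams any conformant TSV.
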