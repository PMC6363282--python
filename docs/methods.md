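# Methods

## Model and assumptions

A metabolic network is an ordered list of metabolites and reactions with a
stoichiometric matrix **S** (metabolites × reactions).  Reactions are
internal, primary exchange (nutrients and products crossing the boundary),
currency exchange (cofactor loads such as ATP regeneration or NAD(P)H
turnover), or 1:1 link reactions created by the subsystem machinery.
Steady state (`S v = 0`) plus irreversibility constraints define the flux
cone; everything in this package derives from its geometry and from no
kinetic information whatsoever.

The central modelling assumption is that a cell reaches a metabolic state
by switching extreme pathways on and off, each pathway being utilised with
equal probability.  A reaction is "on" exactly when an employing pathway is
active, which turns the pathway matrix into a joint distribution of binary
reaction states.  All entropies are computed from exact configuration
counts over the `l` pathway columns (base 2; every decision downstream —
argmax, zero tests, equivalence — is invariant to the base).

## Pathway enumeration

Enumeration runs on the fully split network (every reversible reaction
replaced by an irreversible pair) with an incremental double-description
tableau over exact integers: one metabolite row is zeroed per step by
combining positive/negative ray pairs, and a candidate survives only if no
third ray's support fits inside its support union.  The surviving rays are
the support-minimal flux vectors of the split cone.

*Extreme pathways* keep internal reversible reactions split but treat each
reversible exchange flux as one signed coordinate.  They are recovered by
an exact rank test: a mode is an extreme ray iff the nullspace of **S**
restricted to its support plus all free (reversible-exchange) coordinates
is one-dimensional.  For this computation the balance rows of metabolites
whose only boundary is a reversible single-metabolite exchange can be
dropped and the exchange flux reconstructed afterwards; every extreme ray
remains support-minimal in that reduced space, so the reduction is loss-free
for extreme pathways and cuts the tableau size dramatically.

*Elementary modes* must instead be enumerated on the full, unreduced
tableau: support minimality has to see the exchange coordinates, otherwise
the "through-flux" modes — those that route a boundary metabolite
internally instead of exchanging it, which are exactly the modes that are
conic combinations of extreme pathways — would be lost.  This distinction
is why the elementary-mode set of the red-cell fixture (987 type I) is so
much larger than its extreme-pathway set (36 type I).

Pathway types: type III touches no exchange flux at all, type II only
currency exchanges, type I anything else.  The forward+backward two-cycle
of each internal reversible reaction is itself an extreme ray of the split
cone and is reported as a type III pathway (the red-cell fixture has
exactly its 16 reversible internal reactions as type III); all type III
pathways are discarded before compaction as thermodynamically infeasible.
Compaction merges each split pair into one signed element per network
reaction and provably preserves each pathway's employed-reaction set (the
package asserts this on every run).  Vectors are normalised by their
integer gcd; fully reversible modes are reported once, with the first
non-zero coordinate positive.  Plain enumeration refuses networks with more
than 400 internal reactions and points at the subsystem workflow.

## EqSets, distances, and the greedy sort

Two internal reactions are equivalent when each determines the other
(`H(R_i|R_j) = H(R_j|R_i) = 0`, tolerance 1e−12).  Taken literally this
holds for identical employment rows, complementary rows, and pairs of
constant rows; the package follows the literal reading by default (a
`identical_support` switch restricts it to identical rows — on the red-cell
fixture both give the same 22 EqSets).  Equivalence classes are refined
into connected components of the `D ≤ ρ_e` threshold graph, so every member
has a counterpart within the intra-set radius.  Exchange reactions are
always singleton EqSets.

The local regulatory distance between two reactions is the minimum, over
their shared metabolites, of the number of consuming reactions (metabolites
of reversible reactions count as substrates on both sides); reactions
sharing nothing are infinitely far apart, and infinity is propagated as a
genuine infinity, never a sentinel.  Global distances are all-pairs
shortest paths (Dijkstra) on the weighted reaction graph; EqSet-to-EqSet
distance is the mean over all cross pairs.

The greedy sort keeps a pool P and a queue Q.  Every round each pooled
EqSet X_j is scored

    val(X_j) = [1 + μ(|X_j|−1)] · [H(X_j|N̂_j) + min_{X_u∈C_j} H(X_j|N̂_j ∪ X_u)]

with N̂_j the union of reactions of the queued neighbours within ρ_s
(filtered by distance first, then truncated to the τ most recent) and C_j
the pooled competitors within ρ_s.  When C_j is empty nothing can
substitute for X_j and the minimum term defaults to H(X_j|N̂_j).  Exchange
EqSets compete, occupy window slots and condition N̂_j while queued; they
are removed only from the final output, so reported ranks are 1-based over
internal EqSets.  The loop stops when the pool is empty or every remaining
value is ≤ 1e−12; leftover internal EqSets are "lost".  Ties in the argmax
go to the lexicographically smallest member reaction id, which makes the
output independent of construction order.

Entropies are served from a cache that stores each reaction set as an
integer partition label per pathway and refines two partitions per union,
so parameter sweeps and searches on one profile share almost all work.

## Scoring and exact p-values

A ranked sequence is scored against a meaningful reaction set by
`σ = Σ rank(X_i) + d·(s + (l_lost+1)/2)` where the sum runs over queued
EqSets intersecting the meaningful set, `s` is the queue length, `l_lost`
the number of lost internal EqSets and `d` how many of those contain
meaningful reactions.  The penalty equals the expected rank sum the missing
EqSets would receive if the lost tail were appended in random order (the
package verifies this empirically).

The p-value of a score is the exact probability that a uniformly random
arrangement of all `n` internal EqSets gives a rank sum of the `m`
meaningful EqSets no larger than σ₀ — under that null every meaningful
EqSet is present, so no penalty arises.  The tail is computed by exact
big-integer dynamic programming (k-subsets of {1..n} counted by sum,
divided by C(n, m)); non-integer scores compare as their floor because null
scores are integers.  For the published red-cell configuration
(σ₀ = 44.5, n = 22, m = 8) the DP gives 2.095 × 10⁻⁴, and it matches
exhaustive permutation enumeration for every n ≤ 9.  A seeded Monte-Carlo
estimator and an exact (enumeration-based, mid-rank) two-sample rank-sum
test accompany it.

## Parameters

| parameter | meaning | default | grid |
|---|---|---|---|
| μ | bonus per extra member of an EqSet | 0 | 20 values in [0, 1] |
| ρ_e | intra-EqSet effective radius (distance units = consumer counts) | ∞ | 26 values, 1…52 and ∞ |
| ρ_s | inter-EqSet influence radius, ρ_e ≤ ρ_s | ∞ | 26 values |
| τ | sliding-window length on the queue | ∞ | 30 values, 1…40 |

The constrained grid holds 210,600 tuples.  The heuristic search sweeps one
parameter at a time to its best value (order μ, ρ_e, ρ_s, τ; ties keep the
earlier grid value), restarts from a random admissible tuple at local
optima, memoises every tuple, and stops after `max_steps` unique objective
evaluations or when the grid is exhausted.

## The red-cell fixture

The packaged network is a reconstruction of the classical human erythrocyte
stoichiometric models (glycolysis, Rapoport-Luebering shunt, pentose
phosphate pathway, adenosine nucleotide salvage): 39 metabolites, 51
reactions, 19 of them exchanges.  Cofactor turnover is expressed as paired
reversible exchange fluxes for ATP/ADP, NAD/NADH, NADP/NADPH, Pi, H2O and
H⁺ — the currency set — which makes the three classical ATP-dissipating
futile cycles (adenosine kinase/AMP phosphohydrolase, the
2,3-bisphosphoglycerate shunt against phosphoglycerate kinase, and the
purine-salvage cycle through PRPP synthetase, HGPRT, IMP phosphohydrolase,
PNPase, phosphoribomutase and adenylate kinase) the network's type II
pathways.  Hypoxanthine enters as a salvage substrate only; adenosine and
inosine exchange in both directions; glucose and adenine are imported,
lactate, pyruvate, CO₂, ammonia and 2,3-BPG exported.  With these boundary
choices the enumeration census is 36/3/16 and the EqSet structure (22
internal EqSets, 5 multi-member, 8 regulatory) emerges from the pathway
matrix alone.  The ten regulated reactions are the literature-curated
allosteric control points (hexokinase, phosphofructokinase, pyruvate
kinase, bisphosphoglycerate mutase, both oxidative-branch dehydrogenases,
PRPP synthetase, both transketolase activities, adenine
phosphoribosyltransferase).

Reconstruction limits: the exact greedy ranking is sensitive to details of
the underlying stoichiometry and to tie handling, so sequence-level numbers
(the precise order of the top EqSets, the attained minimum of σ over the μ
sweep) should be read as properties of this reconstruction rather than of
erythrocyte biology; the test suite marks the corresponding expectations
explicitly and the acceptance script reports what the code actually
computes.

## Synthetic data

`random_toy_network` generates connected, seeded toy networks (a backbone
chain plus random small-integer reactions and boundary exchanges).  They
emulate the structural features the algorithms consume — irreversibility,
branching, shared metabolites, boundary fluxes — but none of the biology:
no mass conservation across elements, no realistic pathway length
distribution, no curated regulation.  Tests passing on toys therefore
certify the combinatorics and the exact arithmetic (against brute-force
oracles), not biological fidelity; the red-cell fixture is the biological
anchor.

## Numerical choices

Exact integer/rational arithmetic everywhere in enumeration and p-values;
employment threshold 1e−9 on compact fluxes; entropy and importance zero
tolerance 1e−12; LP zero threshold 1e−6 for classifying flux-variability
bounds (HiGHS defaults underneath); default flux bounds ±1000 in the
COBRA convention, used only by LP steps.  Degenerate inputs: empty
conditioning sets are allowed (H(X|∅) = H(X)), blocked reactions give
constant-off rows and zero entropy, infinite distances simply exclude
neighbours/competitors.

## Known limitations

Enumeration is exponential in network size by nature; genome-scale models
must pass through the subsystem carving step, which (as the cross-boundary
literature shows) biases pathway participation near the cut.  The greedy
sort is a heuristic, not an optimum over sequences.  The uniform-pathway
utilisation prior ignores pathway weighting.  The disease cross-validation
averages over random splits and is only as informative as the annotation
list it is given.
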