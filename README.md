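# epareg — extreme-pathway analysis of metabolic regulatory architecture

`epareg` ranks the reactions of a constraint-based metabolic network by
their **regulatory importance**: the role each reaction plays, on average,
in deciding which of the network's *extreme pathways* are switched on or
off.  It is aimed at systems biologists who want condition-independent
candidates for allosteric or transcriptional regulation (or for
disease association) from stoichiometry alone — no kinetics, no omics.

## The method in brief

For a network with stoichiometric matrix **S**, the steady-state flux cone
`{v : S v = 0, v_i ≥ 0 for irreversible i}` is generated by a unique minimal
set of conically independent *extreme pathways* (EPs).  After discarding the
thermodynamically infeasible purely internal cycles (type III) and merging
each reversible reaction's forward/backward pair, every reaction R_i either
participates in a compact pathway **e**^j (e_ij ≠ 0) or not.  Drawing one of
the `l` pathways uniformly at random makes each reaction a binary random
variable, with Shannon entropy `H(R_i)` and conditional entropies
`H(X₁ | X₂)` between reaction sets.

Reactions that mutually determine each other (`H(R_i|R_j) = H(R_j|R_i) = 0`)
and lie within the intra-set radius ρ_e of a counterpart form an
*equivalent reaction set* (EqSet); each exchange flux is its own singleton.
A greedy algorithm repeatedly moves the EqSet with the highest importance

    val(X_j) = [1 + μ(|X_j| − 1)] · [ H(X_j | N̂_j) + min_{X_u ∈ C_j} H(X_j | N̂_j ∪ X_u) ]

to the end of a queue, where N̂_j is the union of the (at most τ most
recent) queued neighbours within the inter-set radius ρ_s and C_j are the
unqueued competitors within ρ_s.  The resulting sequence is scored against
a set of known regulated (or disease-associated) reactions by the rank sum
σ of the meaningful EqSets — plus the expected tail rank for meaningful
EqSets the sort never queued — and by the exact probability that a random
ordering scores no higher, computed by integer dynamic programming.

Local regulatory distances between reactions are the minimum consumer count
over shared metabolites (infinite when none is shared); global distances
are shortest paths over that weighted reaction graph.  A coordinate-descent
search with random restarts tunes (μ, ρ_e, ρ_s, τ) over a 210,600-point
grid, and a cross-validation protocol checks that high-ranked EqSets
predict held-out disease annotations.

## Worked example: the human red blood cell

The package ships a 39-metabolite, 51-reaction reconstruction of human
erythrocyte metabolism (glycolysis, the Rapoport-Luebering shunt, the
pentose phosphate pathway, adenosine nucleotide salvage) together with its
ten literature-curated allosterically regulated reactions:

```bash
epareg run --outdir out/
# I/II/III = 36/3/16; sigma=64.0 p=0.0297 -> out
```

Enumeration finds 36 type I, 3 type II and 16 type III extreme pathways.
The 32 internal reactions collapse into 22 EqSets (5 with more than one
member — e.g. the transketolase/transaldolase group {TKI, TKII, Xu5PE, TA}
and the upper-glycolysis group {PFK, ALD, TPI}), of which 8 contain
regulated reactions.  At μ = 0.1 with unbounded radii the greedy sort
queues 7 internal EqSets, 5 of them regulatory, and the evaluation score
σ = 64.0 has exact p-value 3.0 × 10⁻² — regulated reactions sit
significantly high in the ranking.  The same pipeline run on the network's
987 elementary modes (`--mode em`) scores strictly worse for every μ,
which is the structural argument that the conically independent extreme
pathways, not arbitrary steady-state modes, are the natural regulatory
targets.

Individual steps are available as `epareg pathways`, `sort`, `evaluate`,
`sweep-mu`, `search`, `artificial`, `subsystem` and `cv-disease`; genome-
scale models (SBML / BiGG JSON) enter through `epareg subsystem`, which
carves a functional subsystem and closes its boundary with flux-variability
constrained exchanges before enumeration.

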