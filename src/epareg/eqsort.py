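"""EqSet construction and greedy sorting by regulatory importance.

An *equivalent reaction set on Shannon entropy* (EqSet) groups internal
reactions that are pairwise mutually determined (zero conditional entropy in
both directions) and lie within the intra-EqSet effective radius ``rho_e``
of a counterpart; every exchange reaction is its own singleton EqSet.

The greedy sort keeps a queue Q of EqSets predicted regulatory.  Each
round, every EqSet still in the pool is scored by

    val(Xj) = [1 + mu (|Xj| - 1)] [H(Xj | N^j) + min_{Xu in Cj} H(Xj | N^j u Xu)]

where N^j is the union of reactions of the (at most ``tau`` most recent)
queued neighbors within the inter-EqSet radius ``rho_s``, and Cj are the
not-yet-queued competitors within ``rho_s``.  The highest-valued EqSet joins
the queue; the loop stops when the pool is empty or every remaining value is
zero.  Exchange EqSets take part throughout and are removed only from the
final output; EqSets never enqueued are reported as lost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .infotheory import ENTROPY_TOL, ParticipationProfile, entropy
from .model_io import MetabolicNetwork
from .regdistance import RegulatoryGraph

INF = math.inf

#: values below this count as zero regulatory importance
VAL_TOL = 1e-12


@dataclass(frozen=True)
class Params:
    """Sorting parameters: size-bonus ratio and flexibility radii."""

    mu: float = 0.0
    rho_e: float = INF
    rho_s: float = INF
    tau: float = INF

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.rho_e <= 0 or self.rho_s <= 0:
            raise ValueError("effective radii must be positive")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.rho_e > self.rho_s:
            raise ValueError("rho_e must not exceed rho_s")


@dataclass(frozen=True)
class EqSet:
    members: frozenset[str]
    is_exchange: bool
    id: int

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("EqSet must be non-empty")

    @property
    def key(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))

    def __repr__(self) -> str:  # pragma: no cover
        return "{" + ",".join(self.key) + "}"


@dataclass
class StepTrace:
    eqset: EqSet
    val: float
    n_neighbors: int
    n_competitors: int


@dataclass
class RankedSequence:
    queue: list[EqSet]  # internal EqSets in rank order (1-based ranks)
    lost: list[EqSet]  # internal EqSets never enqueued
    trace: list[StepTrace] = field(default_factory=list)

    @property
    def s(self) -> int:
        return len(self.queue)

    def rank_of(self, reaction_id: str) -> int | None:
        for i, x in enumerate(self.queue, start=1):
            if reaction_id in x.members:
                return i
        return None


class _EntropyCache:
    """Joint entropies over pathway-configuration partitions.

    Each cached reaction set is stored as an integer label per pathway (its
    joint on/off configuration); the union of two sets refines the two label
    arrays, so growing conditioning sets reuse earlier work.  Shareable
    across sorts on the same profile (entropies do not depend on the
    sorting parameters).
    """

    def __init__(self, profile: ParticipationProfile):
        import numpy as np

        self.profile = profile
        self._np = np
        l = profile.l
        self._store: dict[frozenset, tuple] = {
            frozenset(): (np.zeros(l, dtype=np.int64), 1, 0.0)
        }

    def _entry(self, ids: frozenset) -> tuple:
        entry = self._store.get(ids)
        if entry is None:
            entry = self._from_rows(ids)
            self._store[ids] = entry
        return entry

    def _finish(self, key):
        np = self._np
        uniq, labels, counts = np.unique(
            key, return_inverse=True, return_counts=True
        )
        l = self.profile.l
        p = counts / l
        h = float(-(p * np.log2(p)).sum())
        return labels.astype(np.int64), len(uniq), h

    def _from_rows(self, ids: frozenset) -> tuple:
        np = self._np
        rows = np.stack([self.profile.row(rid) for rid in sorted(ids)])
        packed = np.ascontiguousarray(np.packbits(rows, axis=0).T)
        key = packed.view([("", packed.dtype)] * packed.shape[1]).ravel()
        return self._finish(key)

    def _union_entry(self, a: frozenset, b: frozenset) -> tuple:
        u = a | b
        entry = self._store.get(u)
        if entry is None:
            la, ka, _ = self._entry(a)
            lb, kb, _ = self._entry(b)
            entry = self._finish(la * kb + lb)
            self._store[u] = entry
        return entry

    def H(self, ids: frozenset) -> float:
        return self._entry(ids)[2]

    def cond(self, x1: frozenset, x2: frozenset) -> float:
        """H(x1 | x2), both arbitrary reaction-id sets."""
        if not x1:
            return 0.0
        h_joint = self._union_entry(x1, x2)[2]
        return max(h_joint - self._entry(x2)[2], 0.0)

    def cond_union(self, x1: frozenset, a: frozenset, b: frozenset) -> float:
        """H(x1 | a u b) computed through cached union partitions."""
        if not x1:
            return 0.0
        cond_entry = self._union_entry(a, b)
        h_joint = self._union_entry(a | b, x1)[2]
        return max(h_joint - cond_entry[2], 0.0)


# ---------------------------------------------------------------------------
# EqSet construction


def _row_class_key(profile: ParticipationProfile, rid: str, mode: str) -> tuple:
    row = tuple(int(x) for x in profile.row(rid))
    if mode == "identical_support":
        return row
    if all(x == row[0] for x in row):  # constant rows are mutually determined
        return ("const",)
    neg = tuple(1 - x for x in row)
    return min(row, neg)


def build_eqsets(
    profile: ParticipationProfile,
    graph: RegulatoryGraph,
    net: MetabolicNetwork,
    rho_e: float = INF,
    equivalence: str = "literal",
) -> list[EqSet]:
    """Partition reactions into EqSets.

    Internal reactions fall into entropy-equivalence classes, refined into
    connected components of the D <= rho_e threshold graph; every other
    reaction is a singleton.  Ids follow network reaction order.
    """
    internal = [r.id for r in net.reactions if r.kind == "internal" and r.id in set(profile.reaction_ids)]
    others = [r.id for r in net.reactions if r.kind != "internal" and r.id in set(profile.reaction_ids)]
    classes: dict[tuple, list[str]] = {}
    for rid in internal:
        classes.setdefault(_row_class_key(profile, rid, equivalence), []).append(rid)
    groups: list[list[str]] = []
    for members in classes.values():
        # split the class into connected components under D <= rho_e
        remaining = list(members)
        while remaining:
            comp = [remaining.pop(0)]
            changed = True
            while changed:
                changed = False
                for rid in list(remaining):
                    if any(graph.D(rid, other) <= rho_e for other in comp):
                        comp.append(rid)
                        remaining.remove(rid)
                        changed = True
            groups.append(comp)
    order = {r.id: i for i, r in enumerate(net.reactions)}
    groups.sort(key=lambda g: min(order[rid] for rid in g))
    eqsets = [
        EqSet(frozenset(g), is_exchange=False, id=i) for i, g in enumerate(groups)
    ]
    for rid in others:
        eqsets.append(EqSet(frozenset({rid}), is_exchange=True, id=len(eqsets)))
    return eqsets


# ---------------------------------------------------------------------------
# regulatory importance and the greedy sort


def _neighbors(
    xj: EqSet, queue: list[EqSet], params: Params, graph: RegulatoryGraph
) -> list[EqSet]:
    near = [y for y in queue if graph.eqset_distance(xj.members, y.members) <= params.rho_s]
    if params.tau != INF:
        near = near[-int(params.tau):]
    return near


def regulatory_importance(
    xj: EqSet,
    queue: list[EqSet],
    pool: list[EqSet],
    params: Params,
    profile: ParticipationProfile,
    graph: RegulatoryGraph,
    _cache: _EntropyCache | None = None,
) -> tuple[float, int, int]:
    """val(Xj) plus the neighbor / competitor set sizes."""
    cache = _cache or _EntropyCache(profile)
    nj = _neighbors(xj, queue, params, graph)
    n_hat = frozenset().union(*(y.members for y in nj)) if nj else frozenset()
    competitors = [
        y
        for y in pool
        if y is not xj and graph.eqset_distance(xj.members, y.members) <= params.rho_s
    ]
    base = cache.cond(xj.members, n_hat)
    if competitors:
        sub = min(
            cache.cond_union(xj.members, n_hat, y.members) for y in competitors
        )
    else:
        sub = base  # nothing can substitute for Xj
    weight = 1.0 + params.mu * (len(xj.members) - 1)
    return weight * (base + sub), len(nj), len(competitors)


def sort_eqsets(
    eqsets: list[EqSet],
    profile: ParticipationProfile,
    graph: RegulatoryGraph,
    params: Params,
    cache: _EntropyCache | None = None,
) -> RankedSequence:
    """Greedy ranking; deterministic (ties go to the lexicographically
    smallest member reaction id).  Pass a shared ``_EntropyCache`` when
    sorting the same profile repeatedly (parameter sweeps, searches)."""
    if not eqsets:
        raise ValueError("need at least one EqSet")
    if cache is None:
        cache = _EntropyCache(profile)
    pool = list(eqsets)
    queue: list[EqSet] = []
    trace: list[StepTrace] = []
    while pool:
        scored = []
        for xj in pool:
            val, n_n, n_c = regulatory_importance(
                xj, queue, pool, params, profile, graph, _cache=cache
            )
            scored.append((val, xj, n_n, n_c))
        best_val = max(v for v, *_ in scored)
        if best_val <= VAL_TOL:
            break
        val, best, n_n, n_c = min(
            (s for s in scored if s[0] >= best_val - VAL_TOL),
            key=lambda s: s[1].key,
        )
        queue.append(best)
        pool.remove(best)
        trace.append(StepTrace(best, val, n_n, n_c))
    internal_queue = [x for x in queue if not x.is_exchange]
    lost = [x for x in pool if not x.is_exchange]
    return RankedSequence(queue=internal_queue, lost=lost, trace=trace)
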