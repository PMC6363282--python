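"""Scoring of EqSet sequences against meaningful reaction sets.

The evaluation score of a ranked sequence sums the 1-based ranks of the
queued EqSets that contain biologically meaningful (regulated or
disease-associated) reactions; each meaningful EqSet lost by the sort
contributes the expected rank it would receive were the lost EqSets
appended in random order, ``s + (l_lost + 1)/2``.  The p-value of a score is
the exact probability that a uniformly random arrangement of all internal
EqSets scores no higher, computed by integer dynamic programming over
rank-sum counts (no penalty arises under the null, where every meaningful
EqSet is present in the sequence).
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from functools import lru_cache

from .eqsort import EqSet, RankedSequence


@dataclass
class EvaluationResult:
    sigma: float
    rank_sum: int
    s: int
    l_lost: int
    d_missing: int
    meaningful_set: frozenset[str]
    n_internal: int
    m_meaningful: int
    p_value: float | None = None


def evaluation_score(seq: RankedSequence, meaningful) -> EvaluationResult:
    """Rank-sum score sigma of a ranked sequence (without p-value)."""
    meaningful = frozenset(meaningful)
    if not meaningful:
        raise ValueError("meaningful reaction set must be non-empty")
    rank_sum = sum(
        rank
        for rank, x in enumerate(seq.queue, start=1)
        if x.members & meaningful
    )
    s = seq.s
    l_lost = len(seq.lost)
    d_missing = sum(1 for x in seq.lost if x.members & meaningful)
    sigma = rank_sum + d_missing * (s + (l_lost + 1) / 2)
    m = sum(
        1 for x in list(seq.queue) + list(seq.lost) if x.members & meaningful
    )
    return EvaluationResult(
        sigma=sigma,
        rank_sum=rank_sum,
        s=s,
        l_lost=l_lost,
        d_missing=d_missing,
        meaningful_set=meaningful,
        n_internal=s + l_lost,
        m_meaningful=m,
    )


# ---------------------------------------------------------------------------
# exact p-value by dynamic programming


@lru_cache(maxsize=None)
def _subset_sum_counts(n: int, m: int) -> list[list[int]]:
    """counts[k][s] = number of k-subsets of {1..n} with rank sum s."""
    max_sum = n * (n + 1) // 2
    counts = [[0] * (max_sum + 1) for _ in range(m + 1)]
    counts[0][0] = 1
    for i in range(1, n + 1):
        for k in range(min(i, m), 0, -1):
            row_k, row_km1 = counts[k], counts[k - 1]
            for s in range(max_sum, i - 1, -1):
                c = row_km1[s - i]
                if c:
                    row_k[s] += c
    return counts


def pvalue_exact(sigma0: float, n_internal: int, m_meaningful: int) -> float:
    """P(rank sum of the m meaningful EqSets <= sigma0) under a uniform
    random permutation of all n internal EqSets.  Exact (big-integer DP);
    non-integer scores compare as floor since null scores are integers."""
    n, m = n_internal, m_meaningful
    if not 1 <= m <= n:
        raise ValueError("need 1 <= m_meaningful <= n_internal")
    s0 = math.floor(sigma0)
    if s0 < m * (m + 1) // 2:
        return 0.0
    counts = _subset_sum_counts(n, m)[m]
    hits = sum(counts[: min(s0, len(counts) - 1) + 1])
    return hits / math.comb(n, m)


def evaluate(seq: RankedSequence, meaningful) -> EvaluationResult:
    """Score a sequence and attach the exact p-value."""
    res = evaluation_score(seq, meaningful)
    res.p_value = pvalue_exact(res.sigma, res.n_internal, res.m_meaningful)
    return res


def pvalue_monte_carlo(
    sigma0: float, n_internal: int, m_meaningful: int, reps: int, seed: int
) -> tuple[float, float]:
    """Stochastic estimate of the exact p-value, with its standard error."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = random.Random(seed)
    s0 = math.floor(sigma0)
    ranks = list(range(1, n_internal + 1))
    hits = sum(
        1 for _ in range(reps) if sum(rng.sample(ranks, m_meaningful)) <= s0
    )
    p = hits / reps
    se = math.sqrt(p * (1 - p) / reps)
    return p, se


# ---------------------------------------------------------------------------
# exact two-sample rank-sum test (mid-ranks, conditional enumeration)


def entropy_rank_sum(group_a, group_b) -> float:
    """Exact two-sided Wilcoxon rank-sum p-value by enumerating all label
    assignments (mid-ranks for ties)."""
    from itertools import combinations

    a = list(group_a)
    b = list(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    values = a + b
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    na = len(a)
    w_obs = sum(ranks[:na])
    mu = na * (len(values) + 1) / 2
    dev = abs(w_obs - mu)
    total = 0
    extreme = 0
    for idx in combinations(range(len(values)), na):
        total += 1
        w = sum(ranks[i] for i in idx)
        if abs(w - mu) >= dev - 1e-12:
            extreme += 1
    return extreme / total


# ---------------------------------------------------------------------------
# disease cross-validation protocol


@dataclass
class CVReport:
    rho_e_intervals: list[tuple[float, float]]
    x: float
    repeats: int
    mean_train_pvalues: list[float]
    chosen_interval: tuple[float, float]
    top10_true_positive_rate: float
    background_rate: float = float("nan")
    details: dict = field(default_factory=dict)


def subsequence_pvalue(seq: RankedSequence, subset_eqsets, meaningful) -> float:
    """p-value of the subsequence consisting of the given EqSets, ranked by
    their relative order in the full sequence."""
    keys = {x.key for x in subset_eqsets}
    sub = [x for x in seq.queue if x.key in keys]
    lost = [x for x in seq.lost if x.key in keys]
    meaningful = frozenset(meaningful)
    n = len(sub) + len(lost)
    m = sum(1 for x in sub + lost if x.members & meaningful)
    if n == 0 or m == 0:
        return 1.0
    rank_sum = sum(r for r, x in enumerate(sub, start=1) if x.members & meaningful)
    d = sum(1 for x in lost if x.members & meaningful)
    sigma = rank_sum + d * (len(sub) + (len(lost) + 1) / 2)
    return pvalue_exact(sigma, n, m)


def rho_e_intervals(graph, internal_ids) -> list[tuple[float, float]]:
    """Split the rho_e axis where the EqSet partition can change: at the
    distinct finite pairwise global distances between internal reactions."""
    vals = set()
    ids = sorted(internal_ids)
    for i, ri in enumerate(ids):
        for rj in ids[i + 1:]:
            d = graph.D(ri, rj)
            if d != math.inf:
                vals.add(d)
    cuts = sorted(vals)
    intervals = []
    lo = 0.0
    for c in cuts:
        intervals.append((lo, c))
        lo = c
    intervals.append((lo, math.inf))
    return intervals


def disease_cv(
    profile,
    graph,
    net,
    disease_reactions,
    x: float,
    repeats: int,
    seed: int,
    mu_values=(0.0, 0.1, 0.2),
    tau_values=(math.inf,),
    rho_s_values=(math.inf,),
) -> CVReport:
    """Cross-validated check that regulatory importance predicts
    disease-associated EqSets.

    For each rho_e interval (identical EqSets within), random x% train
    splits pick the best parameters by training-subsequence p-value; the
    interval with the lowest mean training p-value is then scored by the
    proportion of disease EqSets in the top 10% (ceiling) of the test
    subsequences.
    """
    from .eqsort import Params, build_eqsets, sort_eqsets

    if not 0 < x < 100:
        raise ValueError("x must be a percentage strictly between 0 and 100")
    disease = frozenset(disease_reactions)
    if not disease:
        raise ValueError("disease set must be non-empty")
    internal_ids = [r.id for r in net.reactions if r.kind == "internal"]
    intervals = rho_e_intervals(graph, internal_ids)
    rng = random.Random(seed)

    interval_stats = []
    for lo, hi in intervals:
        rep = lo + 1.0 if hi == math.inf else (lo + hi) / 2
        eqsets = build_eqsets(profile, graph, net, rho_e=rep)
        internal_eq = [e for e in eqsets if not e.is_exchange]
        n_train = max(1, round(len(internal_eq) * x / 100))
        if n_train >= len(internal_eq):
            interval_stats.append((math.inf, None))
            continue
        split_pvals = []
        split_info = []
        for _ in range(repeats):
            train = rng.sample(internal_eq, n_train)
            train_keys = {e.key for e in train}
            test = [e for e in internal_eq if e.key not in train_keys]
            best = (math.inf, None)
            for mu in mu_values:
                for rho_s in rho_s_values:
                    if rep > rho_s:
                        continue
                    for tau in tau_values:
                        params = Params(mu=mu, rho_e=rep, rho_s=rho_s, tau=tau)
                        seq = sort_eqsets(eqsets, profile, graph, params)
                        p = subsequence_pvalue(seq, train, disease)
                        if p < best[0]:
                            best = (p, (params, seq))
            split_pvals.append(best[0])
            split_info.append((best[1], test))
        interval_stats.append((sum(split_pvals) / len(split_pvals), split_info))

    means = [m for m, _ in interval_stats]
    best_idx = min(range(len(intervals)), key=lambda i: means[i])
    chosen = intervals[best_idx]

    rates = []
    backgrounds = []
    for (params_seq, test) in interval_stats[best_idx][1]:
        _, seq = params_seq
        test_keys = {e.key for e in test}
        ordered = [x_ for x_ in seq.queue if x_.key in test_keys] + [
            x_ for x_ in seq.lost if x_.key in test_keys
        ]
        k = max(1, math.ceil(0.1 * len(ordered)))
        top = ordered[:k]
        rates.append(sum(1 for e in top if e.members & disease) / len(top))
        backgrounds.append(
            sum(1 for e in ordered if e.members & disease) / len(ordered)
        )
    return CVReport(
        rho_e_intervals=intervals,
        x=x,
        repeats=repeats,
        mean_train_pvalues=means,
        chosen_interval=chosen,
        top10_true_positive_rate=sum(rates) / len(rates),
        background_rate=sum(backgrounds) / len(backgrounds),
    )
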