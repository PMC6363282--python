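"""Discrete parameter grid and heuristic coordinate-descent search.

The candidate grid spans the four sorting parameters (mu, rho_e, rho_s,
tau) subject to rho_e <= rho_s.  The heuristic search starts from a random
admissible tuple and sweeps one parameter at a time to its best value
(lowest p-value); a full cycle with no change is a local optimum and
triggers a restart from a new random tuple.  Objective evaluations are
memoized per tuple, and the search stops after ``max_steps`` unique
evaluations.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Callable

from .eqsort import Params

INF = math.inf

_MU_SPAN = (
    0.0, 0.025, 0.05, 0.075, 0.1, 0.125, 0.15, 0.175, 0.2, 0.25,
    0.3, 0.35, 0.4, 0.45, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
)
_RHO_SPAN = (
    1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 14, 16, 18, 20,
    22, 24, 28, 32, 36, 40, 44, 48, 52, INF,
)
_TAU_SPAN = (
    1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20,
    22, 24, 26, 28, 30, 32, 34, 36, 38, 40,
)


@dataclass(frozen=True)
class ParameterGrid:
    mu_values: tuple = _MU_SPAN
    rho_e_values: tuple = _RHO_SPAN
    rho_s_values: tuple = _RHO_SPAN
    tau_values: tuple = _TAU_SPAN

    def tuples(self):
        for mu in self.mu_values:
            for rho_e in self.rho_e_values:
                for rho_s in self.rho_s_values:
                    if rho_e > rho_s:
                        continue
                    for tau in self.tau_values:
                        yield Params(mu=mu, rho_e=rho_e, rho_s=rho_s, tau=tau)


def default_grid() -> ParameterGrid:
    return ParameterGrid()


def grid_size(grid: ParameterGrid) -> int:
    """Number of admissible (rho_e <= rho_s) parameter tuples."""
    pairs = sum(
        1
        for re_ in grid.rho_e_values
        for rs in grid.rho_s_values
        if re_ <= rs
    )
    return len(grid.mu_values) * pairs * len(grid.tau_values)


@dataclass
class SearchResult:
    best_params: Params
    best_pvalue: float
    evaluations: int
    seed: int
    trace: list[tuple[Params, float]] = field(default_factory=list)


def heuristic_search(
    objective: Callable[[Params], float],
    grid: ParameterGrid,
    max_steps: int,
    seed: int,
) -> SearchResult:
    """Cyclic single-parameter sweeps with random restarts.

    ``max_steps`` counts unique objective evaluations (repeated tuples are
    served from the memo and are free).
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    rng = random.Random(seed)
    memo: dict[Params, float] = {}
    trace: list[tuple[Params, float]] = []
    budget = min(max_steps, grid_size(grid))  # a full grid ends the search

    def evaluate(params: Params) -> float | None:
        if params in memo:
            return memo[params]
        if len(memo) >= budget:
            return None
        val = objective(params)
        memo[params] = val
        trace.append((params, val))
        return val

    def random_start() -> Params:
        while True:
            re_ = rng.choice(grid.rho_e_values)
            rs = rng.choice(grid.rho_s_values)
            if re_ <= rs:
                return Params(
                    mu=rng.choice(grid.mu_values),
                    rho_e=re_,
                    rho_s=rs,
                    tau=rng.choice(grid.tau_values),
                )

    budget_left = True
    while budget_left and len(memo) < budget:
        current = random_start()
        cur_val = evaluate(current)
        if cur_val is None:
            break
        improved = True
        while improved and budget_left:
            improved = False
            for param_name, span in (
                ("mu", grid.mu_values),
                ("rho_e", grid.rho_e_values),
                ("rho_s", grid.rho_s_values),
                ("tau", grid.tau_values),
            ):
                best_here = (cur_val, current)
                for v in span:
                    cand_kwargs = {
                        "mu": current.mu,
                        "rho_e": current.rho_e,
                        "rho_s": current.rho_s,
                        "tau": current.tau,
                    }
                    cand_kwargs[param_name] = v
                    if cand_kwargs["rho_e"] > cand_kwargs["rho_s"]:
                        continue
                    cand = Params(**cand_kwargs)
                    if cand == current:
                        continue
                    val = evaluate(cand)
                    if val is None:
                        budget_left = False
                        break
                    if val < best_here[0]:
                        best_here = (val, cand)
                if best_here[1] != current:
                    cur_val, current = best_here
                    improved = True
                if not budget_left:
                    break

    best_params = min(memo, key=lambda p: (memo[p],))
    return SearchResult(
        best_params=best_params,
        best_pvalue=memo[best_params],
        evaluations=len(memo),
        seed=seed,
        trace=trace,
    )
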