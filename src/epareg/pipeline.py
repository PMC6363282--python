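"""End-to-end composition: model -> pathways -> EqSets -> ranking -> score."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .eqsort import EqSet, Params, RankedSequence, _EntropyCache, build_eqsets, sort_eqsets
from .evaluation import EvaluationResult, evaluate
from .infotheory import ParticipationProfile, participation_profile
from .model_io import MetabolicNetwork
from .pathways import (
    TYPE_I,
    TYPE_II,
    CompactPathwayMatrix,
    compact,
    enumerate_elementary_modes,
    enumerate_extreme_pathways,
    filter_types,
)
from .regdistance import RegulatoryGraph, global_distances


@dataclass
class AnalysisContext:
    """Everything derived from a network that the sort needs."""

    net: MetabolicNetwork
    cpm: CompactPathwayMatrix
    profile: ParticipationProfile
    graph: RegulatoryGraph
    type_counts: dict[str, int]

    _cache: _EntropyCache | None = None

    @property
    def cache(self) -> _EntropyCache:
        if self._cache is None:
            self._cache = _EntropyCache(self.profile)
        return self._cache

    def eqsets(self, rho_e: float = math.inf, equivalence: str = "literal") -> list[EqSet]:
        return build_eqsets(
            self.profile, self.graph, self.net, rho_e=rho_e, equivalence=equivalence
        )

    def sort(self, params: Params) -> RankedSequence:
        return sort_eqsets(
            self.eqsets(rho_e=params.rho_e),
            self.profile,
            self.graph,
            params,
            cache=self.cache,
        )

    def evaluate(self, params: Params, meaningful) -> tuple[RankedSequence, EvaluationResult]:
        seq = self.sort(params)
        return seq, evaluate(seq, meaningful)


def build_context(
    net: MetabolicNetwork, basis: str = "extreme_pathway", cap: int | None = None
) -> AnalysisContext:
    """Enumerate pathways, drop type III, compact, and derive the
    participation profile and the regulatory distance graph."""
    kwargs = {} if cap is None else {"cap": cap}
    if basis == "extreme_pathway":
        pm = enumerate_extreme_pathways(net, **kwargs)
    elif basis == "elementary_mode":
        pm = enumerate_elementary_modes(net, **kwargs)
    else:
        raise ValueError(f"unknown basis {basis!r}")
    counts = pm.type_counts()
    cpm = compact(filter_types(pm, {TYPE_I, TYPE_II}))
    return AnalysisContext(
        net=net,
        cpm=cpm,
        profile=participation_profile(cpm),
        graph=global_distances(net),
        type_counts=counts,
    )


def context_from_compact(net: MetabolicNetwork, cpm: CompactPathwayMatrix) -> AnalysisContext:
    return AnalysisContext(
        net=net,
        cpm=cpm,
        profile=participation_profile(cpm),
        graph=global_distances(net),
        type_counts={},
    )


def mu_sweep(
    ctx: AnalysisContext,
    meaningful,
    mu_values=None,
    rho_e: float = math.inf,
    rho_s: float = math.inf,
    tau: float = math.inf,
) -> list[tuple[float, float, float]]:
    """(mu, sigma, p_value) per mu; default grid 0..1 in steps of 0.025."""
    if mu_values is None:
        mu_values = [k * 0.025 for k in range(41)]
    out = []
    for mu in mu_values:
        _, res = ctx.evaluate(
            Params(mu=mu, rho_e=rho_e, rho_s=rho_s, tau=tau), meaningful
        )
        out.append((mu, res.sigma, res.p_value))
    return out
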