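"""Carving a target subsystem out of a genome-scale network.

Enumerating pathways genome-wide is hopeless, so a functional subsystem is
cut out and its boundary is closed with constrained exchange fluxes.  For
every metabolite shared between the target and the surrounding subsystem, a
duplicate metabolite M' replaces M on the surrounding side and a reversible
link reaction M <-> M' is appended; because the link has one substrate and
one product this leaves the steady-state flux space of the original
reactions unchanged.  Flux variability analysis of the link reaction then
bounds the possible exchange of M, and the sign pattern of (min, max)
decides the direction of the exchange flux added to the target:

    min < 0 < max   ->  reversible exchange
    min = 0 < max   ->  export only
    min < 0 = max   ->  import only
    min = max = 0   ->  no exchange (the metabolite cannot cross)

The forward direction of an added exchange takes M away from the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model_io import DEFAULT_BOUND, MetabolicNetwork, Metabolite, Reaction

logger = logging.getLogger(__name__)

#: |flux| below this counts as zero when classifying FVA bounds (LP noise)
ZERO_FLUX_TOL = 1e-6

_DUP_SUFFIX = "__dup"
_LINK_PREFIX = "LINK_"
_EXCH_PREFIX = "SEX_"


@dataclass
class SubsystemPartition:
    target_reaction_ids: set[str]
    surrounding_reaction_ids: set[str]
    shared_metabolite_ids: set[str]


@dataclass
class FvaResult:
    reaction_id: str
    min_flux: float
    max_flux: float

    def __post_init__(self) -> None:
        if self.min_flux > self.max_flux + 1e-9:
            raise ValueError("FVA minimum exceeds maximum")


@dataclass
class TargetNetwork:
    network: MetabolicNetwork
    constraint_case: dict[str, str] = field(default_factory=dict)  # met -> case
    fva: dict[str, FvaResult] = field(default_factory=dict)


class InfeasibleModelError(RuntimeError):
    pass


def partition_by_subsystem(
    net: MetabolicNetwork, labels: set[str]
) -> SubsystemPartition:
    """Split internal reactions by subsystem label; exchanges stay outside."""
    labels = set(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    available = {r.subsystem for r in net.reactions if r.subsystem}
    unknown = labels - available
    if unknown:
        raise KeyError(
            f"unknown subsystem labels {sorted(unknown)}; "
            f"available: {sorted(available)}"
        )
    target = {
        r.id
        for r in net.reactions
        if r.kind == "internal" and r.subsystem in labels
    }
    surrounding = {
        r.id for r in net.reactions if r.kind == "internal" and r.id not in target
    }
    target_mets = set().union(
        *(net.reaction(rid).metabolites() for rid in target)
    ) if target else set()
    surr_mets = set().union(
        *(net.reaction(rid).metabolites() for rid in surrounding)
    ) if surrounding else set()
    return SubsystemPartition(target, surrounding, target_mets & surr_mets)


def augment_with_links(
    net: MetabolicNetwork, part: SubsystemPartition
) -> MetabolicNetwork:
    """Duplicate each shared metabolite on the surrounding side and join the
    copies with a reversible 1:1 link reaction.  Non-target reactions
    (surrounding internals and the original exchanges) move to M'."""
    if not part.shared_metabolite_ids:
        return net.copy()
    aug = net.copy()
    for mid in sorted(part.shared_metabolite_ids):
        dup = mid + _DUP_SUFFIX
        aug.metabolites.append(Metabolite(dup, is_duplicate=True, duplicate_of=mid))
        for r in aug.reactions:
            if r.id in part.target_reaction_ids:
                continue
            if mid in r.stoichiometry:
                r.stoichiometry[dup] = r.stoichiometry.pop(mid)
    link_rxns = [
        Reaction(
            _LINK_PREFIX + mid,
            {mid: -1.0, mid + _DUP_SUFFIX: 1.0},
            reversible=True,
            kind="link",
        )
        for mid in sorted(part.shared_metabolite_ids)
    ]
    return MetabolicNetwork(aug.metabolites, aug.reactions + link_rxns)


def fva(net: MetabolicNetwork, objective_reaction_id: str) -> FvaResult:
    """Min and max flux of one reaction over {v : S v = 0, bounds}."""
    if objective_reaction_id not in net.rxn_index:
        raise KeyError(objective_reaction_id)
    S = net.S
    n = net.n_reactions
    bounds = [(r.lower_bound, r.upper_bound) for r in net.reactions]
    j = net.rxn_index[objective_reaction_id]
    out = {}
    for sense, sign in (("min", 1.0), ("max", -1.0)):
        c = np.zeros(n)
        c[j] = sign
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                      method="highs")
        if not res.success:
            raise InfeasibleModelError(
                f"FVA {sense} for {objective_reaction_id!r} failed: {res.message}"
            )
        out[sense] = sign * res.fun
        if abs(out[sense]) >= DEFAULT_BOUND - ZERO_FLUX_TOL:
            logger.warning(
                "FVA %s of %s hit the default bound; only the sign is used",
                sense, objective_reaction_id,
            )
    lo, hi = out["min"], out["max"]
    if abs(lo) <= ZERO_FLUX_TOL:
        lo = 0.0
    if abs(hi) <= ZERO_FLUX_TOL:
        hi = 0.0
    return FvaResult(objective_reaction_id, lo, hi)


def fva_all(net: MetabolicNetwork) -> dict[str, FvaResult]:
    return {r.id: fva(net, r.id) for r in net.reactions}


def assign_exchange_constraints(
    aug: MetabolicNetwork, part: SubsystemPartition
) -> TargetNetwork:
    """Build the target network with one FVA-constrained exchange per shared
    metabolite (forward = export from the target)."""
    shared = sorted(part.shared_metabolite_ids)
    cases: dict[str, str] = {}
    fvas: dict[str, FvaResult] = {}
    new_exchanges: list[Reaction] = []
    for mid in shared:
        link_id = _LINK_PREFIX + mid
        if link_id not in aug.rxn_index:
            raise ValueError(f"augmented network lacks link reaction for {mid!r}")
        res = fva(aug, link_id)
        fvas[mid] = res
        lo, hi = res.min_flux, res.max_flux
        if lo < 0 < hi:
            cases[mid] = "out-and-in"
            new_exchanges.append(
                Reaction(_EXCH_PREFIX + mid, {mid: -1.0}, reversible=True,
                         kind="primary-exchange")
            )
        elif lo == 0 and hi > 0:
            cases[mid] = "out"
            new_exchanges.append(
                Reaction(_EXCH_PREFIX + mid, {mid: -1.0}, reversible=False,
                         kind="primary-exchange")
            )
        elif lo < 0 and hi == 0:
            cases[mid] = "in"
            new_exchanges.append(
                Reaction(_EXCH_PREFIX + mid, {mid: 1.0}, reversible=False,
                         kind="primary-exchange")
            )
        else:
            cases[mid] = "none"
    target_rxns = [
        aug.reaction(rid).id for rid in sorted(part.target_reaction_ids)
    ]
    rxns = [aug.reaction(rid) for rid in target_rxns]
    # original exchange reactions whose metabolites live wholly in the target
    target_mets = set()
    for r in rxns:
        target_mets |= r.metabolites()
    for r in aug.reactions:
        if r.is_exchange and r.metabolites() <= target_mets:
            rxns.append(r)
    rxns = rxns + new_exchanges
    used_mets = set().union(*(r.metabolites() for r in rxns))
    mets = [m for m in aug.metabolites if m.id in used_mets]
    sub = MetabolicNetwork(
        [Metabolite(m.id, m.name, m.is_duplicate, m.duplicate_of) for m in mets],
        [
            Reaction(r.id, dict(r.stoichiometry), r.reversible, r.kind,
                     r.subsystem, r.name, r.lower_bound, r.upper_bound)
            for r in rxns
        ],
    )
    return TargetNetwork(network=sub, constraint_case=cases, fva=fvas)


def carve_target(
    net: MetabolicNetwork, labels: set[str]
) -> TargetNetwork:
    """Partition, augment and constrain in one call."""
    part = partition_by_subsystem(net, labels)
    aug = augment_with_links(net, part)
    return assign_exchange_constraints(aug, part)
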