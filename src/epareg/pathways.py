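"""Extreme-pathway and elementary-mode enumeration, typing, and compaction.

The flux cone of a network is ``{v : S v = 0, v_i >= 0 for irreversible i}``.
Enumeration works on the fully split network (every reversible reaction
replaced by an irreversible forward/backward pair) with an incremental
double-description tableau over exact integers: rays are combined pairwise to
zero out one metabolite at a time, and a candidate is kept only if no other
ray's support is contained in its support (the standard elementarity test).
The surviving rays are the support-minimal steady-state flux vectors of the
split cone.

Extreme pathways keep internal reversible reactions split but treat each
reversible exchange flux as one signed coordinate; they are recovered from
the elementary-mode set by an exact rank test on the faces of that partially
split cone.  The forward+backward two-cycle of each internal reversible
reaction is itself an extreme ray of the split cone and is reported as a
type III (purely internal, thermodynamically infeasible) pathway; such
cycles never survive into the compact form used downstream.

Pathway types: type I touches primary exchange fluxes, type II touches only
currency (cofactor-load) exchanges, type III touches no exchange at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd
from typing import Sequence

from .model_io import MetabolicNetwork, Reaction

#: refuse plain enumeration above this many internal reactions
DEFAULT_INTERNAL_CAP = 400

TYPE_I, TYPE_II, TYPE_III = "I", "II", "III"


class EnumerationSizeError(RuntimeError):
    pass


class CompactionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# containers


@dataclass
class PathwayMatrix:
    """Pathways over a (reversibility-split) column layout.

    ``columns`` lists ``(reaction_id, direction)`` pairs.  Internal reversible
    reactions contribute two columns (+1 forward, -1 backward) holding
    non-negative entries; every other reaction contributes a single +1 column
    whose entry is signed for reversible exchanges.
    """

    columns: list[tuple[str, int]]
    vectors: list[tuple[int, ...]]
    basis: str  # extreme_pathway | elementary_mode | artificial
    reaction_ids: list[str]
    exchange_ids: frozenset[str]
    pathway_types: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pathway_types:
            self.pathway_types = [None] * len(self.vectors)

    def __len__(self) -> int:
        return len(self.vectors)

    def type_counts(self) -> dict[str, int]:
        out = {TYPE_I: 0, TYPE_II: 0, TYPE_III: 0}
        for t in self.pathway_types:
            if t is not None:
                out[t] += 1
        return out

    def net_vector(self, k: int) -> tuple[int, ...]:
        """Signed flux per network reaction (forward minus backward)."""
        net = {rid: 0 for rid in self.reaction_ids}
        for (rid, direction), x in zip(self.columns, self.vectors[k]):
            net[rid] += direction * x
        return tuple(net[rid] for rid in self.reaction_ids)


@dataclass
class CompactPathwayMatrix:
    """One signed element per network reaction, type III removed."""

    reaction_ids: list[str]
    vectors: list[tuple[int, ...]]
    source_types: list[str]
    exchange_ids: frozenset[str] = frozenset()

    def __len__(self) -> int:
        return len(self.vectors)

    def support(self, k: int) -> frozenset[str]:
        return frozenset(
            rid for rid, x in zip(self.reaction_ids, self.vectors[k]) if x != 0
        )


@dataclass
class ArtificialConfig:
    p: float
    t: int
    seed: int

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError("selection probability p must be in (0, 1]")
        if self.t < 1:
            raise ValueError("t must be >= 1")


# ---------------------------------------------------------------------------
# exact integer scaffolding


def _integer_columns(net: MetabolicNetwork) -> list[dict[int, int]]:
    """Reaction columns as sparse integer vectors over metabolite indices."""
    cols: list[dict[int, int]] = []
    for r in net.reactions:
        fracs = {
            net.met_index[mid]: Fraction(c).limit_denominator(10**9)
            for mid, c in r.stoichiometry.items()
        }
        denom = 1
        for f in fracs.values():
            denom = denom * f.denominator // gcd(denom, f.denominator)
        ints = {i: int(f * denom) for i, f in fracs.items()}
        g = 0
        for x in ints.values():
            g = gcd(g, abs(x))
        if g > 1:
            ints = {i: x // g for i, x in ints.items()}
        cols.append(ints)
    return cols


def _reduce(vec: list[int], resid: dict[int, int]) -> None:
    g = 0
    for x in vec:
        g = gcd(g, abs(x))
    for x in resid.values():
        g = gcd(g, abs(x))
    if g > 1:
        for i, x in enumerate(vec):
            vec[i] = x // g
        for k in list(resid):
            resid[k] //= g


def _enumerate_split_rays(
    split_cols: list[dict[int, int]], n_mets: int
) -> list[tuple[int, ...]]:
    """Support-minimal rays of ``{v >= 0 : S_split v = 0}`` (tableau method).

    Returns integer vectors over the split columns, gcd-normalised.  The
    elementarity test (no other ray's support inside a candidate's support
    union) runs on bit-packed support masks.
    """
    import numpy as np

    n = len(split_cols)
    words = (n + 63) // 64

    def pack(mask: int) -> "np.ndarray":
        return np.frombuffer(
            mask.to_bytes(words * 8, "little"), dtype=np.uint64
        ).copy()

    rays: list[tuple[list[int], dict[int, int], int]] = []  # (vec, resid, support)
    for j, col in enumerate(split_cols):
        vec = [0] * n
        vec[j] = 1
        rays.append((vec, dict(col), 1 << j))

    remaining = {i for i in range(n_mets) if any(i in c for c in split_cols)}
    while remaining:
        # cheapest metabolite first keeps intermediate ray counts small
        def cost(i: int) -> int:
            p = sum(1 for _, r, _ in rays if r.get(i, 0) > 0)
            q = sum(1 for _, r, _ in rays if r.get(i, 0) < 0)
            return p * q - (p + q)

        met = min(remaining, key=cost)
        remaining.discard(met)
        zer, pos, neg = [], [], []
        for ray in rays:
            x = ray[1].get(met, 0)
            (zer if x == 0 else pos if x > 0 else neg).append(ray)
        new: dict[int, tuple[list[int], dict[int, int]]] = {}
        if not (pos and neg):
            rays = zer
            continue
        support_mat = np.stack([pack(s) for _, _, s in rays])
        for v1, r1, s1 in pos:
            a = r1[met]
            neg_union = np.stack([pack(s1 | s2) for _, _, s2 in neg])
            # rows of support_mat that fit inside each candidate union
            fits = (support_mat[:, None, :] & ~neg_union[None, :, :]) == 0
            n_inside = fits.all(axis=2).sum(axis=0)
            for k2, (v2, r2, s2) in enumerate(neg):
                s = s1 | s2
                if s in new:
                    continue
                # elementarity: exactly the two parents fit inside the union
                if int(n_inside[k2]) > 2:
                    continue
                b = -r2[met]
                vec = [b * x1 + a * x2 for x1, x2 in zip(v1, v2)]
                resid: dict[int, int] = {}
                for k in set(r1) | set(r2):
                    val = b * r1.get(k, 0) + a * r2.get(k, 0)
                    if val:
                        resid[k] = val
                _reduce(vec, resid)
                new[s] = (vec, resid)
        rays = zer + [(vec, resid, s) for s, (vec, resid) in new.items()]
    return [tuple(vec) for vec, resid, _ in rays if not resid]


def _split_layout(
    net: MetabolicNetwork, split_exchanges: bool
) -> tuple[list[tuple[str, int]], list[dict[int, int]]]:
    """Column layout for enumeration: (reaction, direction) plus S columns."""
    base = _integer_columns(net)
    columns: list[tuple[str, int]] = []
    cols: list[dict[int, int]] = []
    for r, col in zip(net.reactions, base):
        columns.append((r.id, +1))
        cols.append(col)
        if r.reversible and (split_exchanges or not r.is_exchange):
            columns.append((r.id, -1))
            cols.append({k: -v for k, v in col.items()})
    return columns, cols


def _enumerate_signed_modes(
    net: MetabolicNetwork,
) -> tuple[list[tuple[int, ...]], list[list[tuple[str, int]]]]:
    """All feasible signed modes (per network reaction) plus the internal
    futile two-cycles, enumerated on a reduced tableau.

    Metabolites whose only boundary is a reversible single-metabolite
    exchange flux are treated as external: their balance rows are dropped and
    the exchange flux is reconstructed from the internal net production, which
    keeps the tableau small without changing the mode set.
    """
    base = _integer_columns(net)
    rxns = net.reactions
    # reversible single-metabolite exchanges are determined by the rest
    dropped: dict[str, tuple[int, int]] = {}  # rid -> (met_index, coeff)
    ext_rows: set[int] = set()
    for r, col in zip(rxns, base):
        if r.is_exchange and r.reversible and len(col) == 1:
            (mi, c), = col.items()
            if mi not in ext_rows:
                dropped[r.id] = (mi, c)
                ext_rows.add(mi)
    columns: list[tuple[str, int]] = []
    cols: list[dict[int, int]] = []
    for r, col in zip(rxns, base):
        if r.id in dropped:
            continue
        red = {k: v for k, v in col.items() if k not in ext_rows}
        columns.append((r.id, +1))
        cols.append(red)
        if r.reversible:
            columns.append((r.id, -1))
            cols.append({k: -v for k, v in red.items()})
    rays = _enumerate_split_rays(cols, net.n_metabolites)

    rxn_order = [r.id for r in rxns]
    full_cols = {r.id: c for r, c in zip(rxns, base)}
    signed_modes: list[tuple[int, ...]] = []
    cycles: list[list[tuple[str, int]]] = []
    for ray in rays:
        used = [(key, x) for key, x in zip(columns, ray) if x != 0]
        net_flux = {rid: 0 for rid in rxn_order}
        for (rid, direction), x in used:
            net_flux[rid] += direction * x
        if all(x == 0 for x in net_flux.values()):
            # forward+backward two-cycle of one reversible reaction
            cycles.append([key for key, _ in used])
            continue
        # reconstruct the dropped exchange fluxes from metabolite balances
        for rid, (mi, c) in dropped.items():
            prod = 0
            for other, f in net_flux.items():
                if other == rid or f == 0:
                    continue
                prod += full_cols[other].get(mi, 0) * f
            net_flux[rid] = -prod // c if prod % c == 0 else 0
            if -net_flux[rid] * c != prod:
                raise AssertionError("non-integral reconstructed exchange flux")
        vec = [net_flux[rid] for rid in rxn_order]
        g = 0
        for x in vec:
            g = gcd(g, abs(x))
        if g > 1:
            vec = [x // g for x in vec]
        signed_modes.append(tuple(vec))
    return signed_modes, cycles


def _nullity(cols: list[dict[int, int]], n_mets: int) -> int:
    """Exact nullity of the matrix with the given columns."""
    # Gaussian elimination over Fractions, column-count minus rank
    ncols = len(cols)
    rows: list[list[Fraction]] = [
        [Fraction(c.get(i, 0)) for c in cols] for i in range(n_mets)
    ]
    rank = 0
    for col in range(ncols):
        piv = next((r for r in range(rank, n_mets) if rows[r][col] != 0), None)
        if piv is None:
            continue
        rows[rank], rows[piv] = rows[piv], rows[rank]
        inv = rows[rank][col]
        rows[rank] = [x / inv for x in rows[rank]]
        for r in range(n_mets):
            if r != rank and rows[r][col] != 0:
                f = rows[r][col]
                rows[r] = [x - f * y for x, y in zip(rows[r], rows[rank])]
        rank += 1
        if rank == min(ncols, n_mets):
            break
    return ncols - rank


def _check_cap(net: MetabolicNetwork, cap: int) -> None:
    n_int = len(net.internal_reactions()) + len(net.link_reactions())
    if n_int > cap:
        raise EnumerationSizeError(
            f"{n_int} internal reactions exceeds the enumeration cap ({cap}); "
            "carve a target subsystem first (epareg.subsystem)"
        )


# ---------------------------------------------------------------------------
# public operations


def _signed_net(
    columns: list[tuple[str, int]], vec: Sequence[int], rxn_order: list[str]
) -> tuple[int, ...]:
    net = {rid: 0 for rid in rxn_order}
    for (rid, direction), x in zip(columns, vec):
        net[rid] += direction * x
    return tuple(net[rid] for rid in rxn_order)


def _canonical_sign(vec: tuple[int, ...]) -> tuple[int, ...]:
    for x in vec:
        if x > 0:
            return vec
        if x < 0:
            return tuple(-y for y in vec)
    return vec


def _dedupe_reversals(signed_vectors: list[tuple[int, ...]]) -> list[tuple[int, ...]]:
    """Drop the mirror twin of fully reversible modes.

    Each vector arriving here is feasible as enumerated.  When both a mode
    and its exact reverse are present (every participating reaction
    reversible) keep the sign-canonical one; a mode whose reverse is
    infeasible is kept in its enumerated orientation.
    """
    uniq = sorted(set(signed_vectors))
    present = set(uniq)
    out = []
    for v in uniq:
        neg = tuple(-x for x in v)
        if neg in present and _canonical_sign(v) != v:
            continue
        out.append(v)
    return out


def enumerate_elementary_modes(
    net: MetabolicNetwork, cap: int = DEFAULT_INTERNAL_CAP
) -> PathwayMatrix:
    """Complete elementary-mode set (support-minimal steady-state vectors).

    A mode and its exact reverse (when every participating reaction is
    reversible) are reported once, sign-canonicalised.
    """
    if net.n_reactions < 1:
        raise ValueError("network has no reactions")
    _check_cap(net, cap)
    # full tableau, no external-metabolite reduction: support-minimality must
    # see the exchange coordinates, else through-flux modes are lost
    columns, cols = _split_layout(net, split_exchanges=True)
    rays = _enumerate_split_rays(cols, net.n_metabolites)
    rxn_order = [r.id for r in net.reactions]
    signed_all = []
    for ray in rays:
        signed = _signed_net(columns, ray, rxn_order)
        if all(x == 0 for x in signed):  # forward+backward futile two-cycle
            continue
        signed_all.append(signed)
    out_cols: list[tuple[str, int]] = _ep_columns(net)
    vectors = [_to_layout(net, out_cols, v) for v in _dedupe_reversals(signed_all)]
    vectors.sort()
    pm = PathwayMatrix(
        columns=out_cols,
        vectors=vectors,
        basis="elementary_mode",
        reaction_ids=rxn_order,
        exchange_ids=frozenset(r.id for r in net.reactions if r.is_exchange),
    )
    return classify_pathways(pm, _currency_ids(net))


def _ep_columns(net: MetabolicNetwork) -> list[tuple[str, int]]:
    cols: list[tuple[str, int]] = []
    for r in net.reactions:
        cols.append((r.id, +1))
        if r.reversible and not r.is_exchange:
            cols.append((r.id, -1))
    return cols


def _to_layout(
    net: MetabolicNetwork, ep_cols: list[tuple[str, int]], signed: tuple[int, ...]
) -> tuple[int, ...]:
    """Signed per-reaction vector -> split-internal / signed-exchange layout."""
    by_rxn = dict(zip((r.id for r in net.reactions), signed))
    out = []
    for rid, direction in ep_cols:
        x = by_rxn[rid]
        r = net.reaction(rid)
        if r.reversible and not r.is_exchange:
            out.append(max(direction * x, 0))
        else:
            out.append(x)
    return tuple(out)


def _currency_ids(net: MetabolicNetwork) -> frozenset[str]:
    return frozenset(r.id for r in net.reactions if r.kind == "currency-exchange")


def enumerate_extreme_pathways(
    net: MetabolicNetwork, cap: int = DEFAULT_INTERNAL_CAP
) -> PathwayMatrix:
    """Complete duplicate-free set of extreme rays of the flux cone.

    Internal reversible reactions are split into forward/backward pairs, so
    each such reaction's futile two-cycle appears as a (type III) extreme
    ray; reversible exchange fluxes stay as single signed coordinates.
    """
    if net.n_reactions < 1:
        raise ValueError("network has no reactions")
    _check_cap(net, cap)
    signed_all, raw_cycles = _enumerate_signed_modes(net)
    rxn_order = [r.id for r in net.reactions]

    ep_cols = _ep_columns(net)
    # exact S in the EP layout, plus the free (reversible exchange) coords
    int_cols = _integer_columns(net)
    by_rid = dict(zip(rxn_order, int_cols))
    ep_S: list[dict[int, int]] = []
    free: list[int] = []
    for idx, (rid, direction) in enumerate(ep_cols):
        col = by_rid[rid]
        ep_S.append(col if direction > 0 else {k: -v for k, v in col.items()})
        r = net.reaction(rid)
        if r.is_exchange and r.reversible:
            free.append(idx)

    def is_extreme(vec: tuple[int, ...]) -> bool:
        active = sorted(set(free) | {i for i, x in enumerate(vec) if x != 0})
        return _nullity([ep_S[i] for i in active], net.n_metabolites) == 1

    cycle_vecs: list[tuple[int, ...]] = []
    col_keys = set(ep_cols)
    for used in raw_cycles:
        # internal futile two-cycle: recover it in the split layout;
        # an exchange forward/backward pair is no pathway at all
        if all(key in col_keys for key in used):
            cycle_vecs.append(
                tuple(1 if key in used else 0 for key in ep_cols)
            )
    vectors = []
    for vec in cycle_vecs + [
        _to_layout(net, ep_cols, v) for v in _dedupe_reversals(signed_all)
    ]:
        if is_extreme(vec):
            vectors.append(vec)
    vectors = sorted(set(vectors))
    pm = PathwayMatrix(
        columns=ep_cols,
        vectors=vectors,
        basis="extreme_pathway",
        reaction_ids=rxn_order,
        exchange_ids=frozenset(r.id for r in net.reactions if r.is_exchange),
    )
    return classify_pathways(pm, _currency_ids(net))


def classify_pathways(
    pm: PathwayMatrix, currency_exchange_ids: set[str] | frozenset[str]
) -> PathwayMatrix:
    """Assign type I/II/III from the exchange coordinates of each pathway."""
    currency = set(currency_exchange_ids)
    col_rids = [rid for rid, _ in pm.columns]
    types: list[str] = []
    for vec in pm.vectors:
        used_exchange = {
            rid
            for rid, x in zip(col_rids, vec)
            if x != 0 and rid in pm.exchange_ids
        }
        if not used_exchange:
            types.append(TYPE_III)
        elif used_exchange <= currency:
            types.append(TYPE_II)
        else:
            types.append(TYPE_I)
    pm.pathway_types = types
    return pm


def compact(pm: PathwayMatrix) -> CompactPathwayMatrix:
    """Merge each forward/backward split pair into one signed net element.

    Type III pathways must be filtered out beforehand; a pathway carrying
    flux through both members of a split pair would be a futile cycle the
    enumeration should have excluded, and raises.
    """
    if TYPE_III in (pm.pathway_types or []):
        raise ValueError("filter type III pathways before compaction")
    vectors: list[tuple[int, ...]] = []
    for k, vec in enumerate(pm.vectors):
        net: dict[str, int] = {rid: 0 for rid in pm.reaction_ids}
        pos_and_neg: dict[str, list[int]] = {}
        for (rid, direction), x in zip(pm.columns, vec):
            net[rid] += direction * x
            pos_and_neg.setdefault(rid, []).append(x)
        for rid, parts in pos_and_neg.items():
            if len(parts) == 2 and all(x != 0 for x in parts):
                raise CompactionError(
                    f"pathway {k}: both directions of {rid!r} carry flux"
                )
        vectors.append(tuple(net[rid] for rid in pm.reaction_ids))
    return CompactPathwayMatrix(
        reaction_ids=list(pm.reaction_ids),
        vectors=vectors,
        source_types=list(pm.pathway_types),
        exchange_ids=pm.exchange_ids,
    )


def filter_types(pm: PathwayMatrix, keep: set[str]) -> PathwayMatrix:
    idx = [k for k, t in enumerate(pm.pathway_types) if t in keep]
    return PathwayMatrix(
        columns=list(pm.columns),
        vectors=[pm.vectors[k] for k in idx],
        basis=pm.basis,
        reaction_ids=list(pm.reaction_ids),
        exchange_ids=pm.exchange_ids,
        pathway_types=[pm.pathway_types[k] for k in idx],
    )


def compact_extreme_pathways(
    net: MetabolicNetwork, cap: int = DEFAULT_INTERNAL_CAP
) -> CompactPathwayMatrix:
    """Convenience: enumerate, drop type III, compact."""
    pm = enumerate_extreme_pathways(net, cap=cap)
    return compact(filter_types(pm, {TYPE_I, TYPE_II}))


# ---------------------------------------------------------------------------
# TSV serialisation (pathways x reactions, one type column)


def write_compact_tsv(
    cpm: CompactPathwayMatrix, path, header: str | None = None
) -> None:
    from pathlib import Path

    lines = []
    if header:
        for h in header.splitlines():
            lines.append(f"# {h}")
    lines.append("\t".join(["pathway", "type"] + list(cpm.reaction_ids)))
    for k, vec in enumerate(cpm.vectors):
        lines.append(
            "\t".join([f"p{k+1}", cpm.source_types[k]] + [str(x) for x in vec])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_compact_tsv(path, exchange_ids=frozenset()) -> CompactPathwayMatrix:
    from pathlib import Path

    rows = [
        line.split("\t")
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    header = rows[0]
    if header[:2] != ["pathway", "type"]:
        raise ValueError(f"{path}: not a compact pathway table")
    rids = header[2:]
    vectors, types = [], []
    for row in rows[1:]:
        types.append(row[1])
        vectors.append(tuple(int(float(x)) for x in row[2:]))
    return CompactPathwayMatrix(rids, vectors, types, frozenset(exchange_ids))


# ---------------------------------------------------------------------------
# artificial pathways


def generate_artificial_pathways(
    eps: CompactPathwayMatrix, cfg: ArtificialConfig
) -> CompactPathwayMatrix:
    """Sums of randomly selected extreme pathways (an EP enters each draw
    independently with probability ``p``; ``t`` draws; unique non-zero sums
    form the set)."""
    import random

    rng = random.Random(cfg.seed)
    n = len(eps.reaction_ids)
    seen: set[tuple[int, ...]] = set()
    vectors: list[tuple[int, ...]] = []
    for _ in range(cfg.t):
        total = [0] * n
        for vec in eps.vectors:
            if rng.random() < cfg.p:
                for i, x in enumerate(vec):
                    total[i] += x
        tot = tuple(total)
        if all(x == 0 for x in tot) or tot in seen:
            continue
        seen.add(tot)
        vectors.append(tot)
    return CompactPathwayMatrix(
        reaction_ids=list(eps.reaction_ids),
        vectors=vectors,
        source_types=["artificial"] * len(vectors),
        exchange_ids=eps.exchange_ids,
    )
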