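"""Independent brute-force oracles for pathway enumeration.

These deliberately avoid the package's tableau/rank code paths: supports are
enumerated exhaustively and checked with sympy's exact nullspace.
"""

from __future__ import annotations

from itertools import combinations

import sympy

from epareg.model_io import MetabolicNetwork


def _signed_matrix(net: MetabolicNetwork) -> sympy.Matrix:
    S = sympy.zeros(net.n_metabolites, net.n_reactions)
    for j, r in enumerate(net.reactions):
        for mid, c in r.stoichiometry.items():
            S[net.met_index[mid], j] = sympy.Rational(c)
    return S


def brute_force_elementary_modes(net: MetabolicNetwork) -> set[tuple]:
    """All support-minimal steady-state signed flux vectors, canonicalised.

    A support is elementary iff the nullspace of S restricted to it is
    one-dimensional, its generator is non-zero on the whole support, and a
    sign choice exists respecting the irreversibilities.  Exponential in the
    reaction count; use on tiny networks only.
    """
    S = _signed_matrix(net)
    n = net.n_reactions
    irreversible = [not r.reversible for r in net.reactions]
    found: dict[frozenset, tuple] = {}
    for size in range(1, n + 1):
        for supp in combinations(range(n), size):
            if any(frozenset(supp) > k for k in found):
                continue
            sub = S[:, list(supp)]
            null = sub.nullspace()
            if len(null) != 1:
                continue
            gen = [null[0][i, 0] for i in range(size)]
            if any(g == 0 for g in gen):
                continue
            # scale to integers
            denoms = [sympy.fraction(g)[1] for g in gen]
            lcm = sympy.ilcm(*denoms) if len(denoms) > 1 else denoms[0]
            gen = [sympy.Integer(g * lcm) for g in gen]
            gcd = sympy.igcd(*[abs(g) for g in gen]) if len(gen) > 1 else abs(gen[0])
            gen = [int(g // gcd) for g in gen]
            feasible = []
            for sign in (1, -1):
                vals = [sign * g for g in gen]
                if all(
                    vals[k] >= 0 or not irreversible[supp[k]]
                    for k in range(size)
                ):
                    feasible.append(vals)
            if not feasible:
                continue
            if len(feasible) == 2:
                # fully reversible mode: canonical sign has the first
                # non-zero coordinate positive
                first = next(x for x in feasible[0] if x != 0)
                vals = feasible[0] if first > 0 else feasible[1]
            else:
                vals = feasible[0]
            vec = [0] * n
            for k, j in enumerate(supp):
                vec[j] = vals[k]
            found.setdefault(frozenset(supp), tuple(vec))
    return set(found.values())


def brute_force_extreme_pathways(net: MetabolicNetwork) -> set[tuple]:
    """Extreme rays of the flux cone with split internal reversibles and
    signed reversible exchanges, obtained by filtering the brute-force
    elementary modes with an exact face-dimension test, plus the internal
    two-cycles."""
    S = _signed_matrix(net)
    modes = brute_force_elementary_modes(net)
    free = [
        j
        for j, r in enumerate(net.reactions)
        if r.is_exchange and r.reversible
    ]
    out = set()
    for vec in modes:
        active = sorted(set(free) | {j for j, x in enumerate(vec) if x != 0})
        # columns of the split-internal representation restricted to the face
        cols = []
        for j in active:
            cols.append(S[:, j])
        face = sympy.Matrix.hstack(*cols)
        if len(face.nullspace()) == 1:
            out.add(vec)
    return out
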