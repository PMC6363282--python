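"""Constraint-based metabolic model containers and readers.

The package operates on a small, explicit network representation: an ordered
list of metabolites, an ordered list of reactions (each a sparse signed
stoichiometry over metabolite ids), and the stoichiometric matrix S derived
from them.  Reaction and metabolite order is file order and is preserved
everywhere; all downstream tie-breaking refers to this order.

Three on-disk formats are supported: SBML and BiGG-style JSON (read through
COBRApy) and a plain-text TSV dialect used for fixtures and intermediate
artifacts (one reaction per line, ``id: 2 A + B -> C``, with ``<->`` marking
reversible reactions).
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np

REACTION_KINDS = ("internal", "primary-exchange", "currency-exchange", "link")

#: COBRA-convention default flux bounds, used only by LP-based steps.
DEFAULT_BOUND = 1000.0


class ModelFormatError(ValueError):
    """Raised when an input file cannot be parsed as a metabolic model."""


class ModelValidationError(ValueError):
    """Raised when a parsed model violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    is_duplicate: bool = False
    duplicate_of: str | None = None

    def __post_init__(self) -> None:
        if self.is_duplicate and not self.duplicate_of:
            raise ModelValidationError(
                f"duplicate metabolite {self.id!r} must reference its original"
            )


@dataclass
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed)."""

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    kind: str = "internal"
    subsystem: str = ""
    name: str = ""
    lower_bound: float | None = None
    upper_bound: float | None = None

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r} has empty stoichiometry")
        if self.kind not in REACTION_KINDS:
            raise ModelValidationError(f"reaction {self.id!r}: unknown kind {self.kind!r}")
        if self.lower_bound is None:
            self.lower_bound = -DEFAULT_BOUND if self.reversible else 0.0
        if self.upper_bound is None:
            self.upper_bound = DEFAULT_BOUND
        if not self.reversible and self.lower_bound < 0:
            raise ModelValidationError(
                f"irreversible reaction {self.id!r} has negative lower bound"
            )
        if self.kind == "link":
            coeffs = sorted(self.stoichiometry.values())
            if len(coeffs) != 2 or coeffs != [-1.0, 1.0]:
                raise ModelValidationError(
                    f"link reaction {self.id!r} must be a 1:1 metabolite transfer"
                )

    @property
    def is_exchange(self) -> bool:
        return self.kind in ("primary-exchange", "currency-exchange")

    def substrates(self) -> set[str]:
        return {m for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> set[str]:
        return {m for m, c in self.stoichiometry.items() if c > 0}

    def metabolites(self) -> set[str]:
        return set(self.stoichiometry)


class MetabolicNetwork:
    """Ordered metabolites + reactions with the stoichiometric matrix S."""

    def __init__(self, metabolites: list[Metabolite], reactions: list[Reaction]):
        met_ids = [m.id for m in metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelValidationError("metabolite ids are not unique")
        rxn_ids = [r.id for r in reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelValidationError("reaction ids are not unique")
        known = set(met_ids)
        for r in reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(missing)}"
                )
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        self.met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self.rxn_index = {r.id: j for j, r in enumerate(self.reactions)}

    # -- basic accessors ---------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self.rxn_index[rid]]

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self.met_index[mid]]

    def internal_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == "internal"]

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def link_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == "link"]

    @property
    def S(self) -> np.ndarray:
        """Dense stoichiometric matrix, metabolites x reactions."""
        S = np.zeros((self.n_metabolites, self.n_reactions))
        for j, r in enumerate(self.reactions):
            for mid, coeff in r.stoichiometry.items():
                S[self.met_index[mid], j] = coeff
        return S

    def S_fractions(self) -> list[list[Fraction]]:
        """Exact rational S for the enumeration code paths."""
        S = [[Fraction(0)] * self.n_reactions for _ in range(self.n_metabolites)]
        for j, r in enumerate(self.reactions):
            for mid, coeff in r.stoichiometry.items():
                S[self.met_index[mid]][j] = Fraction(coeff).limit_denominator(10**9)
        return S

    def copy(self) -> "MetabolicNetwork":
        mets = [
            Metabolite(m.id, m.name, m.is_duplicate, m.duplicate_of)
            for m in self.metabolites
        ]
        rxns = [
            Reaction(
                r.id,
                dict(r.stoichiometry),
                r.reversible,
                r.kind,
                r.subsystem,
                r.name,
                r.lower_bound,
                r.upper_bound,
            )
            for r in self.reactions
        ]
        return MetabolicNetwork(mets, rxns)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"MetabolicNetwork({self.n_metabolites} metabolites, "
            f"{self.n_reactions} reactions, "
            f"{len(self.exchange_reactions())} exchange)"
        )


# ---------------------------------------------------------------------------
# exchange detection


def detect_exchange(reaction: Reaction) -> bool:
    """A reaction with metabolites on only one side is an exchange."""
    return not reaction.substrates() or not reaction.products()


def classify_exchanges(
    net: MetabolicNetwork,
    currency_ids: set[str] | None = None,
    exchange_override: set[str] | None = None,
) -> MetabolicNetwork:
    """Label exchange reactions in place; returns the same network.

    Exchanges are auto-detected as one-sided reactions unless an explicit
    override id list is given.  Reactions in ``currency_ids`` are labelled
    currency exchanges (cofactor loads); the rest are primary exchanges.
    """
    currency_ids = currency_ids or set()
    for r in net.reactions:
        if r.kind == "link":
            continue
        is_ex = r.id in exchange_override if exchange_override is not None else detect_exchange(r)
        if is_ex:
            r.kind = "currency-exchange" if r.id in currency_ids else "primary-exchange"
        else:
            r.kind = "internal"
    return net


# ---------------------------------------------------------------------------
# TSV dialect

_ARROWS = ("<->", "->")


def _parse_side(text: str, rid: str, lineno: int) -> dict[str, float]:
    out: dict[str, float] = {}
    text = text.strip()
    if not text:
        return out
    for term in re.split(r"\s\+\s", text):
        term = term.strip()
        if not term:
            continue
        m = re.match(r"^(\d+(?:\.\d+)?(?:/\d+)?)\s+(\S+)$", term)
        if m:
            num = m.group(1)
            coeff = float(Fraction(num)) if "/" in num else float(num)
            met = m.group(2)
        else:
            coeff, met = 1.0, term
        if not re.match(r"^[A-Za-z0-9_\-\[\]'()]+$", met):
            raise ModelFormatError(f"line {lineno}: bad metabolite token {met!r} in {rid!r}")
        out[met] = out.get(met, 0.0) + coeff
    return out


def parse_reaction_line(line: str, lineno: int = 0) -> Reaction:
    """Parse one ``id: lhs -> rhs`` line of the TSV dialect."""
    parts = line.split("\t")
    body, meta = parts[0], parts[1:]
    if ":" not in body:
        raise ModelFormatError(f"line {lineno}: missing ':' separator")
    rid, eq = body.split(":", 1)
    rid = rid.strip()
    if not rid:
        raise ModelFormatError(f"line {lineno}: empty reaction id")
    reversible = "<->" in eq
    arrow = "<->" if reversible else "->"
    if arrow not in eq:
        raise ModelFormatError(f"line {lineno}: no reaction arrow in {rid!r}")
    lhs, rhs = eq.split(arrow, 1)
    stoich: dict[str, float] = {}
    for mid, c in _parse_side(lhs, rid, lineno).items():
        stoich[mid] = stoich.get(mid, 0.0) - c
    for mid, c in _parse_side(rhs, rid, lineno).items():
        stoich[mid] = stoich.get(mid, 0.0) + c
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise ModelFormatError(f"line {lineno}: reaction {rid!r} has no net stoichiometry")
    kwargs: dict = {}
    for tok in meta:
        tok = tok.strip()
        if not tok:
            continue
        if "=" not in tok:
            raise ModelFormatError(f"line {lineno}: bad metadata token {tok!r}")
        key, val = tok.split("=", 1)
        key = key.strip()
        if key == "subsystem":
            kwargs["subsystem"] = val.strip()
        elif key == "name":
            kwargs["name"] = val.strip()
        elif key == "kind":
            kwargs["kind"] = val.strip()
        elif key == "lb":
            kwargs["lower_bound"] = float(val)
        elif key == "ub":
            kwargs["upper_bound"] = float(val)
        else:
            raise ModelFormatError(f"line {lineno}: unknown metadata key {key!r}")
    return Reaction(rid, stoich, reversible=reversible, **kwargs)


def read_tsv(path: str | Path) -> MetabolicNetwork:
    reactions: list[Reaction] = []
    met_order: list[str] = []
    seen: set[str] = set()
    explicit_kinds = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        r = parse_reaction_line(raw, lineno)
        if r.kind != "internal" or "kind=" in raw:
            explicit_kinds = True
        reactions.append(r)
        for mid in r.stoichiometry:
            if mid not in seen:
                seen.add(mid)
                met_order.append(mid)
    mets = [Metabolite(mid) for mid in met_order]
    net = MetabolicNetwork(mets, reactions)
    if not explicit_kinds:
        classify_exchanges(net)
    else:
        # respect explicit kinds; auto-detect only the unlabelled one-sided rest
        for r in net.reactions:
            if r.kind == "internal" and detect_exchange(r):
                r.kind = "primary-exchange"
    return net


def write_tsv(net: MetabolicNetwork, path: str | Path, header: str | None = None) -> None:
    lines = []
    if header:
        for h in header.splitlines():
            lines.append(f"# {h}")
    for r in net.reactions:
        subs = []
        prods = []
        for mid, c in r.stoichiometry.items():
            mag = abs(c)
            coeff = "" if mag == 1 else (f"{int(mag)} " if float(mag).is_integer() else f"{mag} ")
            (subs if c < 0 else prods).append(f"{coeff}{mid}")
        arrow = "<->" if r.reversible else "->"
        body = f"{r.id}: {' + '.join(subs)} {arrow} {' + '.join(prods)}".strip()
        meta = []
        if r.kind != "internal":
            meta.append(f"kind={r.kind}")
        if r.subsystem:
            meta.append(f"subsystem={r.subsystem}")
        lines.append("\t".join([body] + meta))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# COBRA-backed readers


def _from_cobra(model) -> MetabolicNetwork:
    mets = [Metabolite(m.id, m.name or "") for m in model.metabolites]
    rxns = []
    for r in model.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        rxns.append(
            Reaction(
                r.id,
                stoich,
                reversible=r.lower_bound < 0,
                subsystem=r.subsystem or "",
                name=r.name or "",
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
            )
        )
    net = MetabolicNetwork(mets, rxns)
    classify_exchanges(net)
    return net


def read_model(
    path: str | Path,
    format: str | None = None,
    currency_ids: set[str] | None = None,
    exchange_override: set[str] | None = None,
) -> MetabolicNetwork:
    """Read a model from SBML, BiGG-style JSON, or the repo TSV dialect."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".xml": "sbml", ".sbml": "sbml", ".json": "json"}.get(
            path.suffix.lower(), "tsv"
        )
    if format == "tsv":
        net = read_tsv(path)
    elif format == "json":
        import cobra.io

        try:
            net = _from_cobra(cobra.io.load_json_model(str(path)))
        except Exception as exc:  # cobra raises assorted json/key errors
            raise ModelFormatError(f"{path}: not a readable JSON model: {exc}") from exc
    elif format == "sbml":
        import cobra.io

        try:
            net = _from_cobra(cobra.io.read_sbml_model(str(path)))
        except Exception as exc:
            raise ModelFormatError(f"{path}: not a readable SBML model: {exc}") from exc
    else:
        raise ValueError(f"unknown format {format!r}")
    if currency_ids or exchange_override:
        classify_exchanges(net, currency_ids, exchange_override)
    return net


# ---------------------------------------------------------------------------
# toy-network generator


def random_toy_network(
    n_metabolites: int,
    n_internal: int,
    n_exchange: int,
    seed: int,
    p_reversible: float = 0.3,
) -> MetabolicNetwork:
    """Random connected mass-balanced toy network, reproducible per seed.

    Internal reactions convert one or two metabolites into one or two others
    with unit/small-integer coefficients; exchange reactions are attached to
    the first ``n_exchange`` metabolites so inputs and outputs exist.  Every
    metabolite takes part in at least one reaction.
    """
    if min(n_metabolites, n_internal, n_exchange) < 1:
        raise ValueError("all counts must be >= 1")
    if n_exchange > n_metabolites:
        raise ValueError("cannot have more exchange reactions than metabolites")
    rng = random.Random(seed)
    mids = [f"M{i+1}" for i in range(n_metabolites)]
    reactions: list[Reaction] = []
    # backbone chain guarantees connectivity and that every metabolite appears
    for i in range(n_metabolites - 1):
        if len(reactions) >= n_internal:
            break
        reactions.append(
            Reaction(
                f"R{len(reactions)+1}",
                {mids[i]: -1.0, mids[i + 1]: 1.0},
                reversible=rng.random() < p_reversible,
            )
        )
    while len(reactions) < n_internal:
        n_sub = rng.choice([1, 1, 2])
        n_prod = rng.choice([1, 1, 2])
        subs = rng.sample(mids, n_sub)
        prods = rng.sample([m for m in mids if m not in subs], n_prod)
        stoich: dict[str, float] = {}
        for m in subs:
            stoich[m] = -float(rng.choice([1, 1, 2]))
        for m in prods:
            stoich[m] = float(rng.choice([1, 1, 2]))
        reactions.append(
            Reaction(
                f"R{len(reactions)+1}",
                stoich,
                reversible=rng.random() < p_reversible,
            )
        )
    for k in range(n_exchange):
        mid = mids[k]
        reactions.append(
            Reaction(f"EX_{mid}", {mid: 1.0 if k % 2 == 0 else -1.0}, reversible=True)
        )
    net = MetabolicNetwork([Metabolite(m) for m in mids], reactions)
    classify_exchanges(net)
    return net


# ---------------------------------------------------------------------------
# packaged hRBC fixture

_DATA_DIR = Path(__file__).parent / "data"


def hrbc_fixture() -> tuple[MetabolicNetwork, set[str], set[str]]:
    """The human red blood cell network with its regulated and currency sets.

    Returns ``(network, regulated_reaction_ids, currency_exchange_ids)``.
    The network covers glycolysis, the Rapoport-Luebering shunt, the pentose
    phosphate pathway and adenosine nucleotide metabolism: 39 metabolites and
    51 reactions, 19 of them exchange fluxes (nutrient exchanges plus the
    cofactor loads).  The regulated set lists the 10 reactions under known
    allosteric control.
    """
    regulated = {
        line.strip()
        for line in (_DATA_DIR / "hrbc_regulated.txt").read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    currency = {
        line.strip()
        for line in (_DATA_DIR / "hrbc_currency.txt").read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    net = read_tsv(_DATA_DIR / "hrbc.tsv")
    classify_exchanges(net, currency_ids=currency)
    return net, regulated, currency
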