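"""Reaction participation probabilities and Shannon entropies.

A reaction is *employed* by a compact pathway when its element is non-zero.
Under the uniform-utilization model one pathway is drawn uniformly at random
from the ``l`` available ones; the on/off state of every reaction is its
employment indicator in the drawn pathway.  All entropies (base 2, bits) are
computed from exact configuration counts over the ``l`` pathway columns --
never by floating accumulation of probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .pathways import CompactPathwayMatrix

#: tolerance below which an entropy is treated as exactly zero
ENTROPY_TOL = 1e-12
#: compact flux magnitudes below this never count as employment
EMPLOYMENT_TOL = 1e-9


@dataclass
class ParticipationProfile:
    """Binary reactions x pathways employment matrix."""

    matrix: np.ndarray  # uint8, n x l
    reaction_ids: list[str]

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.reaction_ids):
            raise ValueError("matrix shape does not match reaction ids")
        if self.matrix.shape[1] < 1:
            raise ValueError("need at least one pathway column")
        self._index = {rid: i for i, rid in enumerate(self.reaction_ids)}

    @property
    def l(self) -> int:
        return int(self.matrix.shape[1])

    def row(self, rid: str) -> np.ndarray:
        return self.matrix[self._index[rid]]

    def p_on(self, rid: str) -> float:
        return float(self.row(rid).sum()) / self.l


def participation_profile(cpm: CompactPathwayMatrix) -> ParticipationProfile:
    if len(cpm) < 1:
        raise ValueError("need at least one pathway")
    mat = np.zeros((len(cpm.reaction_ids), len(cpm)), dtype=np.uint8)
    for j, vec in enumerate(cpm.vectors):
        for i, x in enumerate(vec):
            if abs(x) > EMPLOYMENT_TOL:
                mat[i, j] = 1
    return ParticipationProfile(mat, list(cpm.reaction_ids))


def _config_counts(profile: ParticipationProfile, reaction_ids) -> list[int]:
    rows = [profile.row(rid) for rid in reaction_ids]
    if not rows:
        return [profile.l]
    sub = np.stack(rows)  # k x l
    # bit-pack each pathway's on/off configuration and count duplicates
    packed = np.ascontiguousarray(np.packbits(sub, axis=0).T)
    _, counts = np.unique(packed, axis=0, return_counts=True)
    return [int(c) for c in counts]


def entropy(profile: ParticipationProfile, reaction_set) -> float:
    """Joint Shannon entropy (bits) of the on/off states of a reaction set."""
    ids = sorted(set(reaction_set))
    if not ids:
        return 0.0
    l = profile.l
    return -sum((c / l) * math.log2(c / l) for c in _config_counts(profile, ids))


def conditional_entropy(profile: ParticipationProfile, X1, X2) -> float:
    """H(X1 | X2) = H(X1 u X2) - H(X2); X2 may be empty."""
    X1, X2 = set(X1), set(X2)
    if not X1:
        return 0.0
    h = entropy(profile, X1 | X2) - entropy(profile, X2)
    return max(h, 0.0)  # clip the negative rounding residue


def equivalent_couple(
    profile: ParticipationProfile,
    ri: str,
    rj: str,
    tol: float = ENTROPY_TOL,
    mode: str = "literal",
) -> bool:
    """Mutual zero conditional entropy between two reactions.

    ``literal`` follows the definition H(Ri|Rj) = H(Rj|Ri) = 0, which holds
    whenever each employment row determines the other (identical rows,
    complementary rows, or two constant rows).  ``identical_support``
    restricts equivalence to identical employment rows.
    """
    if mode == "identical_support":
        return bool(np.array_equal(profile.row(ri), profile.row(rj)))
    if mode != "literal":
        raise ValueError(f"unknown equivalence mode {mode!r}")
    return (
        conditional_entropy(profile, {ri}, {rj}) <= tol
        and conditional_entropy(profile, {rj}, {ri}) <= tol
    )


def pairwise_conditional_entropy(
    profile: ParticipationProfile, reaction_ids: list[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Matrix M[i, j] = H(Ri | Rj) for heat-map style reporting."""
    ids = reaction_ids if reaction_ids is not None else list(profile.reaction_ids)
    n = len(ids)
    out = np.zeros((n, n))
    singles = {rid: entropy(profile, {rid}) for rid in ids}
    for i, ri in enumerate(ids):
        for j, rj in enumerate(ids):
            if i == j:
                continue
            out[i, j] = entropy(profile, {ri, rj}) - singles[rj]
    return ids, out
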