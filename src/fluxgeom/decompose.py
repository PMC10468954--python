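"""Conic decomposition of flux vectors into few, low-degree EFMs.

Any steady-state flux vector v decomposes as v = sum_i lambda_i e^i with
lambda_i > 0 over EFMs. The decompositions built here are the structured
ones: every term lies in the inclusionwise minimal face of v, every term
has degree at most t+1 (lineality dimension plus one, i.e. it belongs to
the lineality space or to a minimal proper face), and after Caratheodory
reduction the number of terms is at most deg(v).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Optional, Sequence

from .cone import Face, FluxCone, degree as cone_degree, minimal_face
from .efm import EFM
from .exceptions import DomainError, ResourceError, VerificationError
from .netmodel import FluxVector
from .ratlinalg import (
    RationalMatrix,
    linear_opt,
    nullspace_basis,
    solve_nonneg,
)

__all__ = [
    "Decomposition",
    "decompose",
    "caratheodory_reduce",
    "count_minimal_decompositions",
    "verify_decomposition",
]

#: Default guard on the candidate set size for decomposition counting.
CANDIDATE_LIMIT = 25


@dataclass(frozen=True)
class Decomposition:
    """v = sum of coefficient * EFM, exactly, with all coefficients > 0."""

    target: FluxVector
    terms: tuple[tuple[Fraction, EFM], ...]
    face: Face

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def reconstruct(self) -> tuple[Fraction, ...]:
        total = [Fraction(0)] * len(self.target)
        for coeff, e in self.terms:
            total = [a + coeff * b for a, b in zip(total, e.vector.values)]
        return tuple(total)


def _candidates(
    cone: FluxCone, zero_set: frozenset[int], efms: Sequence[EFM]
) -> list[EFM]:
    """EFMs of degree <= t+1 inside the face {v_Z = 0}; reversible-pair EFMs
    contribute both orientations as separate candidates."""
    t = cone.dim_lineality
    out = []
    for e in efms:
        if e.degree > t + 1:
            continue
        if e.irr_support & zero_set:
            continue
        out.append(e)
        if e.is_reversible_pair:
            out.append(e.negated())
    return out


def decompose(
    cone: FluxCone, v: FluxVector, efms: Sequence[EFM]
) -> Decomposition:
    """Decompose v into at most deg(v) EFMs of degree <= t+1 in its minimal face.

    A nonnegative exact solution over all admissible candidates at once is
    found first (feasible because the low-degree EFMs of the face generate
    it), then Caratheodory-reduced to a linearly independent active set.
    """
    if all(x == 0 for x in v.values):
        raise DomainError("cannot decompose the zero vector")
    cone.check_membership(v)
    face = minimal_face(cone, v)
    cand = _candidates(cone, face.canonical_zero_set, efms)
    if not cand:
        raise VerificationError(
            "no admissible low-degree EFM candidates; EFM set incomplete?"
        )
    E = RationalMatrix(
        [[e.vector.values[i] for e in cand] for i in range(cone.n)]
    )
    lam = solve_nonneg(E, v.values, nonneg=range(len(cand)))
    if lam is None:
        raise VerificationError(
            "flux vector does not decompose over the low-degree EFMs of its "
            "face; EFM set incomplete?"
        )
    terms = [
        (coeff, e) for coeff, e in zip(lam, cand) if coeff > 0
    ]
    reduced = caratheodory_reduce(
        [(c, e.vector.values) for c, e in terms], v.values
    )
    # Map reduced vectors back to their EFM objects (positions preserved).
    by_vec = {e.vector.values: e for _, e in terms}
    final = tuple((c, by_vec[vec]) for c, vec in reduced)
    # At most one orientation of a reversible pair may survive reduction.
    pair_supports = [e.support for _, e in final if e.is_reversible_pair]
    if len(pair_supports) != len(set(pair_supports)):
        raise VerificationError(
            "both orientations of a reversible-pair EFM survived reduction"
        )
    k = cone_degree(cone, v)
    if len(final) > k:
        raise VerificationError(
            f"{len(final)} terms exceed the degree {k} of the target"
        )
    return Decomposition(target=v, terms=final, face=face)


def caratheodory_reduce(
    terms: Sequence[tuple[Fraction, Sequence[Fraction]]],
    target: Sequence[Fraction],
) -> list[tuple[Fraction, tuple[Fraction, ...]]]:
    """Reduce a conic combination until the active vectors are independent.

    While the active vectors are linearly dependent, an exact kernel
    combination is shifted off the coefficients with the largest step that
    keeps them nonnegative (ties broken by lowest candidate index); zeroed
    terms are dropped. The sum is preserved exactly at every step.
    """
    cur = [(Fraction(c), tuple(Fraction(x) for x in vec)) for c, vec in terms]
    tgt = tuple(Fraction(x) for x in target)
    total = [Fraction(0)] * len(tgt)
    for c, vec in cur:
        if c <= 0:
            raise ValueError("coefficients must be positive")
        total = [a + c * b for a, b in zip(total, vec)]
    if tuple(total) != tgt:
        raise ValueError("input combination does not sum to the target")
    while len(cur) > 1:
        mat = RationalMatrix(
            [[vec[i] for _, vec in cur] for i in range(len(tgt))]
        )
        kernel = nullspace_basis(mat)
        if not kernel:
            break
        mu = list(kernel[0])
        if all(m <= 0 for m in mu):
            mu = [-m for m in mu]
        theta = None
        for (lam, _), m in zip(cur, mu):
            if m > 0:
                ratio = lam / m
                if theta is None or ratio < theta:
                    theta = ratio
        new = []
        for (lam, vec), m in zip(cur, mu):
            lam2 = lam - theta * m
            if lam2 < 0:
                raise VerificationError("Caratheodory step produced a negative")
            if lam2 > 0:
                new.append((lam2, vec))
        cur = new
    return cur


def count_minimal_decompositions(
    cone: FluxCone,
    v: FluxVector,
    efms: Sequence[EFM],
    candidate_limit: Optional[int] = CANDIDATE_LIMIT,
) -> int:
    """Number of k-subsets of low-degree face EFMs that decompose v strictly
    positively, where k = deg(v).

    Each unordered k-subset counts once; a subset qualifies iff v is an
    exact combination of its vectors with every coefficient strictly
    positive (decided by an exact LP maximizing the smallest coefficient).
    """
    cone.check_membership(v)
    k = cone_degree(cone, v)
    face = minimal_face(cone, v)
    cand = _candidates(cone, face.canonical_zero_set, efms)
    if candidate_limit is not None and len(cand) > candidate_limit:
        raise ResourceError(
            f"{len(cand)} candidates exceed the counting limit {candidate_limit}"
        )
    count = 0
    for subset in combinations(range(len(cand)), k):
        vecs = [cand[i].vector.values for i in subset]
        if _has_strictly_positive_solution(vecs, v.values):
            count += 1
    return count


def _has_strictly_positive_solution(
    vecs: Sequence[Sequence[Fraction]], target: Sequence[Fraction]
) -> bool:
    """Exists lambda > 0 (componentwise) with sum lambda_i vec_i = target?

    Formulated as max s over {lambda_i = s + extra_i, extra_i >= 0,
    0 <= s <= 1}; strict positivity holds iff the optimum is positive.
    """
    n = len(target)
    k = len(vecs)
    # Variables: s, extra_1..extra_k.
    rows = []
    for i in range(n):
        srow = sum(vec[i] for vec in vecs)
        rows.append([srow] + [vec[i] for vec in vecs])
    A = RationalMatrix(rows)
    c = [Fraction(1)] + [Fraction(0)] * k
    bounds = [(Fraction(0), Fraction(1))] + [(Fraction(0), None)] * k
    res = linear_opt(A, list(target), c, bounds)
    return res.status == "optimal" and res.value > 0


def verify_decomposition(cone: FluxCone, d: Decomposition) -> dict:
    """Check every structural property of a decomposition; raise on failure.

    Verified: exact reconstruction; positive coefficients; term count at
    most deg(target); every term inside the minimal face of the target;
    every term degree at most t+1. When the target is itself an EFM of
    degree >= t+2, additionally at least two terms, each of degree strictly
    below deg(target).
    """
    from .efm import is_efm

    k = cone_degree(cone, d.target)
    t = cone.dim_lineality
    if d.reconstruct() != d.target.values:
        raise VerificationError("terms do not reconstruct the target exactly")
    if any(c <= 0 for c, _ in d.terms):
        raise VerificationError("a coefficient is not strictly positive")
    if len(d.terms) > k:
        raise VerificationError(
            f"{len(d.terms)} terms exceed the target degree {k}"
        )
    zs = d.face.canonical_zero_set
    for c, e in d.terms:
        if any(e.vector[j] != 0 for j in zs):
            raise VerificationError(
                "a term lies outside the minimal face of the target"
            )
        if e.degree > t + 1:
            raise VerificationError("a term has degree above dim(L)+1")
    report = {
        "target_degree": k,
        "n_terms": len(d.terms),
        "max_term_degree": max((e.degree for _, e in d.terms), default=t),
        "efm_split_clause_active": False,
    }
    target_is_efm = is_efm(cone, d.target)
    if target_is_efm and k >= t + 2:
        report["efm_split_clause_active"] = True
        if len(d.terms) < 2:
            raise VerificationError(
                "an EFM of degree >= t+2 must split into at least two terms"
            )
        if any(e.degree >= k for _, e in d.terms):
            raise VerificationError(
                "every term must have degree strictly below the target degree"
            )
    return report
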