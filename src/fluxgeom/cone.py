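"""Steady-state flux cone: construction, canonicalization and core geometry.

The flux cone of a network is C = {v | Sv = 0, v_j >= 0 for irreversible j}.
This module computes its implicit equalities (blocked reactions), redundant
irreversibility constraints, lineality space, dimension, facets, the degree
of a flux vector (the dimension of the smallest face containing it), minimal
faces, relative-interior tests, the decomposition C = L + P into lineality
space plus a pointed cone, and exact flux balance analysis.

Every quantity here is an integer or an exact rational vector; all linear
programs are solved by the exact rational simplex in :mod:`.ratlinalg`, so
no verdict depends on a floating-point tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

from .exceptions import DomainError, StateError, VerificationError
from .netmodel import FluxVector, MetabolicNetwork
from .ratlinalg import (
    LPResult,
    RationalMatrix,
    linear_opt,
    nullspace_basis,
    primitive,
    rank,
    solve_nonneg,
)

__all__ = [
    "FluxCone",
    "Face",
    "PointedDecomposition",
    "build_cone",
    "blocked_reactions",
    "redundant_irr_constraints",
    "canonicalize",
    "facets",
    "degree",
    "minimal_face",
    "in_relative_interior",
    "pointed_decomposition",
    "fba",
]


def _unit_rows(n: int, idx: Iterable[int]) -> RationalMatrix:
    rows = []
    for j in sorted(idx):
        row = [Fraction(0)] * n
        row[j] = Fraction(1)
        rows.append(row)
    if not rows:
        return RationalMatrix.zeros(0, n)
    return RationalMatrix(rows)


@dataclass(frozen=True)
class FluxCone:
    """A flux cone together with its cached canonical data.

    ``network`` carries the *current* Rev/Irr description (canonicalization
    shifts redundant irreversible reactions to Rev). ``blocked_irr`` are the
    irreversibility constraints that are implicit equalities; the columns are
    retained so vector indices always align with the input network.
    """

    network: MetabolicNetwork
    blocked_irr: frozenset[int]
    blocked_rev: frozenset[int]
    lineality_basis: tuple[tuple[Fraction, ...], ...]
    dim_lineality: int
    dim_cone: int
    canonical: bool = False
    shift_history: tuple[int, ...] = ()

    @property
    def n(self) -> int:
        return self.network.n

    @property
    def free_irr(self) -> frozenset[int]:
        """Irreversible reactions that are not implicit equalities."""
        return self.network.irr - self.blocked_irr

    # -- exact membership -------------------------------------------------

    def contains(self, v: FluxVector) -> bool:
        S = self.network.S
        if any(x != 0 for x in S.matvec(v.values)):
            return False
        return all(v[j] >= 0 for j in self.network.irr)

    def check_membership(self, v: FluxVector) -> None:
        S = self.network.S
        sv = S.matvec(v.values)
        for i, x in enumerate(sv):
            if x != 0:
                raise DomainError(
                    f"vector violates steady state at metabolite row {i}"
                )
        for j in sorted(self.network.irr):
            if v[j] < 0:
                raise DomainError(
                    f"vector violates irreversibility of reaction index {j}"
                )

    def flux(self, values: Sequence) -> FluxVector:
        return self.network.flux(values)


@dataclass(frozen=True)
class Face:
    """A face of a flux cone, keyed by its canonical zero-set.

    The face is {v in C | v_j = 0 for j in zero_set} with zero_set a subset
    of the unblocked irreversible reactions; ``canonical_zero_set`` is the
    maximal zero-set defining the same point set. Two faces are equal iff
    their canonical zero-sets are equal.
    """

    cone: FluxCone = field(compare=False, repr=False)
    canonical_zero_set: frozenset[int]
    dim: int = field(compare=False)
    relint_witness: Optional[FluxVector] = field(compare=False, default=None)

    @property
    def zero_set(self) -> frozenset[int]:
        return self.canonical_zero_set

    @property
    def relint_behavior(self) -> frozenset[int]:
        """Common irreversible support of all relative-interior points."""
        return self.cone.free_irr - self.canonical_zero_set

    def contains(self, v: FluxVector) -> bool:
        return self.cone.contains(v) and all(
            v[j] == 0 for j in self.canonical_zero_set
        )


@dataclass(frozen=True)
class PointedDecomposition:
    """C = L + P with P pointed, one generator per minimal proper face."""

    lineality_basis: tuple[tuple[Fraction, ...], ...]
    generators: tuple[FluxVector, ...]
    complement_tag: str


# ---------------------------------------------------------------------------
# Feasibility helpers (exact LP certificates)


def _feasible_with(
    net: MetabolicNetwork,
    irr: Iterable[int],
    fixed: Mapping[int, Fraction],
) -> Optional[tuple[Fraction, ...]]:
    """Exact witness for {v | Sv=0, v_i >= 0 (i in irr), v_j = c_j (fixed)}."""
    n = net.n
    rows = list(net.S.rows)
    rhs = [Fraction(0)] * net.m
    for j, c in fixed.items():
        row = [Fraction(0)] * n
        row[j] = Fraction(1)
        rows.append(tuple(row))
        rhs.append(Fraction(c))
    M = RationalMatrix(rows)
    return solve_nonneg(M, rhs, irr)


# ---------------------------------------------------------------------------
# Construction


def blocked_sets(
    net: MetabolicNetwork,
) -> tuple[frozenset[int], frozenset[int]]:
    """Blocked irreversible and blocked reversible reactions of a network.

    An irreversible j is blocked iff no v in C attains v_j = 1 (homogeneity
    makes normalization to 1 lossless); a reversible j is blocked iff neither
    v_j = 1 nor v_j = -1 is attainable. Verdicts are exact certificates.
    """
    blocked_i = set()
    blocked_r = set()
    for j in range(net.n):
        fwd = _feasible_with(net, net.irr, {j: Fraction(1)}) is not None
        if j in net.irr:
            if not fwd:
                blocked_i.add(j)
        else:
            if not fwd and _feasible_with(net, net.irr, {j: Fraction(-1)}) is None:
                blocked_r.add(j)
    return frozenset(blocked_i), frozenset(blocked_r)


def build_cone(net: MetabolicNetwork) -> FluxCone:
    """Construct the flux cone with blocked sets, lineality basis and dims."""
    n = net.n
    lin_rows = RationalMatrix.vstack(net.S, _unit_rows(n, net.irr))
    lin_basis = tuple(nullspace_basis(lin_rows))
    dim_lin = len(lin_basis)
    b_irr, b_rev = blocked_sets(net)
    eq_rows = RationalMatrix.vstack(net.S, _unit_rows(n, b_irr))
    dim_cone = n - rank(eq_rows)
    return FluxCone(
        network=net,
        blocked_irr=b_irr,
        blocked_rev=b_rev,
        lineality_basis=lin_basis,
        dim_lineality=dim_lin,
        dim_cone=dim_cone,
        canonical=False,
    )


def blocked_reactions(cone: FluxCone) -> tuple[frozenset[int], frozenset[int]]:
    """(blocked irreversible, blocked reversible) index sets of the cone."""
    return cone.blocked_irr, cone.blocked_rev


def redundant_irr_constraints(cone: FluxCone) -> frozenset[int]:
    """Irreversibility constraints implied by the remaining constraints.

    j is redundant iff dropping v_j >= 0 does not change the cone, i.e. no
    vector with Sv = 0, v_i >= 0 for i in Irr\\{j} attains v_j = -1. Blocked
    constraints are implicit equalities and reported separately, not here.
    Semantics are one-at-a-time against the current constraint set.
    """
    net = cone.network
    out = set()
    for j in sorted(cone.free_irr):
        others = net.irr - {j}
        if _feasible_with(net, others, {j: Fraction(-1)}) is None:
            out.add(j)
    return frozenset(out)


def canonicalize(
    cone: FluxCone, order: Optional[Sequence[int]] = None
) -> FluxCone:
    """Irredundant description: shift redundant irreversible reactions to Rev.

    Redundant constraints are removed one at a time, re-testing redundancy
    after each shift, in lexicographic order of the reaction index unless an
    explicit ``order`` is given. Blocked irreversible constraints stay in the
    description as implicit equalities. The point set of the cone is never
    changed; the shift history is recorded on the result.
    """
    net = cone.network
    history: list[int] = []
    current = cone
    while True:
        red = sorted(redundant_irr_constraints(current))
        if order is not None:
            red = [j for j in order if j in red]
        if not red:
            break
        j = red[0]
        net = net.with_irr(net.irr - {j})
        history.append(j)
        current = replace(current, network=net)
    return FluxCone(
        network=net,
        blocked_irr=cone.blocked_irr,
        blocked_rev=cone.blocked_rev,
        lineality_basis=cone.lineality_basis,
        dim_lineality=cone.dim_lineality,
        dim_cone=cone.dim_cone,
        canonical=True,
        shift_history=tuple(cone.shift_history) + tuple(history),
    )


# ---------------------------------------------------------------------------
# Faces and degree


def _face_dim(cone: FluxCone, zero_set: Iterable[int]) -> int:
    n = cone.n
    rows = RationalMatrix.vstack(
        cone.network.S,
        _unit_rows(n, set(cone.blocked_irr) | set(zero_set)),
    )
    return n - rank(rows)


def _relint_witness_lp(cone: FluxCone, zero_set: frozenset[int]) -> FluxVector:
    """Relative-interior witness of {v in C | v_Z = 0} by exact LPs.

    For each free irreversible j outside Z, a witness with v_j = 1 is sought;
    the sum of all witnesses found is positive exactly on the attainable
    coordinates, hence lies in the relative interior of the face.
    """
    net = cone.network
    total = [Fraction(0)] * net.n
    fixed0 = {j: Fraction(0) for j in zero_set}
    for j in sorted(cone.free_irr - zero_set):
        w = _feasible_with(net, net.irr, {**fixed0, j: Fraction(1)})
        if w is not None:
            total = [a + b for a, b in zip(total, w)]
    return net.flux(total)


def face_from_zero_set(
    cone: FluxCone, zero_set: Iterable[int], witness: Optional[FluxVector] = None
) -> Face:
    """Canonical face {v in C | v_Z = 0} for Z among the unblocked Irr."""
    zs = frozenset(zero_set)
    if not zs <= cone.free_irr:
        raise DomainError("zero set must consist of unblocked irreversible indices")
    if witness is None:
        witness = _relint_witness_lp(cone, zs)
    canonical_zs = cone.free_irr - witness.irr_support
    return Face(
        cone=cone,
        canonical_zero_set=canonical_zs,
        dim=_face_dim(cone, canonical_zs),
        relint_witness=witness,
    )


def facets(cone: FluxCone) -> list[Face]:
    """The facets of a canonical cone: one per remaining irreversible reaction."""
    if not cone.canonical:
        raise StateError("facets requires a canonical cone; call canonicalize first")
    out = []
    for j in sorted(cone.free_irr):
        f = face_from_zero_set(cone, {j})
        if f.canonical_zero_set != frozenset({j}):
            raise VerificationError(
                f"facet zero-set {{{j}}} canonicalized to {set(f.canonical_zero_set)} "
                "on a supposedly canonical cone"
            )
        out.append(f)
    return out


def degree(cone: FluxCone, v: FluxVector) -> int:
    """Dimension of the inclusionwise minimal face of the cone containing v.

    Computed as n minus the exact rank of S stacked with unit rows for the
    irreversible reactions at zero in v. The cone here must be the original
    flux cone, not a reconfigured (reversible-split) cone, for the value to
    be meaningful.
    """
    cone.check_membership(v)
    zero_irr = {j for j in cone.network.irr if v[j] == 0}
    rows = RationalMatrix.vstack(cone.network.S, _unit_rows(cone.n, zero_irr))
    return cone.n - rank(rows)


def minimal_face(cone: FluxCone, v: FluxVector) -> Face:
    """The smallest face containing v; v is a relative-interior witness."""
    cone.check_membership(v)
    zs = cone.free_irr - v.irr_support
    return Face(
        cone=cone,
        canonical_zero_set=zs,
        dim=degree(cone, v),
        relint_witness=v,
    )


def in_relative_interior(cone: FluxCone, v: FluxVector) -> bool:
    """True iff v_j > 0 for every unblocked irreversible j (deg(v) = dim C)."""
    cone.check_membership(v)
    return all(v[j] > 0 for j in cone.free_irr)


# ---------------------------------------------------------------------------
# C = L + P


def _project_off_lineality(
    cone: FluxCone, v: Sequence[Fraction]
) -> tuple[Fraction, ...]:
    """Exact orthogonal projection of v onto the complement of L."""
    B = cone.lineality_basis
    if not B:
        return tuple(Fraction(x) for x in v)
    Bm = RationalMatrix(B)
    G = RationalMatrix([Bm.matvec(row) for row in B])  # Gram matrix B B^T
    rhs = Bm.matvec(v)
    y = solve_nonneg(G, rhs, nonneg=())
    if y is None:  # Gram matrix of a basis is invertible
        raise VerificationError("lineality Gram system unexpectedly singular")
    proj = [Fraction(0)] * len(v)
    for yi, row in zip(y, B):
        proj = [p + yi * x for p, x in zip(proj, row)]
    return tuple(Fraction(x) - p for x, p in zip(v, proj))


def pointed_decomposition(
    cone: FluxCone, mmb_witnesses: Sequence[FluxVector]
) -> PointedDecomposition:
    """C = L + P with generators in the orthogonal complement of L.

    ``mmb_witnesses`` supplies one flux vector per minimal proper face (e.g.
    from the MMB computation). Each is projected off the lineality space and
    rescaled to primitive form, which guarantees L and lin(P) intersect only
    in the origin and hence dim C = dim L + dim P.
    """
    gens = []
    for w in mmb_witnesses:
        g = list(primitive(_project_off_lineality(cone, w.values)))
        if all(x == 0 for x in g):
            raise DomainError("a witness lies in the lineality space")
        # primitive() fixes the sign by the first nonzero entry; restore the
        # orientation dictated by the irreversible support.
        if any(g[j] < 0 for j in cone.network.irr):
            g = [-x for x in g]
        gens.append(cone.network.flux(tuple(g)))
    if gens:
        stacked = RationalMatrix(
            list(cone.lineality_basis) + [g.values for g in gens]
        )
        gen_rank = rank(RationalMatrix([g.values for g in gens]))
        if rank(stacked) != cone.dim_lineality + gen_rank:
            raise VerificationError("generators are not independent of L")
        if cone.dim_lineality + gen_rank != cone.dim_cone:
            raise VerificationError(
                "dim L + dim P does not reach dim C; witness set incomplete?"
            )
    return PointedDecomposition(
        lineality_basis=cone.lineality_basis,
        generators=tuple(gens),
        complement_tag="orthogonal complement of L",
    )


# ---------------------------------------------------------------------------
# Flux balance analysis


def fba(
    net: MetabolicNetwork,
    objective: str,
    bounds: Mapping[str, tuple[Optional[Fraction], Optional[Fraction]]],
) -> FluxVector:
    """Maximize the objective flux over {Sv = 0, bounds}, exactly.

    Irreversible reactions get an effective lower bound of max(0, stated
    lower). The optimal value is unique; the optimal vector in general is
    not. Raises DomainError on infeasibility or unboundedness.
    """
    obj_idx = net.reaction_index(objective)
    var_bounds: list[tuple[Optional[Fraction], Optional[Fraction]]] = []
    for j, rid in enumerate(net.reaction_ids):
        lo, hi = bounds.get(rid, (None, None))
        lo = None if lo is None else Fraction(lo)
        hi = None if hi is None else Fraction(hi)
        if j in net.irr:
            lo = Fraction(0) if lo is None else max(Fraction(0), lo)
        var_bounds.append((lo, hi))
    c = [Fraction(0)] * net.n
    c[obj_idx] = Fraction(1)
    res: LPResult = linear_opt(net.S, [Fraction(0)] * net.m, c, var_bounds)
    if res.status == "infeasible":
        raise DomainError("FBA problem is infeasible under the given bounds")
    if res.status == "unbounded":
        raise DomainError("FBA objective is unbounded; add finite bounds")
    return net.flux(res.x)
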