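"""Elementary flux modes: verification, enumeration, degrees and bounds.

An elementary flux mode (EFM) is a nonzero steady-state flux vector with
inclusionwise minimal support. Verification uses the exact rank test:
v in C is an EFM iff rank(S restricted to supp(v)) = |supp(v)| - 1.

Enumeration splits every reversible reaction into a forward/backward pair,
which turns the flux cone into a pointed cone in a higher-dimensional space
whose extreme rays (found by the double description method, in exact
arithmetic) correspond to the EFMs of the original cone, plus futile
two-cycle artifacts which are discarded. A brute-force enumerator that scans
all support candidates with the rank test serves as an independent oracle
for small networks.

The degree of each EFM is always computed in the original flux cone, never
in the reconfigured split cone (where every extreme ray trivially has
degree 1).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

from .cone import FluxCone, degree as cone_degree
from .exceptions import ResourceError, VerificationError
from .netmodel import FluxVector
from .ratlinalg import RationalMatrix, nullspace_basis, primitive, rank

__all__ = [
    "EFM",
    "is_efm",
    "enumerate_efms",
    "efms_brute_force",
    "degree_distribution",
    "check_degree_bounds",
    "DegreeBoundReport",
]

#: Default guard on n + |Rev| for the double-description enumerator.
DD_SIZE_LIMIT = 60
#: Default guard on n for the brute-force (2^n support scan) oracle.
BRUTE_FORCE_LIMIT = 14


@dataclass(frozen=True)
class EFM:
    """An elementary flux mode in primitive integer form.

    ``is_reversible_pair`` marks EFMs whose support contains only reversible
    reactions; for those the negated vector is an EFM too, and only one
    canonical representative (lowest-index nonzero entry positive) is kept.
    Such EFMs lie in the lineality space and have degree dim(L).
    """

    vector: FluxVector
    degree: int
    is_reversible_pair: bool

    @property
    def support(self) -> frozenset[int]:
        return self.vector.support

    @property
    def irr_support(self) -> frozenset[int]:
        return self.vector.irr_support

    def negated(self) -> "EFM":
        if not self.is_reversible_pair:
            raise ValueError("only reversible-pair EFMs may be negated")
        return EFM(-self.vector, self.degree, True)


def is_efm(cone: FluxCone, v: FluxVector) -> bool:
    """Exact rank test: rank(S_{*,supp(v)}) = |supp(v)| - 1 and v in C."""
    supp = sorted(v.support)
    if not supp:
        raise ValueError("the zero vector is not an elementary flux mode")
    if not cone.contains(v):
        return False
    sub = cone.network.S.submatrix(col_idx=supp)
    return rank(sub) == len(supp) - 1


def _canonical_efm(cone: FluxCone, vec: Sequence[Fraction]) -> EFM:
    """Primitive canonical representative with its degree in the original cone."""
    net = cone.network
    p = list(primitive(vec))
    irr_sup = [j for j in net.irr if p[j] != 0]
    if irr_sup:
        # Membership fixes the orientation; primitive() may have flipped it.
        if any(p[j] < 0 for j in irr_sup):
            p = [-x for x in p]
        pair = False
    else:
        pair = True  # support within Rev: canonical sign, negation implied
    fv = net.flux(p)
    return EFM(fv, cone_degree(cone, fv), pair)


# ---------------------------------------------------------------------------
# Double description on the reconfigured (reversible-split) cone


def _dd_extreme_rays(A: RationalMatrix) -> list[tuple[Fraction, ...]]:
    """Extreme rays of {w >= 0 | Aw = 0} by exact double description.

    Starts from the unit rays of the nonnegative orthant and imposes the
    equalities Aw = 0 one row at a time (ascending index). Adjacency of a
    positive/negative ray pair is decided by the exact rank test on their
    common zero-set together with the equality rows processed so far.
    """
    N = A.ncols
    rays: list[tuple[Fraction, ...]] = [
        tuple(Fraction(int(i == j)) for j in range(N)) for i in range(N)
    ]
    processed: list[tuple[Fraction, ...]] = []
    for row in A.rows:
        if all(x == 0 for x in row):
            continue
        vals = [sum(a * r for a, r in zip(row, ray)) for ray in rays]
        keep = [rays[i] for i in range(len(rays)) if vals[i] == 0]
        pos = [i for i in range(len(rays)) if vals[i] > 0]
        neg = [i for i in range(len(rays)) if vals[i] < 0]

        def adjacent(p: int, q: int) -> bool:
            zero = [
                k for k in range(N) if rays[p][k] == 0 and rays[q][k] == 0
            ]
            unit = [
                tuple(Fraction(int(j == k)) for j in range(N)) for k in zero
            ]
            mat = RationalMatrix(processed + unit) if (processed or unit) else None
            r = 0 if mat is None else rank(mat)
            return N - r == 2

        for p in pos:
            for q in neg:
                if adjacent(p, q):
                    new = tuple(
                        vals[p] * rq - vals[q] * rp
                        for rp, rq in zip(rays[p], rays[q])
                    )
                    keep.append(primitive(new))
        # Deduplicate (primitive form is canonical).
        rays = list(dict.fromkeys(keep))
        processed.append(tuple(row))
    return rays


def enumerate_efms(
    cone: FluxCone, size_limit: Optional[int] = DD_SIZE_LIMIT
) -> list[EFM]:
    """All EFMs of the cone, exactly, via reversible splitting + double description.

    Each reversible reaction j is split into nonnegative forward/backward
    fluxes; extreme rays of the reconfigured pointed cone are mapped back by
    v_j = w_j+ - w_j-. Rays supported on exactly one split pair are futile
    two-cycles and discarded. Reversible-pair EFMs (support within Rev)
    appear once, in canonical orientation, flagged.
    """
    net = cone.network
    rev = sorted(net.rev)
    N = net.n + len(rev)
    if size_limit is not None and N > size_limit:
        raise ResourceError(
            f"reconfigured cone has {N} variables (> limit {size_limit}); "
            "raise size_limit or use efms_brute_force on a smaller network"
        )
    # Columns: original n (forward), then one backward column per reversible.
    cols = [[net.S.rows[i][j] for i in range(net.m)] for j in range(net.n)]
    cols += [[-net.S.rows[i][j] for i in range(net.m)] for j in rev]
    A = RationalMatrix(list(zip(*cols))) if net.m else RationalMatrix.zeros(0, N)
    back_of = {j: net.n + r for r, j in enumerate(rev)}

    seen: dict[tuple, EFM] = {}
    for w in _dd_extreme_rays(A):
        v = list(w[: net.n])
        for j in rev:
            v[j] -= w[back_of[j]]
        if all(x == 0 for x in v):
            # Futile two-cycle: support must be exactly one split pair.
            sup = [k for k, x in enumerate(w) if x != 0]
            if not (
                len(sup) == 2
                and sup[0] in back_of
                and back_of[sup[0]] == sup[1]
            ):
                raise VerificationError(
                    "cancelling ray is not a single futile two-cycle"
                )
            continue
        for j in rev:
            if w[j] != 0 and w[back_of[j]] != 0:
                raise VerificationError(
                    "extreme ray uses both directions of a split reaction"
                )
        e = _canonical_efm(cone, v)
        seen.setdefault(e.vector.values, e)
    return sorted(
        seen.values(), key=lambda e: tuple(-x for x in e.vector.values)
    )


# ---------------------------------------------------------------------------
# Brute-force oracle


def efms_brute_force(
    cone: FluxCone, size_limit: Optional[int] = BRUTE_FORCE_LIMIT
) -> list[EFM]:
    """Independent EFM oracle: scan all support candidates with the rank test.

    For each candidate support R, accept iff rank(S_{*,R}) = |R| - 1, the
    one-dimensional kernel of the restricted matrix has no zero entry (so
    the support is exactly R), and the kernel vector is sign-feasible on the
    irreversible part of R. Exponential in n; guarded by ``size_limit``.
    """
    net = cone.network
    n = net.n
    if size_limit is not None and n > size_limit:
        raise ResourceError(
            f"brute force scans 2^{n} supports (> limit 2^{size_limit})"
        )
    max_size = min(n, rank(net.S) + 1)
    out: list[EFM] = []
    from itertools import combinations

    for size in range(1, max_size + 1):
        for supp in combinations(range(n), size):
            sub = net.S.submatrix(col_idx=supp)
            kern = nullspace_basis(sub)
            if len(kern) != 1 or len(supp) - 1 != rank(sub):
                continue
            k = kern[0]
            if any(x == 0 for x in k):
                continue  # actual support is a strict subset of the candidate
            vec = [Fraction(0)] * n
            for idx, j in enumerate(supp):
                vec[j] = k[idx]
            irr_here = [j for j in supp if j in net.irr]
            if irr_here:
                signs = {vec[j] > 0 for j in irr_here}
                if len(signs) > 1:
                    continue  # neither orientation satisfies irreversibility
                if not signs.pop():
                    vec = [-x for x in vec]
            out.append(_canonical_efm(cone, vec))
    return sorted(out, key=lambda e: tuple(-x for x in e.vector.values))


# ---------------------------------------------------------------------------
# Degree statistics and the degree bounds


def degree_distribution(cone: FluxCone, efms: Sequence[EFM]) -> dict[int, int]:
    """Histogram degree -> number of EFMs."""
    return dict(sorted(Counter(e.degree for e in efms).items()))


@dataclass(frozen=True)
class DegreeBoundReport:
    """Summary statistics and verified degree bounds over an EFM set.

    Layout mirrors the standard characteristics table: q is the maximum
    number of active irreversible reactions over the EFMs, r the rank of the
    irreversible column block plus one (an upper bound on q), t the lineality
    dimension. ``sharp_cases`` lists bound names attained with equality.
    """

    n_efms: int
    t: int
    dim_cone: int
    rank_s_irr: int
    q_max_irr_supp: int
    r_bound_irr_supp: int
    max_degree: int
    bound_deg_t_plus_q: int
    bound_deg_t_plus_r: int
    facet_distance_bound: Optional[int]
    l_simple_bound: Optional[Fraction]
    sharp_cases: tuple[str, ...]


def check_degree_bounds(
    cone: FluxCone, efms: Sequence[EFM], l: Optional[int] = None
) -> DegreeBoundReport:
    """Verify every applicable degree bound for every EFM; raise on violation.

    Checked per EFM: the rank test itself; |irr.supp(e)| <= rank(S_Irr) + 1;
    deg(e) <= t + |irr.supp(e)|; deg(e) <= t + rank(S_Irr) + 1. On canonical
    cones additionally deg(e) <= dim(C) - q whenever |Irr| > rank(S_Irr) + q
    for q in {1,2,3}, and the l-simple bound when ``l`` is given. A violation
    raises VerificationError (it would falsify the implementation).
    """
    net = cone.network
    irr = sorted(net.irr)
    s_irr_rank = (
        rank(net.S.submatrix(col_idx=irr)) if irr else 0
    )
    t = cone.dim_lineality
    r = s_irr_rank + 1
    q_max = 0
    deg_max = t
    sharp: set[str] = set()
    facet_q = None
    if cone.canonical:
        for q in (3, 2, 1):
            if len(cone.free_irr) > s_irr_rank + q:
                facet_q = q
                break
    l_bound = None
    if l is not None and cone.canonical:
        l_bound = Fraction(cone.dim_cone) - Fraction(
            len(cone.free_irr) - r, l
        )
    for e in efms:
        if not is_efm(cone, e.vector):
            raise VerificationError("a listed vector fails the EFM rank test")
        isupp = len(e.irr_support)
        q_max = max(q_max, isupp)
        deg_max = max(deg_max, e.degree)
        if isupp > r:
            raise VerificationError("irr-support bound rank(S_Irr)+1 violated")
        if e.degree > t + isupp:
            raise VerificationError("degree bound dim(L)+|irr.supp| violated")
        if e.degree > t + r:
            raise VerificationError("degree bound dim(L)+rank(S_Irr)+1 violated")
        if isupp == r:
            sharp.add("irr_supp_eq_rank_plus_1")
        if e.degree == t + r:
            sharp.add("deg_eq_t_plus_r")
        if facet_q is not None and e.degree > cone.dim_cone - facet_q:
            raise VerificationError(
                f"degree bound dim(C)-{facet_q} violated on a canonical cone"
            )
        if l_bound is not None and e.degree > l_bound:
            raise VerificationError("l-simple degree bound violated")
    return DegreeBoundReport(
        n_efms=len(efms),
        t=t,
        dim_cone=cone.dim_cone,
        rank_s_irr=s_irr_rank,
        q_max_irr_supp=q_max,
        r_bound_irr_supp=r,
        max_degree=deg_max,
        bound_deg_t_plus_q=t + q_max,
        bound_deg_t_plus_r=t + r,
        facet_distance_bound=(
            cone.dim_cone - facet_q if facet_q is not None else None
        ),
        l_simple_bound=l_bound,
        sharp_cases=tuple(sorted(sharp)),
    )
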