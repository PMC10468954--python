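"""Exact rational linear algebra kernel.

Every geometric decision made by this package (ranks, face dimensions,
support sets, EFM rank tests, LP feasibility certificates) is an integer or
a yes/no answer that a floating-point tolerance could silently corrupt.
This module therefore works entirely over :class:`fractions.Fraction`; there
are no epsilon comparisons anywhere.

The workhorses are reduced row echelon form (:func:`rref`), the derived
:func:`rank` / :func:`nullspace_basis`, and an exact simplex method with
Bland's anti-cycling rule (:func:`solve_nonneg`, :func:`linear_opt`) used
for feasibility certificates and flux balance analysis.
"""

from __future__ import annotations

from fractions import Fraction
from math import gcd
from typing import Iterable, Optional, Sequence

Rat = Fraction

__all__ = [
    "RationalMatrix",
    "rref",
    "rank",
    "nullspace_basis",
    "primitive",
    "solve_nonneg",
    "linear_opt",
    "LPResult",
]


def _to_frac_row(row: Iterable) -> tuple[Fraction, ...]:
    return tuple(Fraction(x) for x in row)


class RationalMatrix:
    """Dense matrix of exact rationals.

    Rows are stored as tuples of :class:`~fractions.Fraction`; instances are
    immutable and hashable by content.
    """

    __slots__ = ("rows", "shape")

    def __init__(self, rows: Iterable[Iterable]):
        self.rows: tuple[tuple[Fraction, ...], ...] = tuple(
            _to_frac_row(r) for r in rows
        )
        ncols = len(self.rows[0]) if self.rows else 0
        for r in self.rows:
            if len(r) != ncols:
                raise ValueError("ragged rows in RationalMatrix")
        self.shape = (len(self.rows), ncols)

    @property
    def nrows(self) -> int:
        return self.shape[0]

    @property
    def ncols(self) -> int:
        return self.shape[1]

    def __eq__(self, other) -> bool:
        return isinstance(other, RationalMatrix) and self.rows == other.rows

    def __hash__(self) -> int:
        return hash(self.rows)

    def __repr__(self) -> str:
        return f"RationalMatrix({[list(map(str, r)) for r in self.rows]})"

    @classmethod
    def identity(cls, k: int) -> "RationalMatrix":
        return cls(
            [[Fraction(int(i == j)) for j in range(k)] for i in range(k)]
        )

    @classmethod
    def zeros(cls, m: int, n: int) -> "RationalMatrix":
        zero = Fraction(0)
        out = cls.__new__(cls)
        out.rows = tuple(tuple([zero] * n) for _ in range(m))
        out.shape = (m, n)  # explicit so that a 0 x n matrix keeps its width
        return out

    @classmethod
    def vstack(cls, *blocks: "RationalMatrix") -> "RationalMatrix":
        rows: list[tuple[Fraction, ...]] = []
        ncols = None
        for b in blocks:
            if b.nrows == 0:
                continue
            if ncols is None:
                ncols = b.ncols
            elif b.ncols != ncols:
                raise ValueError("column mismatch in vstack")
            rows.extend(b.rows)
        if ncols is None:
            ncols = blocks[0].ncols if blocks else 0
        out = cls.__new__(cls)
        out.rows = tuple(rows)
        out.shape = (len(rows), ncols)
        return out

    def transpose(self) -> "RationalMatrix":
        return RationalMatrix(zip(*self.rows)) if self.nrows else RationalMatrix([])

    def submatrix(
        self,
        row_idx: Optional[Sequence[int]] = None,
        col_idx: Optional[Sequence[int]] = None,
    ) -> "RationalMatrix":
        ri = range(self.nrows) if row_idx is None else row_idx
        ci = range(self.ncols) if col_idx is None else col_idx
        return RationalMatrix([[self.rows[i][j] for j in ci] for i in ri])

    def matvec(self, v: Sequence) -> tuple[Fraction, ...]:
        if len(v) != self.ncols:
            raise ValueError("dimension mismatch in matvec")
        vf = [Fraction(x) for x in v]
        return tuple(sum(a * b for a, b in zip(row, vf)) for row in self.rows)


def rref(M: RationalMatrix) -> tuple[RationalMatrix, tuple[int, ...]]:
    """Reduced row echelon form with strictly increasing pivot columns."""
    rows = [list(r) for r in M.rows]
    m, n = M.shape
    pivots: list[int] = []
    r = 0
    for c in range(n):
        pivot_row = next((i for i in range(r, m) if rows[i][c] != 0), None)
        if pivot_row is None:
            continue
        rows[r], rows[pivot_row] = rows[pivot_row], rows[r]
        pv = rows[r][c]
        rows[r] = [x / pv for x in rows[r]]
        for i in range(m):
            if i != r and rows[i][c] != 0:
                f = rows[i][c]
                rows[i] = [a - f * b for a, b in zip(rows[i], rows[r])]
        pivots.append(c)
        r += 1
        if r == m:
            break
    return RationalMatrix(rows), tuple(pivots)


def rank(M: RationalMatrix) -> int:
    return len(rref(M)[1])


def primitive(v: Sequence) -> tuple[Fraction, ...]:
    """Canonical primitive integer form of a rational vector.

    Denominators are cleared by their lcm, the gcd of absolute values is
    divided out, and the sign is fixed so the lowest-index nonzero entry is
    positive. The zero vector is returned unchanged.
    """
    vf = [Fraction(x) for x in v]
    nz = [x for x in vf if x != 0]
    if not nz:
        return tuple(vf)
    lcm = 1
    for x in nz:
        lcm = lcm * x.denominator // gcd(lcm, x.denominator)
    ints = [x * lcm for x in vf]
    g = 0
    for x in ints:
        g = gcd(g, abs(x.numerator))
    sign = 1 if next(x for x in ints if x != 0) > 0 else -1
    return tuple(Fraction(sign) * x / g for x in ints)


def nullspace_basis(M: RationalMatrix) -> list[tuple[Fraction, ...]]:
    """Primitive basis of the exact kernel {x | Mx = 0}."""
    R, pivots = rref(M)
    n = M.ncols
    free = [j for j in range(n) if j not in pivots]
    basis = []
    for f in free:
        vec = [Fraction(0)] * n
        vec[f] = Fraction(1)
        for i, p in enumerate(pivots):
            vec[p] = -R.rows[i][f]
        basis.append(primitive(vec))
    return basis


class LPResult:
    """Outcome of an exact LP: status in {'optimal', 'infeasible', 'unbounded'}."""

    __slots__ = ("status", "x", "value")

    def __init__(self, status: str, x=None, value=None):
        self.status = status
        self.x = x
        self.value = value

    def __repr__(self) -> str:
        return f"LPResult({self.status!r}, value={self.value})"


def _simplex_standard(
    A: list[list[Fraction]], b: list[Fraction], c: list[Fraction]
) -> LPResult:
    """max c.x  s.t.  Ax = b, x >= 0, by two-phase tableau simplex.

    Bland's smallest-index rule is used throughout, so the method terminates
    on degenerate problems.
    """
    m = len(A)
    n = len(c)
    # Make b nonnegative.
    A = [list(row) for row in A]
    b = list(b)
    for i in range(m):
        if b[i] < 0:
            A[i] = [-x for x in A[i]]
            b[i] = -b[i]
    # Tableau columns: n structural + m artificial, plus rhs.
    ncols = n + m
    T = [A[i] + [Fraction(int(j == i)) for j in range(m)] + [b[i]] for i in range(m)]
    basis = [n + i for i in range(m)]

    def pivot(row: int, col: int) -> None:
        pv = T[row][col]
        T[row] = [x / pv for x in T[row]]
        for i in range(m):
            if i != row and T[i][col] != 0:
                f = T[i][col]
                T[i] = [a - f * bb for a, bb in zip(T[i], T[row])]
        basis[row] = col

    def optimize(obj: list[Fraction], allowed: int) -> Optional[str]:
        # Maximize obj.x over current basis; columns >= allowed are barred.
        while True:
            # Reduced costs: z_j - c_j with current basis.
            red = []
            for j in range(allowed):
                zj = sum(obj[basis[i]] * T[i][j] for i in range(m))
                red.append(obj[j] - zj)
            enter = next((j for j in range(allowed) if red[j] > 0), None)
            if enter is None:
                return None
            # Ratio test, Bland: smallest basis index on ties.
            leave = None
            best = None
            for i in range(m):
                if T[i][enter] > 0:
                    ratio = T[i][ncols] / T[i][enter]
                    if (
                        best is None
                        or ratio < best
                        or (ratio == best and basis[i] < basis[leave])
                    ):
                        best = ratio
                        leave = i
            if leave is None:
                return "unbounded"
            pivot(leave, enter)

    # Phase 1: maximize -sum(artificials).
    obj1 = [Fraction(0)] * n + [Fraction(-1)] * m
    optimize(obj1, ncols)
    if any(obj1[basis[i]] * T[i][ncols] != 0 for i in range(m)):
        return LPResult("infeasible")
    # Drive remaining artificials out of the basis (they sit at level 0).
    for i in range(m):
        if basis[i] >= n:
            enter = next((j for j in range(n) if T[i][j] != 0), None)
            if enter is not None:
                pivot(i, enter)
    # Rows still basic in an artificial are redundant constraints; bar the
    # artificial columns from phase 2 instead of deleting rows.
    status = optimize(list(c) + [Fraction(0)] * m, n)
    if status == "unbounded":
        return LPResult("unbounded")
    x = [Fraction(0)] * n
    for i in range(m):
        if basis[i] < n:
            x[basis[i]] = T[i][ncols]
    value = sum(ci * xi for ci, xi in zip(c, x))
    return LPResult("optimal", tuple(x), value)


def solve_nonneg(
    M: RationalMatrix,
    b: Sequence,
    nonneg: Iterable[int],
) -> Optional[tuple[Fraction, ...]]:
    """Exact solution of Mx = b with x_i >= 0 for i in ``nonneg``.

    Variables outside ``nonneg`` are free (internally split into positive and
    negative parts). Returns an exact solution vector, or None if the system
    is infeasible.
    """
    bf = [Fraction(x) for x in b]
    if len(bf) != M.nrows:
        raise ValueError("right-hand side length does not match matrix rows")
    nonneg = set(nonneg)
    n = M.ncols
    cols: list[tuple[int, int]] = []  # (original index, sign)
    for j in range(n):
        cols.append((j, 1))
        if j not in nonneg:
            cols.append((j, -1))
    A = [
        [sign * M.rows[i][j] for (j, sign) in cols]
        for i in range(M.nrows)
    ]
    res = _simplex_standard(A, bf, [Fraction(0)] * len(cols))
    if res.status != "optimal":
        return None
    x = [Fraction(0)] * n
    for (j, sign), val in zip(cols, res.x):
        x[j] += sign * val
    return tuple(x)


def linear_opt(
    A_eq: RationalMatrix,
    b_eq: Sequence,
    c: Sequence,
    bounds: Sequence[tuple[Optional[Fraction], Optional[Fraction]]],
) -> LPResult:
    """Exact LP: maximize c.x subject to A_eq x = b_eq and per-variable bounds.

    ``bounds[j]`` is (lower, upper); None means unbounded on that side.
    Variables are shifted/split into standard form and solved by the exact
    two-phase simplex.
    """
    n = A_eq.ncols
    if len(bounds) != n or len(c) != n:
        raise ValueError("bounds/objective length must match number of variables")
    bf = [Fraction(x) for x in b_eq]
    cf = [Fraction(x) for x in c]

    # Standard-form columns; recover[j] = list of (std col, sign, offset share).
    std_cols: list[list[Fraction]] = []  # one column per std variable (over eq rows)
    std_c: list[Fraction] = []
    rhs = list(bf)
    extra_rows: list[tuple[list[Fraction], Fraction]] = []  # bound-gap rows
    mapping: list[list[tuple[int, int]]] = []  # per original var: (std idx, sign)
    offsets = [Fraction(0)] * n

    def col_of(j: int) -> list[Fraction]:
        return [A_eq.rows[i][j] for i in range(A_eq.nrows)]

    for j in range(n):
        lo, hi = bounds[j]
        lo = None if lo is None else Fraction(lo)
        hi = None if hi is None else Fraction(hi)
        if lo is not None and hi is not None and lo > hi:
            return LPResult("infeasible")
        if lo is not None:
            # x = lo + y, y >= 0 (and y <= hi - lo if hi finite).
            offsets[j] = lo
            idx = len(std_cols)
            std_cols.append(col_of(j))
            std_c.append(cf[j])
            mapping.append([(idx, 1)])
            for i in range(A_eq.nrows):
                rhs[i] -= A_eq.rows[i][j] * lo
            if hi is not None:
                gap = [Fraction(0)] * len(std_cols)
                gap[idx] = Fraction(1)
                extra_rows.append((gap, hi - lo))
        elif hi is not None:
            # x = hi - y, y >= 0.
            offsets[j] = hi
            idx = len(std_cols)
            std_cols.append([-a for a in col_of(j)])
            std_c.append(-cf[j])
            mapping.append([(idx, -1)])
            for i in range(A_eq.nrows):
                rhs[i] -= A_eq.rows[i][j] * hi
        else:
            # Free: x = y+ - y-.
            ip = len(std_cols)
            std_cols.append(col_of(j))
            std_c.append(cf[j])
            im = len(std_cols)
            std_cols.append([-a for a in col_of(j)])
            std_c.append(-cf[j])
            mapping.append([(ip, 1), (im, -1)])

    nstd = len(std_cols)
    rows = [[std_cols[j][i] for j in range(nstd)] for i in range(A_eq.nrows)]
    b_all = list(rhs)
    for gap, g_rhs in extra_rows:
        # Upper-bound gap rows need a slack variable: y + s = gap.
        row = gap + [Fraction(0)] * (nstd - len(gap))
        slack_col_index = len(std_c)
        for r in rows:
            r.append(Fraction(0))
        row.append(Fraction(1))
        std_c.append(Fraction(0))
        rows.append(row)
        b_all.append(g_rhs)
        nstd = slack_col_index + 1

    res = _simplex_standard(rows, b_all, std_c)
    if res.status != "optimal":
        return res
    x = list(offsets)
    for j in range(n):
        for idx, sign in mapping[j]:
            x[j] += sign * res.x[idx]
    value = sum(ci * xi for ci, xi in zip(cf, x))
    return LPResult("optimal", tuple(x), value)
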