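"""Metabolic network data model, file I/O, embedded fixtures and a random
network generator.

A metabolic network is a stoichiometric matrix S (metabolites x reactions)
together with a partition of the reactions into reversible and irreversible
ones. All stoichiometric coefficients are stored as exact rationals; file
formats round-trip losslessly (integers as JSON numbers, non-integers as
"p/q" or decimal strings).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .exceptions import CapabilityError, NetworkParseError
from .ratlinalg import RationalMatrix

__all__ = [
    "MetabolicNetwork",
    "FluxVector",
    "load_network",
    "write_network",
    "fixture_fig1",
    "fixture_ex54",
    "random_network",
]


def _parse_rational(x, where: str) -> Fraction:
    if isinstance(x, bool):
        raise NetworkParseError(f"boolean is not a stoichiometric value at {where}")
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        if x.is_integer():
            return Fraction(int(x))
        raise NetworkParseError(
            f"non-integer JSON number at {where}; encode it as a string "
            '("p/q" or decimal) for an exact round-trip'
        )
    if isinstance(x, str):
        try:
            return Fraction(x)
        except (ValueError, ZeroDivisionError) as exc:
            raise NetworkParseError(f"non-rational entry {x!r} at {where}") from exc
    raise NetworkParseError(f"unsupported value type {type(x).__name__} at {where}")


def _format_rational(x: Fraction):
    if x.denominator == 1:
        return int(x)
    return str(x)


@dataclass(frozen=True)
class MetabolicNetwork:
    """A metabolic network: metabolites, reactions, S, and the Rev/Irr split.

    ``irr`` holds 0-based column indices of irreversible reactions;
    user-facing output uses the reaction-id strings instead.
    """

    metabolite_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    S: RationalMatrix
    irr: frozenset[int]

    def __post_init__(self):
        m, n = self.S.shape
        if len(self.metabolite_ids) != m:
            raise NetworkParseError("metabolite count does not match S rows")
        if len(self.reaction_ids) != n:
            raise NetworkParseError("reaction count does not match S columns")
        if len(set(self.reaction_ids)) != n:
            raise NetworkParseError("duplicate reaction ids")
        bad = [j for j in self.irr if not 0 <= j < n]
        if bad:
            raise NetworkParseError(f"irreversible index out of range: {bad}")

    @property
    def m(self) -> int:
        return self.S.nrows

    @property
    def n(self) -> int:
        return self.S.ncols

    @property
    def rev(self) -> frozenset[int]:
        return frozenset(range(self.n)) - self.irr

    @property
    def irr_ids(self) -> tuple[str, ...]:
        return tuple(self.reaction_ids[j] for j in sorted(self.irr))

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    def with_irr(self, irr: Iterable[int]) -> "MetabolicNetwork":
        """Copy of the network with a different Rev/Irr partition."""
        return MetabolicNetwork(
            self.metabolite_ids, self.reaction_ids, self.S, frozenset(irr)
        )

    def flux(self, values: Sequence) -> "FluxVector":
        return FluxVector(tuple(Fraction(x) for x in values), self)


@dataclass(frozen=True)
class FluxVector:
    """An exact rational flux vector attached to its network."""

    values: tuple[Fraction, ...]
    network: MetabolicNetwork = field(compare=False)

    def __post_init__(self):
        if len(self.values) != self.network.n:
            raise ValueError("flux vector length does not match reaction count")

    def __getitem__(self, j: int) -> Fraction:
        return self.values[j]

    def __len__(self) -> int:
        return len(self.values)

    @property
    def support(self) -> frozenset[int]:
        return frozenset(j for j, x in enumerate(self.values) if x != 0)

    @property
    def irr_support(self) -> frozenset[int]:
        return self.support & self.network.irr

    @property
    def rev_support(self) -> frozenset[int]:
        return self.support & self.network.rev

    def scaled(self, factor) -> "FluxVector":
        f = Fraction(factor)
        return FluxVector(tuple(f * x for x in self.values), self.network)

    def __add__(self, other: "FluxVector") -> "FluxVector":
        return FluxVector(
            tuple(a + b for a, b in zip(self.values, other.values)), self.network
        )

    def __neg__(self) -> "FluxVector":
        return FluxVector(tuple(-x for x in self.values), self.network)


# ---------------------------------------------------------------------------
# File I/O


def _network_to_dict(net: MetabolicNetwork) -> dict:
    return {
        "metabolites": list(net.metabolite_ids),
        "reactions": [
            {"id": rid, "reversible": j not in net.irr}
            for j, rid in enumerate(net.reaction_ids)
        ],
        "S": [[_format_rational(x) for x in row] for row in net.S.rows],
    }


def _network_from_dict(doc: dict) -> MetabolicNetwork:
    for key in ("metabolites", "reactions", "S"):
        if key not in doc:
            raise NetworkParseError(f"missing field {key!r} in network JSON")
    mets = [str(x) for x in doc["metabolites"]]
    rids = []
    irr = set()
    for j, r in enumerate(doc["reactions"]):
        if not isinstance(r, dict) or "id" not in r or "reversible" not in r:
            raise NetworkParseError(
                f"reactions[{j}] must be an object with 'id' and 'reversible'"
            )
        if not isinstance(r["reversible"], bool):
            raise NetworkParseError(f"reactions[{j}].reversible must be a boolean")
        rids.append(str(r["id"]))
        if not r["reversible"]:
            irr.add(j)
    S = RationalMatrix(
        [
            [_parse_rational(x, f"S[{i}][{j}]") for j, x in enumerate(row)]
            for i, row in enumerate(doc["S"])
        ]
    )
    return MetabolicNetwork(tuple(mets), tuple(rids), S, frozenset(irr))


def _load_tsv(path: Path) -> MetabolicNetwork:
    matrix_lines = path.read_text().rstrip("\n").split("\n")
    if not matrix_lines:
        raise NetworkParseError("empty TSV matrix file")
    header = matrix_lines[0].split("\t")
    if header and header[0] in ("", "metabolite"):
        header = header[1:]
    rids = [h for h in header]
    mets = []
    rows = []
    for i, line in enumerate(matrix_lines[1:]):
        fields = line.split("\t")
        if len(fields) != len(rids) + 1:
            raise NetworkParseError(
                f"TSV row {i + 1} has {len(fields) - 1} entries, expected {len(rids)}"
            )
        mets.append(fields[0])
        rows.append(
            [_parse_rational(x, f"S[{i}][{j}]") for j, x in enumerate(fields[1:])]
        )
    sidecar = path.with_suffix(".rev.tsv")
    if not sidecar.exists():
        raise NetworkParseError(f"missing reversibility sidecar {sidecar.name}")
    irr = set()
    seen = set()
    for line in sidecar.read_text().rstrip("\n").split("\n"):
        rid, flag = line.split("\t")
        if flag not in ("0", "1"):
            raise NetworkParseError(
                f"reversibility flag for {rid!r} must be 0 or 1, got {flag!r}"
            )
        if rid not in rids:
            raise NetworkParseError(f"sidecar mentions unknown reaction {rid!r}")
        seen.add(rid)
        if flag == "0":
            irr.add(rids.index(rid))
    missing = set(rids) - seen
    if missing:
        raise NetworkParseError(f"sidecar missing reactions: {sorted(missing)}")
    return MetabolicNetwork(
        tuple(mets), tuple(rids), RationalMatrix(rows), frozenset(irr)
    )


def _load_sbml(path: Path) -> MetabolicNetwork:
    try:
        import cobra  # type: ignore
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise CapabilityError(
            "SBML input requires the optional 'cobra' dependency"
        ) from exc
    model = cobra.io.read_sbml_model(str(path))
    mets = [
        m.id
        for m in model.metabolites
        if not getattr(m, "boundary_condition", False)
    ]
    met_index = {mid: i for i, mid in enumerate(mets)}
    rids = [r.id for r in model.reactions]
    rows = [[Fraction(0)] * len(rids) for _ in mets]
    irr = set()
    for j, r in enumerate(model.reactions):
        if not r.reversibility:
            irr.add(j)
        for met, coeff in r.metabolites.items():
            if met.id in met_index:
                rows[met_index[met.id]][j] = _parse_rational(
                    coeff if isinstance(coeff, int) else str(coeff),
                    f"{r.id}:{met.id}",
                )
    return MetabolicNetwork(
        tuple(mets), tuple(rids), RationalMatrix(rows), frozenset(irr)
    )


def load_network(
    path: Union[str, Path], format: Optional[str] = None
) -> MetabolicNetwork:
    """Load a network from JSON, TSV (matrix + .rev.tsv sidecar) or SBML."""
    path = Path(path)
    if format is None:
        format = {".json": "json", ".tsv": "tsv", ".xml": "sbml", ".sbml": "sbml"}.get(
            path.suffix.lower(), "json"
        )
    if format == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise NetworkParseError(f"invalid JSON in {path.name}: {exc}") from exc
        return _network_from_dict(doc)
    if format == "tsv":
        return _load_tsv(path)
    if format == "sbml":
        return _load_sbml(path)
    raise NetworkParseError(f"unknown network format {format!r}")


def write_network(
    net: MetabolicNetwork, path: Union[str, Path], format: Optional[str] = None
) -> None:
    """Write a network as JSON or TSV; round-trips exactly via load_network."""
    path = Path(path)
    if format is None:
        format = "tsv" if path.suffix.lower() == ".tsv" else "json"
    if format == "json":
        path.write_text(json.dumps(_network_to_dict(net), indent=1) + "\n")
        return
    if format == "tsv":
        lines = ["\t".join(("metabolite",) + net.reaction_ids)]
        for mid, row in zip(net.metabolite_ids, net.S.rows):
            lines.append(
                "\t".join([mid] + [str(_format_rational(x)) for x in row])
            )
        path.write_text("\n".join(lines) + "\n")
        sidecar = path.with_suffix(".rev.tsv")
        sidecar.write_text(
            "\n".join(
                f"{rid}\t{0 if j in net.irr else 1}"
                for j, rid in enumerate(net.reaction_ids)
            )
            + "\n"
        )
        return
    raise NetworkParseError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# Embedded fixtures

_FIG1_S = [
    # reactions:  1   2   3   4   5   6   7   8   9  10  11  12  13
    [1, -1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],  # A
    [0, 1, 1, 0, -1, 0, 0, 0, 0, 0, 0, 0, 0],  # B
    [0, 1, 0, -1, 0, -1, 0, 0, 0, 0, 0, 0, 0],  # C
    [0, 0, 0, 0, 1, 0, 0, 1, -1, 0, -1, 0, 0],  # D
    [0, 0, 0, 0, 0, 1, -1, -1, 0, 0, 0, 0, 0],  # E
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, -1, 0],  # F
    [0, 0, 0, 0, 0, 0, 0, 0, 1, -1, 0, 0, -1],  # G
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1],  # H
]

_FIG1_IRR_1BASED = (2, 6, 7, 8, 13)


def fixture_fig1() -> MetabolicNetwork:
    """The 8-metabolite, 13-reaction example network.

    Metabolites A..H; irreversible reactions 2, 6, 7, 8 and 13 (1-based
    reaction labels, matching the reaction-id strings "1".."13").
    """
    return MetabolicNetwork(
        tuple("ABCDEFGH"),
        tuple(str(i) for i in range(1, 14)),
        RationalMatrix(_FIG1_S),
        frozenset(j - 1 for j in _FIG1_IRR_1BASED),
    )


def fixture_ex54() -> MetabolicNetwork:
    """The 2-metabolite, 4-reaction toy network with Rev={1,2}, Irr={3,4}.

    Its flux cone is pointed and 2-dimensional, with three elementary flux
    modes e1=(1,1,0,1), e2=(-1,-1,1,0), e3=(0,0,1,1)=e1+e2.
    """
    return MetabolicNetwork(
        ("A", "B"),
        ("1", "2", "3", "4"),
        RationalMatrix([[1, -1, 0, 0], [0, 1, 1, -1]]),
        frozenset({2, 3}),
    )


def random_network(
    m: int,
    n: int,
    n_irr: int,
    seed: int,
    density: float = 0.4,
    entry_range: int = 2,
) -> MetabolicNetwork:
    """Random integer test network, a pure function of its arguments.

    Entries are drawn uniformly from {-entry_range..entry_range}\\{0} with the
    given density; every row and column is guaranteed at least one nonzero
    entry. ``irr`` is a uniformly random n_irr-subset of the reactions.
    """
    if m < 1 or n < 1:
        raise ValueError("need at least one metabolite and one reaction")
    if not 0 <= n_irr <= n:
        raise ValueError("n_irr must lie between 0 and n")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    if entry_range < 1:
        raise ValueError("entry_range must be >= 1")
    rng = random.Random(seed)

    def draw() -> int:
        v = rng.randint(1, entry_range)
        return v if rng.random() < 0.5 else -v

    rows = [
        [draw() if rng.random() < density else 0 for _ in range(n)]
        for _ in range(m)
    ]
    for i in range(m):
        if all(x == 0 for x in rows[i]):
            rows[i][rng.randrange(n)] = draw()
    for j in range(n):
        if all(rows[i][j] == 0 for i in range(m)):
            rows[rng.randrange(m)][j] = draw()
    irr = frozenset(rng.sample(range(n), n_irr))
    return MetabolicNetwork(
        tuple(f"M{i + 1}" for i in range(m)),
        tuple(f"R{j + 1}" for j in range(n)),
        RationalMatrix(rows),
        irr,
    )
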