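"""Metabolic behaviors, MMBs, face lattices and their structural bounds.

A metabolic behavior is the set of irreversible reactions active in some
steady-state flux vector; a minimal metabolic behavior (MMB) is an
inclusion-minimal one. MMBs are in 1-1 correspondence with the minimal
proper faces (dimension dim(L)+1) of the flux cone, which generalize
extreme rays to non-pointed cones.

The face-lattice enumerator works on canonical cone descriptions, where
every proper face is an intersection of facets and faces can be represented
purely by their canonical zero-sets over the unblocked irreversible
reactions. MMB extraction itself only needs the EFM set and therefore works
on any description - the MMBs of a network genuinely depend on which
description is used (removing a redundant irreversibility constraint can
shrink them), so no silent canonicalization is done anywhere here.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Iterable, Optional, Sequence

from .cone import Face, FluxCone, face_from_zero_set, _face_dim
from .efm import EFM
from .exceptions import ResourceError, StateError, VerificationError
from .netmodel import FluxVector

__all__ = [
    "MMB",
    "FaceLattice",
    "metabolic_behavior",
    "mmbs",
    "face_lattice",
    "relint_behavior",
    "is_union_of_mmbs",
    "l_simplicity",
    "mmb_cardinality_bound",
    "check_prop72",
]

#: Default guard on the number of facets for full lattice enumeration.
FACET_LIMIT = 25


@dataclass(frozen=True)
class MMB:
    """A minimal metabolic behavior with a witness flux vector.

    ``reactions`` is the behavior (a set of irreversible reaction indices);
    the witness is an EFM realizing it, which lies in the corresponding
    minimal proper face and has degree dim(L) + 1.
    """

    reactions: frozenset[int]
    witness: EFM

    def reaction_ids(self, cone: FluxCone) -> tuple[str, ...]:
        return tuple(
            cone.network.reaction_ids[j] for j in sorted(self.reactions)
        )


@dataclass(frozen=True)
class FaceLattice:
    """All faces of a flux cone, partially ordered by inclusion.

    Inclusion of faces is reverse inclusion of canonical zero-sets; ``edges``
    holds cover relations as (lower face index, upper face index) pairs.
    """

    cone: FluxCone
    faces: tuple[Face, ...]
    edges: tuple[tuple[int, int], ...]
    efm_members: tuple[tuple[int, ...], ...]  # per face: indices into the EFM list
    bottom: int
    top: int


def metabolic_behavior(cone: FluxCone, v: FluxVector) -> frozenset[int]:
    """The irreversible support of v; empty iff v lies in the lineality space."""
    cone.check_membership(v)
    return v.irr_support


def mmbs(cone: FluxCone, efms: Sequence[EFM]) -> list[MMB]:
    """Inclusion-minimal behaviors realized by a complete EFM set.

    Each MMB is cross-checked against direct face construction: its zero-set
    must define a face of dimension dim(L) + 1 whose contained EFMs realize
    exactly the behavior.
    """
    behaviors: dict[frozenset[int], EFM] = {}
    for e in efms:
        b = e.irr_support
        if b and b not in behaviors:
            behaviors[b] = e
    minimal = [
        b
        for b in behaviors
        if not any(other < b for other in behaviors)
    ]
    out = []
    for b in sorted(minimal, key=sorted):
        witness = behaviors[b]
        face_zero = cone.free_irr - b
        dim = _face_dim(cone, face_zero)
        if dim != cone.dim_lineality + 1:
            raise VerificationError(
                f"behavior {sorted(b)} does not correspond to a minimal "
                f"proper face (dim {dim} != {cone.dim_lineality + 1})"
            )
        realized = frozenset().union(
            *(
                e.irr_support
                for e in efms
                if not (e.irr_support & face_zero)
            )
        )
        if realized != b:
            raise VerificationError(
                f"face of behavior {sorted(b)} has relint behavior "
                f"{sorted(realized)}"
            )
        if witness.degree != cone.dim_lineality + 1:
            raise VerificationError("MMB witness degree is not dim(L)+1")
        out.append(MMB(reactions=b, witness=witness))
    return out


def _face_members(zero_set: frozenset[int], efms: Sequence[EFM]) -> tuple[int, ...]:
    return tuple(
        i for i, e in enumerate(efms) if not (e.irr_support & zero_set)
    )


def face_lattice(
    cone: FluxCone,
    efms: Sequence[EFM],
    facet_limit: Optional[int] = FACET_LIMIT,
) -> FaceLattice:
    """Full face lattice of a canonical cone, as meet-closure of the facets.

    Faces are generated by intersecting facets (union of zero-sets) and
    canonicalized through the EFMs they contain: the canonical zero-set of a
    face is the unblocked irreversible set minus the union of irreversible
    supports of its EFMs. Each face is annotated with its dimension, relint
    behavior witness (sum of contained EFMs) and EFM membership.
    """
    if not cone.canonical:
        raise StateError(
            "face_lattice requires a canonical cone; call canonicalize first"
        )
    free = cone.free_irr
    if facet_limit is not None and len(free) > facet_limit:
        raise ResourceError(
            f"{len(free)} facets exceed the lattice enumeration limit "
            f"{facet_limit}"
        )

    def canonical(zs: frozenset[int]) -> frozenset[int]:
        members = _face_members(zs, efms)
        realized = frozenset().union(
            frozenset(), *(efms[i].irr_support for i in members)
        )
        return free - realized

    # Meet-closure: start from C (empty zero-set) and the facets, keep
    # intersecting until no new canonical zero-set appears.
    closure: set[frozenset[int]] = {canonical(frozenset())}
    frontier = [canonical(frozenset({j})) for j in sorted(free)]
    closure.update(frontier)
    while frontier:
        new: list[frozenset[int]] = []
        for z in frontier:
            for other in list(closure):
                cand = canonical(z | other)
                if cand not in closure:
                    closure.add(cand)
                    new.append(cand)
        frontier = new

    ordered = sorted(closure, key=lambda z: (len(z), sorted(z)))
    faces = []
    members = []
    for zs in ordered:
        mem = _face_members(zs, efms)
        witness_vals = [0] * cone.n
        for i in mem:
            witness_vals = [
                a + b for a, b in zip(witness_vals, efms[i].vector.values)
            ]
        faces.append(
            Face(
                cone=cone,
                canonical_zero_set=zs,
                dim=_face_dim(cone, zs),
                relint_witness=cone.network.flux(witness_vals),
            )
        )
        members.append(mem)
    faces_sorted = sorted(
        range(len(faces)), key=lambda i: (faces[i].dim, sorted(faces[i].zero_set))
    )
    faces = [faces[i] for i in faces_sorted]
    members = [members[i] for i in faces_sorted]

    # Cover relations: F < G iff zero(F) > zero(G), with nothing in between.
    edges = []
    for i, fi in enumerate(faces):
        for j, fj in enumerate(faces):
            if fi.canonical_zero_set > fj.canonical_zero_set:
                between = any(
                    fi.canonical_zero_set > fk.canonical_zero_set
                    and fk.canonical_zero_set > fj.canonical_zero_set
                    for fk in faces
                )
                if not between:
                    if fi.dim >= fj.dim:
                        raise VerificationError(
                            "face dimensions do not increase along an edge"
                        )
                    edges.append((i, j))
    bottom = max(range(len(faces)), key=lambda i: len(faces[i].zero_set))
    top = min(range(len(faces)), key=lambda i: len(faces[i].zero_set))
    if faces[bottom].dim != cone.dim_lineality or faces[top].dim != cone.dim_cone:
        raise VerificationError("lattice bottom/top dimensions are inconsistent")
    return FaceLattice(
        cone=cone,
        faces=tuple(faces),
        edges=tuple(edges),
        efm_members=tuple(members),
        bottom=bottom,
        top=top,
    )


def relint_behavior(face: Face) -> frozenset[int]:
    """Common irreversible support of the relative interior of a face."""
    b = face.relint_behavior
    w = face.relint_witness
    if w is not None and w.irr_support != b:
        raise VerificationError(
            "relint witness support disagrees with the canonical zero-set"
        )
    return b


def is_union_of_mmbs(
    behavior: Iterable[int], mmb_list: Sequence[MMB]
) -> bool:
    """True iff the behavior is exactly a union of (contained) MMBs."""
    b = frozenset(behavior)
    covered = frozenset().union(
        frozenset(), *(m.reactions for m in mmb_list if m.reactions <= b)
    )
    return covered == b


def l_simplicity(lattice: FaceLattice) -> int:
    """Smallest l >= 1 with every k-face in at most l*(dim C - k) facets."""
    cone = lattice.cone
    facet_sets = [
        f.canonical_zero_set for f in lattice.faces if f.dim == cone.dim_cone - 1
    ]
    l = 1
    for f in lattice.faces:
        gap = cone.dim_cone - f.dim
        if gap == 0:
            continue
        n_facets = sum(1 for z in facet_sets if z <= f.canonical_zero_set)
        l = max(l, ceil(n_facets / gap))
    return l


def mmb_cardinality_bound(cone: FluxCone) -> int:
    """Upper bound |Irr| - (dim C - dim L) + 1 on MMB cardinality.

    Evaluated on the cone's current description; it applies both before and
    after redundancy removal, and is typically much smaller afterwards.
    """
    return len(cone.network.irr) - (cone.dim_cone - cone.dim_lineality) + 1


def check_prop72(
    cone: FluxCone, mmb_list: Sequence[MMB]
) -> tuple[bool, bool]:
    """Facet-count criterion: #facets = dim C - dim L iff all MMBs are singletons.

    Requires a canonical description (where the facets are exactly the
    remaining irreversibility constraints). Returns both sides; raises if
    they disagree, which would indicate an implementation bug.
    """
    if not cone.canonical:
        raise StateError("check_prop72 requires a canonical cone")
    facet_criterion = len(cone.free_irr) == cone.dim_cone - cone.dim_lineality
    all_singleton = all(len(m.reactions) == 1 for m in mmb_list)
    if facet_criterion != all_singleton:
        raise VerificationError(
            "facet-count criterion and MMB singleton condition disagree"
        )
    return facet_criterion, all_singleton
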