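import random
from fractions import Fraction as F

import pytest

import fluxgeom as fg
from fluxgeom.exceptions import DomainError, StateError


class TestBuild:
    def test_ex54_dimensions(self, ex54_cone):
        assert ex54_cone.dim_lineality == 0
        assert ex54_cone.dim_cone == 2
        assert ex54_cone.lineality_basis == ()

    def test_fig1_dimensions(self, fig1_cone):
        assert fig1_cone.dim_cone == 5
        assert fig1_cone.dim_lineality == 2

    def test_lineality_basis_in_cone(self, fig1_cone):
        net = fig1_cone.network
        for b in fig1_cone.lineality_basis:
            assert all(x == 0 for x in net.S.matvec(b))
            assert all(b[j] == 0 for j in net.irr)

    def test_all_reversible_cone_is_linear_space(self):
        net = fg.MetabolicNetwork(
            ("A",), ("1", "2"), fg.RationalMatrix([[1, -1]]), frozenset()
        )
        cone = fg.build_cone(net)
        assert cone.dim_cone == cone.dim_lineality == 1


class TestBlockedAndRedundant:
    def test_fig1_blocked(self, fig1_cone):
        bi, br = fg.blocked_reactions(fig1_cone)
        assert {j + 1 for j in bi} == {13}
        assert br == frozenset()

    def test_ex54_nothing_blocked(self, ex54_cone):
        assert fg.blocked_reactions(ex54_cone) == (frozenset(), frozenset())

    def test_single_irreversible_uptake_blocked(self):
        net = fg.MetabolicNetwork(
            ("A",), ("1",), fg.RationalMatrix([[1]]), frozenset({0})
        )
        cone = fg.build_cone(net)
        assert cone.blocked_irr == {0}

    def test_blocked_reversible_detected(self):
        # A reversible dead-end: v_1 = 0 is forced but sign-free.
        net = fg.MetabolicNetwork(
            ("A",), ("1",), fg.RationalMatrix([[1]]), frozenset()
        )
        cone = fg.build_cone(net)
        assert cone.blocked_rev == {0}

    def test_fig1_redundant_is_reaction_6(self, fig1_cone):
        assert {j + 1 for j in fg.redundant_irr_constraints(fig1_cone)} == {6}

    def test_ex54_no_redundancy(self, ex54_cone):
        assert fg.redundant_irr_constraints(ex54_cone) == frozenset()
        # Witnesses from the derivation: dropping either constraint admits
        # a sign-violating vector.
        net = ex54_cone.network
        relaxed3 = net.flux([2, 2, -1, 1])
        assert all(x == 0 for x in net.S.matvec(relaxed3.values))
        assert relaxed3[2] < 0 <= relaxed3[3]


class TestCanonicalize:
    def test_fig1_shifts_reaction_6(self, fig1_canonical):
        assert [j + 1 for j in fig1_canonical.shift_history] == [6]
        free = {j + 1 for j in fig1_canonical.free_irr}
        assert free == {2, 7, 8}
        assert {j + 1 for j in fig1_canonical.blocked_irr} == {13}

    def test_ex54_is_fixed_point(self, ex54_cone):
        can = fg.canonicalize(ex54_cone)
        assert can.network.irr == ex54_cone.network.irr
        assert can.shift_history == ()
        assert can.canonical

    def test_idempotent(self, fig1_canonical):
        again = fg.canonicalize(fig1_canonical)
        assert again.network.irr == fig1_canonical.network.irr
        assert again.shift_history == fig1_canonical.shift_history

    def test_point_set_unchanged(self, fig1_cone, fig1_canonical, fig1_efms):
        """Membership of random conic combinations is invariant."""
        rng = random.Random(11)
        for _ in range(40):
            coeffs = [F(rng.randint(0, 3)) for _ in fig1_efms]
            v = fig1_cone.network.flux(
                [
                    sum(c * e.vector[j] for c, e in zip(coeffs, fig1_efms))
                    for j in range(fig1_cone.n)
                ]
            )
            assert fig1_cone.contains(v) == fig1_canonical.contains(v)
        # And a vector outside C stays outside.
        bad = fig1_cone.network.flux([0] * 12 + [1])
        assert not fig1_cone.contains(bad) and not fig1_canonical.contains(bad)


class TestFacets:
    def test_requires_canonical(self, fig1_cone):
        with pytest.raises(StateError, match="canonicalize"):
            fg.facets(fig1_cone)

    def test_fig1_three_facets_dim4(self, fig1_canonical):
        fs = fg.facets(fig1_canonical)
        assert sorted({j + 1 for j in f.zero_set}.pop() for f in fs) == [2, 7, 8]
        assert all(f.dim == 4 for f in fs)

    def test_ex54_two_facets_dim1(self, ex54_cone):
        fs = fg.facets(fg.canonicalize(ex54_cone))
        assert len(fs) == 2
        assert all(f.dim == 1 for f in fs)

    def test_no_irreversible_no_facets(self):
        net = fg.MetabolicNetwork(
            ("A",), ("1", "2"), fg.RationalMatrix([[1, -1]]), frozenset()
        )
        assert fg.facets(fg.canonicalize(fg.build_cone(net))) == []


class TestDegree:
    @pytest.mark.parametrize(
        "vec,expected",
        [((0, 0, 1, 1), 2), ((1, 1, 0, 1), 1), ((-1, -1, 1, 0), 1), ((0, 0, 0, 0), 0)],
    )
    def test_ex54_degrees(self, ex54_cone, ex54_net, vec, expected):
        assert fg.degree(ex54_cone, ex54_net.flux(vec)) == expected

    def test_zero_vector_has_lineality_degree(self, fig1_cone):
        zero = fig1_cone.network.flux([0] * 13)
        assert fg.degree(fig1_cone, zero) == fig1_cone.dim_lineality == 2

    def test_out_of_cone_raises_with_index(self, ex54_cone, ex54_net):
        with pytest.raises(DomainError, match="irreversibility"):
            fg.degree(ex54_cone, ex54_net.flux([0, 0, -1, -1]))
        with pytest.raises(DomainError, match="steady state"):
            fg.degree(ex54_cone, ex54_net.flux([1, 0, 0, 0]))

    def test_description_invariant(self, fig1_cone, fig1_canonical, fig1_efms):
        """The degree is geometric: identical before/after canonicalization."""
        for e in fig1_efms:
            assert fg.degree(fig1_cone, e.vector) == fg.degree(
                fig1_canonical, e.vector
            )

    def test_scaling_invariant(self, ex54_cone, ex54_efms):
        for e in ex54_efms:
            assert fg.degree(ex54_cone, e.vector.scaled(7)) == e.degree


class TestMinimalFaceAndRelint:
    def test_e3_minimal_face_is_cone(self, ex54_cone, ex54_net):
        f = fg.minimal_face(ex54_cone, ex54_net.flux([0, 0, 1, 1]))
        assert f.canonical_zero_set == frozenset()
        assert f.dim == 2

    def test_e1_minimal_face_is_ray(self, ex54_cone, ex54_net):
        f = fg.minimal_face(ex54_cone, ex54_net.flux([1, 1, 0, 1]))
        assert {j + 1 for j in f.canonical_zero_set} == {3}
        assert f.dim == 1

    def test_zero_maps_to_lineality_face(self, fig1_cone):
        f = fg.minimal_face(fig1_cone, fig1_cone.network.flux([0] * 13))
        assert f.canonical_zero_set == fig1_cone.free_irr
        assert f.dim == fig1_cone.dim_lineality

    def test_relint_membership(self, ex54_cone, ex54_net):
        assert fg.in_relative_interior(ex54_cone, ex54_net.flux([0, 0, 1, 1]))
        assert not fg.in_relative_interior(ex54_cone, ex54_net.flux([1, 1, 0, 1]))

    def test_all_reversible_everything_in_relint(self):
        net = fg.MetabolicNetwork(
            ("A",), ("1", "2"), fg.RationalMatrix([[1, -1]]), frozenset()
        )
        cone = fg.build_cone(net)
        assert fg.in_relative_interior(cone, net.flux([3, 3]))


class TestPointedDecomposition:
    def test_ex54_generators_are_the_extreme_rays(self, ex54_cone, ex54_efms):
        m = fg.mmbs(ex54_cone, ex54_efms)
        pd = fg.pointed_decomposition(ex54_cone, [x.witness.vector for x in m])
        gens = {g.values for g in pd.generators}
        assert gens == {
            (F(1), F(1), F(0), F(1)),
            (F(-1), F(-1), F(1), F(0)),
        }
        assert pd.lineality_basis == ()

    def test_fig1_dim_splits(self, fig1_canonical, fig1_canonical_efms):
        m = fg.mmbs(fig1_canonical, fig1_canonical_efms)
        pd = fg.pointed_decomposition(
            fig1_canonical, [x.witness.vector for x in m]
        )
        assert len(pd.generators) == 3
        assert len(pd.lineality_basis) == 2  # 2 + 3 = 5 = dim C
        # Generators lie in the orthogonal complement of L.
        for g in pd.generators:
            for b in pd.lineality_basis:
                assert sum(x * y for x, y in zip(g.values, b)) == 0

    def test_combinatorial_type_independent_of_complement(
        self, fig1_canonical, fig1_canonical_efms
    ):
        """Pointed parts over different complements have the same facet
        incidence structure (combinatorial invariance)."""
        m = fg.mmbs(fig1_canonical, fig1_canonical_efms)
        raw = [x.witness.vector for x in m]  # coordinate representatives
        pd = fg.pointed_decomposition(fig1_canonical, raw)
        # Incidence labelling: which generator activates which MMB.
        label_raw = sorted(frozenset(v.irr_support) for v in raw)
        label_proj = sorted(frozenset(g.irr_support) for g in pd.generators)
        assert label_raw == label_proj


class TestFBA:
    def test_toy_network_optimum(self, ex54_net):
        v = fg.fba(
            ex54_net,
            "4",
            {
                "1": (F(-10), F(10)),
                "2": (F(-10), F(10)),
                "3": (F(0), F(10)),
                "4": (F(0), None),
            },
        )
        assert v[3] == 20
        assert all(x == 0 for x in ex54_net.S.matvec(v.values))

    def test_blocked_objective_zero(self):
        net = fg.MetabolicNetwork(
            ("A",), ("1",), fg.RationalMatrix([[1]]), frozenset({0})
        )
        v = fg.fba(net, "1", {"1": (F(0), F(0))})
        assert v[0] == 0

    def test_unbounded_reported(self, ex54_net):
        with pytest.raises(DomainError, match="unbounded"):
            fg.fba(ex54_net, "4", {})

    def test_infeasible_reported(self, ex54_net):
        with pytest.raises(DomainError, match="infeasible"):
            fg.fba(ex54_net, "4", {"1": (F(1), F(1)), "2": (F(2), F(2))})
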