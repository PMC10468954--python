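import pytest

import fluxgeom as fg
from fluxgeom.exceptions import StateError, VerificationError


def _behaviors_1based(mmb_list):
    return sorted(sorted(j + 1 for j in m.reactions) for m in mmb_list)


class TestMetabolicBehavior:
    def test_ex54_behaviors(self, ex54_cone, ex54_net):
        assert fg.metabolic_behavior(ex54_cone, ex54_net.flux([1, 1, 0, 1])) == {3}
        assert fg.metabolic_behavior(ex54_cone, ex54_net.flux([0, 0, 1, 1])) == {
            2,
            3,
        }

    def test_lineality_vector_has_empty_behavior(self, fig1_cone):
        b = fig1_cone.lineality_basis[0]
        assert fg.metabolic_behavior(fig1_cone, fig1_cone.network.flux(b)) == frozenset()


class TestMMBs:
    def test_fig1_original_description(self, fig1_cone, fig1_efms):
        # Reaction 6 still irreversible: MMBs are {2}, {6,7}, {6,8}.
        assert _behaviors_1based(fg.mmbs(fig1_cone, fig1_efms)) == [
            [2],
            [6, 7],
            [6, 8],
        ]

    def test_fig1_canonical_description(self, fig1_canonical, fig1_canonical_efms):
        assert _behaviors_1based(
            fg.mmbs(fig1_canonical, fig1_canonical_efms)
        ) == [[2], [7], [8]]

    def test_ex54(self, ex54_cone, ex54_efms):
        assert _behaviors_1based(fg.mmbs(ex54_cone, ex54_efms)) == [[3], [4]]

    def test_witness_degree_is_t_plus_1(self, fig1_canonical, fig1_canonical_efms):
        for m in fg.mmbs(fig1_canonical, fig1_canonical_efms):
            assert m.witness.degree == fig1_canonical.dim_lineality + 1

    def test_one_to_one_with_minimal_proper_faces(
        self, fig1_canonical, fig1_canonical_efms
    ):
        lat = fg.face_lattice(fig1_canonical, fig1_canonical_efms)
        t1_faces = [
            f for f in lat.faces if f.dim == fig1_canonical.dim_lineality + 1
        ]
        mmb_list = fg.mmbs(fig1_canonical, fig1_canonical_efms)
        assert len(t1_faces) == len(mmb_list)
        assert {f.relint_behavior for f in t1_faces} == {
            m.reactions for m in mmb_list
        }


class TestFaceLattice:
    def test_requires_canonical(self, fig1_cone, fig1_efms):
        with pytest.raises(StateError):
            fg.face_lattice(fig1_cone, fig1_efms)

    def test_fig1_dimension_multiset(self, fig1_canonical, fig1_canonical_efms):
        lat = fg.face_lattice(fig1_canonical, fig1_canonical_efms)
        assert sorted(f.dim for f in lat.faces) == [2, 3, 3, 3, 4, 4, 4, 5]
        assert lat.faces[lat.bottom].dim == 2  # the lineality space
        assert lat.faces[lat.top].dim == 5  # the cone itself

    def test_ex54_four_faces(self, ex54_cone, ex54_efms):
        lat = fg.face_lattice(fg.canonicalize(ex54_cone), ex54_efms)
        assert sorted(f.dim for f in lat.faces) == [0, 1, 1, 2]

    def test_single_face_when_all_reversible(self):
        net = fg.MetabolicNetwork(
            ("A",), ("1", "2"), fg.RationalMatrix([[1, -1]]), frozenset()
        )
        cone = fg.canonicalize(fg.build_cone(net))
        lat = fg.face_lattice(cone, fg.enumerate_efms(cone))
        assert len(lat.faces) == 1
        assert lat.bottom == lat.top

    def test_cover_edges_increase_dimension(self, fig1_canonical, fig1_canonical_efms):
        lat = fg.face_lattice(fig1_canonical, fig1_canonical_efms)
        for lo, hi in lat.edges:
            assert lat.faces[lo].dim < lat.faces[hi].dim
            assert (
                lat.faces[lo].canonical_zero_set
                > lat.faces[hi].canonical_zero_set
            )

    def test_meet_closed(self, fig1_canonical, fig1_canonical_efms):
        lat = fg.face_lattice(fig1_canonical, fig1_canonical_efms)
        keys = {f.canonical_zero_set for f in lat.faces}
        free = fig1_canonical.free_irr
        for a in lat.faces:
            for b in lat.faces:
                union = a.canonical_zero_set | b.canonical_zero_set
                members = [
                    e
                    for e in fig1_canonical_efms
                    if not (e.irr_support & union)
                ]
                realized = frozenset().union(
                    frozenset(), *(e.irr_support for e in members)
                )
                assert free - realized in keys

    def test_every_k_face_contains_k_efms(
        self, fig1_canonical, fig1_canonical_efms
    ):
        lat = fg.face_lattice(fig1_canonical, fig1_canonical_efms)
        for f, mem in zip(lat.faces, lat.efm_members):
            # Reversible-pair EFMs count once per orientation.
            n_efms = len(mem) + sum(
                1 for i in mem if fig1_canonical_efms[i].is_reversible_pair
            )
            assert n_efms >= f.dim

    def test_random_pool_lattice_consistency(self, random_pool):
        for seed, net, cone in random_pool[:6]:
            can = fg.canonicalize(cone)
            efms = fg.enumerate_efms(can)
            lat = fg.face_lattice(can, efms)
            assert lat.faces[lat.bottom].dim == can.dim_lineality
            assert lat.faces[lat.top].dim == can.dim_cone
            for f, mem in zip(lat.faces, lat.efm_members):
                n = len(mem) + sum(1 for i in mem if efms[i].is_reversible_pair)
                assert n >= f.dim


class TestRelintBehavior:
    def test_top_face_behavior(self, fig1_canonical, fig1_canonical_efms):
        lat = fg.face_lattice(fig1_canonical, fig1_canonical_efms)
        top = lat.faces[lat.top]
        assert {j + 1 for j in fg.relint_behavior(top)} == {2, 7, 8}

    def test_lineality_face_behavior_empty(self, fig1_canonical, fig1_canonical_efms):
        lat = fg.face_lattice(fig1_canonical, fig1_canonical_efms)
        assert fg.relint_behavior(lat.faces[lat.bottom]) == frozenset()

    def test_minimal_proper_face_behavior_is_its_mmb(
        self, fig1_canonical, fig1_canonical_efms
    ):
        lat = fg.face_lattice(fig1_canonical, fig1_canonical_efms)
        for f in lat.faces:
            if f.dim == fig1_canonical.dim_lineality + 1:
                assert len(fg.relint_behavior(f)) == 1


class TestUnionOfMMBs:
    def test_ex54_full_behavior(self, ex54_cone, ex54_efms):
        mmb_list = fg.mmbs(ex54_cone, ex54_efms)
        assert fg.is_union_of_mmbs({2, 3}, mmb_list)

    def test_fig1_pairwise_union(self, fig1_canonical, fig1_canonical_efms):
        mmb_list = fg.mmbs(fig1_canonical, fig1_canonical_efms)
        assert fg.is_union_of_mmbs({1, 6}, mmb_list)  # reactions 2 and 7

    def test_non_union_rejected(self, ex54_cone, ex54_efms):
        mmb_list = fg.mmbs(ex54_cone, ex54_efms)
        assert not fg.is_union_of_mmbs({0}, mmb_list)

    def test_every_realized_behavior_is_a_union(self, fig1_cone, fig1_efms):
        mmb_list = fg.mmbs(fig1_cone, fig1_efms)
        for e in fig1_efms:
            if e.irr_support:
                assert fg.is_union_of_mmbs(e.irr_support, mmb_list)


class TestSimplicityAndCardinality:
    def test_ex54_is_1_simple(self, ex54_cone, ex54_efms):
        lat = fg.face_lattice(fg.canonicalize(ex54_cone), ex54_efms)
        assert fg.l_simplicity(lat) == 1

    def test_fig1_is_1_simple(self, fig1_canonical, fig1_canonical_efms):
        lat = fg.face_lattice(fig1_canonical, fig1_canonical_efms)
        assert fg.l_simplicity(lat) == 1

    def test_mmb_cardinality_bound_values(self, ex54_cone, fig1_cone, fig1_efms):
        assert fg.mmb_cardinality_bound(ex54_cone) == 1
        assert fg.mmb_cardinality_bound(fig1_cone) == 3
        actual_max = max(
            len(m.reactions) for m in fg.mmbs(fig1_cone, fig1_efms)
        )
        assert actual_max == 2 <= 3

    def test_bound_holds_on_random_pool(self, random_pool):
        for seed, net, cone in random_pool:
            efms = fg.enumerate_efms(cone)
            mmb_list = fg.mmbs(cone, efms)
            if mmb_list:
                bound = fg.mmb_cardinality_bound(cone)
                assert max(len(m.reactions) for m in mmb_list) <= bound


class TestProp72:
    def test_fixtures_satisfy_equivalence(
        self, ex54_cone, ex54_efms, fig1_canonical, fig1_canonical_efms
    ):
        can54 = fg.canonicalize(ex54_cone)
        assert fg.check_prop72(can54, fg.mmbs(can54, ex54_efms)) == (True, True)
        assert fg.check_prop72(
            fig1_canonical, fg.mmbs(fig1_canonical, fig1_canonical_efms)
        ) == (True, True)

    def test_requires_canonical(self, fig1_cone, fig1_efms):
        with pytest.raises(StateError):
            fg.check_prop72(fig1_cone, fg.mmbs(fig1_cone, fig1_efms))

    def test_equivalence_on_random_pool(self, random_pool):
        for seed, net, cone in random_pool:
            can = fg.canonicalize(cone)
            mmb_list = fg.mmbs(can, fg.enumerate_efms(can))
            both = fg.check_prop72(can, mmb_list)  # raises if sides disagree
            assert both[0] == both[1]

    def test_disagreement_raises(self, fig1_canonical, fig1_canonical_efms):
        mmb_list = fg.mmbs(fig1_canonical, fig1_canonical_efms)
        fat = [
            fg.MMB(reactions=m.reactions | {99}, witness=m.witness)
            for m in mmb_list
        ]
        with pytest.raises(VerificationError):
            fg.check_prop72(fig1_canonical, fat)
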