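"""MSN morphology, cable coupling and lesion operators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbgt import msn
from cbgt.msn import Level


class TestMorphologyContract:
    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_printed_counts(self, seed):
        m = msn.build_morphology("D1", seed=seed)
        assert m.n_compartments == 121
        assert len(m.sections) == 58
        assert len(m.children(m.soma_id)) == 8
        n_sec = len(m.section_ids(Level.SECONDARY))
        n_sub = len(m.section_ids(Level.SUBORDINATE))
        assert n_sec + n_sub == 32
        assert len(m.glut_synapse_sites) == 32
        assert len(m.da_synapse_sites) == 32

    def test_sites_on_subordinate_level(self, intact_morph):
        m = intact_morph
        levels = {c.id: c.level for c in m.compartments}
        for s in m.glut_synapse_sites + m.da_synapse_sites:
            assert levels[s] is Level.SUBORDINATE

    def test_is_tree_and_positive_coupling(self, intact_morph):
        m = intact_morph
        assert m.is_tree()
        for c in m.compartments:
            if c.parent is not None:
                assert c.coupling_conductance_to_parent > 0

    def test_invalid_receptor_type(self):
        with pytest.raises(ValueError):
            msn.build_morphology("D3")


class TestCableCoupling:
    def test_zero_at_equal_potentials(self, intact_morph):
        v = np.full(121, -77.0)
        for cid in (0, 1, 60, 120):
            assert msn.cable_coupling_current(intact_morph, v, cid) == 0.0

    def test_edge_conservation(self, intact_morph):
        # current flowing 1->2 equals -(current 2->1) in absolute terms
        m = intact_morph
        ids, parent, _, areas, g_ax = m.index_arrays()
        v = np.full(121, -70.0)
        child = 120  # a leaf: its only edge is to its parent
        v[child] = -50.0
        i_child = msn.cable_coupling_current(m, v, int(ids[child]))
        i_parent = msn.cable_coupling_current(m, v, int(ids[parent[child]]))
        # convert densities back to absolute nA
        abs_child = i_child * areas[child] * 1e3
        # parent may have other children at equal potential (no flow)
        abs_parent = i_parent * areas[parent[child]] * 1e3
        assert abs_child == pytest.approx(-abs_parent, rel=1e-9)

    def test_soma_couples_over_eight_edges(self, intact_morph):
        m = intact_morph
        v = np.full(121, -70.0)
        soma_children = m.children(m.soma_id)
        assert len(soma_children) == 8
        # raising one trunk-root potential changes the soma current
        ids, parent, _, areas, _ = m.index_arrays()
        pos = {int(i): k for k, i in enumerate(ids)}
        base = msn.cable_coupling_current(m, v, m.soma_id)
        v2 = v.copy()
        v2[pos[soma_children[0]]] = -60.0
        assert msn.cable_coupling_current(m, v2, m.soma_id) != base

    def test_detached_compartment_errors(self, intact_morph):
        m2 = msn.degrade_dendrites(intact_morph, 32, seed=0)
        gone = set(c.id for c in intact_morph.compartments) \
            - set(c.id for c in m2.compartments)
        v = np.full(m2.n_compartments, -70.0)
        with pytest.raises(ValueError):
            msn.cable_coupling_current(m2, v, next(iter(gone)))


class TestSpineRemoval:
    def test_identity_at_zero(self, intact_morph):
        m2 = msn.remove_spines(intact_morph, 0)
        assert m2.glut_synapse_sites == intact_morph.glut_synapse_sites

    def test_fractions(self, intact_morph):
        m2 = msn.remove_spines(intact_morph, 16, seed=3)
        assert m2.lesion.spine_loss_fraction == 0.5
        assert len(m2.glut_synapse_sites) == 16

    def test_full_removal_silences_glut(self, intact_morph):
        m2 = msn.remove_spines(intact_morph, 32, seed=3)
        assert m2.glut_synapse_sites == []

    def test_type1_sites_removed_first(self, intact_morph):
        md = msn.mark_lost_da_sites(intact_morph, 0.5, seed=5)
        assert len(md.lost_da_sites) == 16
        m2 = msn.remove_spines(md, 10, "type1_first", seed=6)
        assert set(m2.lesion.removed_spine_sites) <= set(md.lost_da_sites)
        # beyond the type-1 pool, type-2 sites start to go
        m3 = msn.remove_spines(md, 20, "type1_first", seed=6)
        assert set(md.lost_da_sites) <= set(m3.lesion.removed_spine_sites)

    def test_out_of_range(self, intact_morph):
        with pytest.raises(ValueError):
            msn.remove_spines(intact_morph, 33)


class TestDendriteDegradation:
    def test_identity_at_zero(self, intact_morph):
        m2 = msn.degrade_dendrites(intact_morph, 0)
        assert m2.n_compartments == 121

    def test_full_removal_leaves_soma_and_trunks(self, intact_morph):
        m2 = msn.degrade_dendrites(intact_morph, 32, seed=1)
        levels = {c.level for c in m2.compartments}
        assert levels == {Level.SOMA, Level.PRIMARY}
        assert m2.glut_synapse_sites == []
        assert m2.da_synapse_sites == []

    def test_fraction_granularity(self, intact_morph):
        m2 = msn.degrade_dendrites(intact_morph, 10, seed=1)
        assert m2.lesion.dendrite_loss_fraction == pytest.approx(0.3125)

    @pytest.mark.parametrize("nd", [4, 12, 24])
    def test_compartment_conservation_and_tree(self, intact_morph, nd):
        m2 = msn.degrade_dendrites(intact_morph, nd, seed=2)
        detached = 121 - m2.n_compartments
        assert m2.n_compartments + detached == 121
        assert m2.is_tree()
        assert m2.lesion.nd == nd
        # sites remain a subset of attached subordinate compartments
        attached_sub = {c.id for c in m2.compartments
                        if c.level is Level.SUBORDINATE}
        assert set(m2.glut_synapse_sites) <= attached_sub

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(a=st.integers(0, 16), b=st.integers(0, 16))
    def test_composition_matches_single_lesion_count(self, a, b):
        m = msn.build_morphology("D1", seed=0)
        two_step = msn.degrade_dendrites(
            msn.degrade_dendrites(m, a, seed=9), b, seed=10)
        one_step = msn.degrade_dendrites(m, a + b, seed=9)
        attached_two = len(two_step.attached_section_ids())
        attached_one = len(one_step.attached_section_ids())
        assert attached_two == attached_one
        assert two_step.lesion.nd == a + b

    def test_out_of_range(self, intact_morph):
        with pytest.raises(ValueError):
            msn.degrade_dendrites(intact_morph, 33)


class TestDynamicsUnderLesions:
    def test_mfr_non_decreasing_with_dendrite_removal(self, intact_morph):
        from cbgt.engine import run_msn_cell
        rates = []
        for nd in (0, 16, 32):
            m = msn.degrade_dendrites(intact_morph, nd, seed=42)
            _, _, sp = run_msn_cell(m, 40.0, 600.0)
            rates.append(len(sp))
        assert rates[0] <= rates[1] <= rates[2]

    def test_soma_rhs_matches_full_rhs(self, intact_morph):
        params = msn.MSNParams()
        state = msn.msn_steady_state(intact_morph, -80.0, params)
        state.v += np.linspace(-3, 3, 121)  # non-uniform potentials
        full = msn.msn_rhs(intact_morph, state, params)
        soma = msn.msn_soma_rhs(intact_morph, state, params)
        assert soma == pytest.approx(full.v[0])
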