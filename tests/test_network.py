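"""Wiring contracts, reproducibility, dopamine depletion semantics."""

import numpy as np
import pytest

from cbgt import network as net


def in_degree(wiring, post_pop, pre_pop):
    df = net.count_in_degrees(wiring)
    sel = df[(df.post_pop == post_pop) & (df.pre_pop == pre_pop)]
    return sel.set_index("post")["count"]


class TestWiringContract:
    @pytest.mark.parametrize("seed", range(20))
    def test_connectivity_contract_across_seeds(self, seed):
        cfg = net.NetworkConfig(seed=seed)
        w = net.build_network(cfg)
        # STN <- 3 PY and 2 GPe
        assert (in_degree(w, "stn", "py") == 3).all()
        assert (in_degree(w, "stn", "gpe") == 2).all()
        # TH <- 3 GPi
        assert (in_degree(w, "th", "gpi") == 3).all()
        # GPi <- 2 GPe, 2 STN, 1 GPi
        assert (in_degree(w, "gpi", "gpe") == 2).all()
        assert (in_degree(w, "gpi", "stn") == 2).all()
        assert (in_degree(w, "gpi", "gpi") == 1).all()
        # exactly 6 PY receive thalamic feedback
        fed = in_degree(w, "py", "th")
        assert len(fed) == 6

    def test_msn_all_to_one(self):
        cfg = net.NetworkConfig(seed=3)
        w = net.build_network(cfg)
        assert (in_degree(w, "d1", "py") == 2 * cfg.n_py).all()  # AMPA+NMDA
        assert (in_degree(w, "d1", "da") == cfg.n_da).all()
        assert (in_degree(w, "d2", "py") == 2 * cfg.n_py).all()

    def test_reproducible_wiring(self):
        cfg = net.NetworkConfig(seed=11)
        w1 = net.build_network(cfg)
        w2 = net.build_network(cfg)
        assert w1.to_frame().equals(w2.to_frame())
        w3 = net.build_network(net.NetworkConfig(seed=12))
        assert not w1.to_frame().equals(w3.to_frame())

    def test_empty_count_table(self):
        out = net.count_in_degrees(net.Wiring(edges=[], th_fed_py=[]))
        assert out.empty

    def test_population_too_small_errors(self):
        with pytest.raises(ValueError):
            net.build_network(net.NetworkConfig(n_py=2))

    def test_inhibitory_classes_are_gabaergic(self):
        # the pallidal and striatal projections, including GPe->STN and
        # D2->GPe, are inhibitory
        for cls in ("gpe_stn", "d2_gpe", "gpe_gpe", "d1_gpi", "gpe_gpi",
                    "gpi_gpi", "gpi_th"):
            assert net.EDGE_KIND[cls] == "GABA"


class TestConfigValidation:
    def test_depletion_range(self):
        with pytest.raises(ValueError):
            net.NetworkConfig(dopamine_depletion=1.2)

    def test_unknown_weight_key(self):
        with pytest.raises(ValueError):
            net.NetworkConfig(weights={"nope": 1.0})

    def test_lesion_ranges(self):
        with pytest.raises(ValueError):
            net.LesionSpec(ns=40)
        with pytest.raises(ValueError):
            net.LesionSpec(nd=-1)


class TestDepletion:
    def test_zero_fraction_is_identity(self):
        nw = net.build(net.NetworkConfig(seed=4))
        out = net.apply_dopamine_depletion(nw, 0.0)
        assert out.removed_da == []
        assert not out.is_pd
        assert out.d1_cells[0].lost_da_sites == []

    def test_pd_threshold_is_strictly_above_half(self):
        nw = net.build(net.NetworkConfig(seed=4))
        assert not net.apply_dopamine_depletion(nw, 0.5).is_pd
        assert net.apply_dopamine_depletion(nw, 0.51).is_pd

    def test_full_depletion_silences_all_da(self):
        nw = net.build(net.NetworkConfig(seed=4))
        out = net.apply_dopamine_depletion(nw, 1.0)
        assert out.active_da_cells() == []
        for m in out.d1_cells + out.d2_cells:
            assert len(m.lost_da_sites) == 32

    def test_rounding_is_ceiling(self):
        cfg = net.NetworkConfig(seed=4)  # n_da = 8
        nw = net.build(cfg)
        out = net.apply_dopamine_depletion(nw, 0.51)
        assert len(out.removed_da) == int(np.ceil(0.51 * cfg.n_da))

    def test_site_accounting_after_depletion(self):
        # active DA->MSN synapse sites = 32 * (1 - f) rounded by ceil
        nw = net.build(net.NetworkConfig(seed=8))
        for f in (0.125, 0.5, 0.75):
            out = net.apply_dopamine_depletion(nw, f)
            for m in out.d1_cells + out.d2_cells:
                n_lost = len(m.lost_da_sites)
                assert n_lost == int(np.ceil(32 * f))
                assert len(m.da_synapse_sites) - n_lost == 32 - n_lost

    def test_lesion_applied_after_depletion_sees_type1(self):
        cfg = net.NetworkConfig(seed=5, dopamine_depletion=0.5,
                                lesion=net.LesionSpec(ns=8))
        nw = net.build(cfg)
        for m in nw.d1_cells + nw.d2_cells:
            removed = set(m.lesion.removed_spine_sites)
            assert removed <= set(m.lost_da_sites)
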