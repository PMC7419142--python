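"""Connectivity construction, projection rules and structural invariants."""

import numpy as np
import pytest

from cxring import circuit as cc
from cxring.circuit import (WeightVector, build_species_circuit,
                            delta7_inhibition_profile, epg_transition_octants,
                            hemisphere_asymmetry, remove_peg, synaptic_noise,
                            unit_graph)

W = WeightVector(3.0, 1.0, 1.0, -3.0, -3.0)


class TestWeightVector:
    def test_bounds_enforced(self):
        with pytest.raises(cc.CircuitError):
            WeightVector(101.0, 1, 1, -1, -1)
        with pytest.raises(cc.CircuitError):
            WeightVector(1, 1, 1, 1, -1)   # w4 must be <= 0

    def test_initialisation_convention(self):
        init = WeightVector.initial().as_array()
        assert np.allclose(np.abs(init), 0.01)
        assert np.all(np.sign(init) == [1, 1, 1, -1, -1])

    def test_roundtrip(self):
        assert WeightVector.from_dict(W.to_dict()) == W


class TestInventory:
    def test_fly_inventory(self):
        cx = build_species_circuit("fly", W)
        assert cx.n_neurons == 60
        counts = cx.neurons["cls"].value_counts()
        assert counts["E-PG"] == 18
        assert counts["P-EN"] == 16   # no P-EN in the innermost glomeruli
        assert counts["P-EG"] == 18
        assert counts["Delta7"] == 8

    def test_locust_inventory(self):
        cx = build_species_circuit("locust", W)
        assert cx.n_neurons == 56
        counts = cx.neurons["cls"].value_counts()
        assert all(counts[c] == n for c, n in
                   [("E-PG", 16), ("P-EN", 16), ("P-EG", 16), ("Delta7", 8)])

    def test_unknown_species(self):
        with pytest.raises(cc.CircuitError):
            build_species_circuit("bee", W)

    def test_zero_weights_zero_matrix(self):
        cx = build_species_circuit("fly", WeightVector.zeros())
        assert cx.M.shape == (60, 60)
        assert np.all(cx.M == 0)
        assert len(cx.labels) == 60


class TestDelta7Profile:
    def test_peak_value(self):
        # exponent argument vanishes at i = 5 for n = 8; peak W/(sigma sqrt(2 pi))
        val = delta7_inhibition_profile(5, 8, 0.8, 1.0)
        assert val == pytest.approx(1.0 / (0.8 * np.sqrt(2 * np.pi)), rel=1e-9)
        assert val == pytest.approx(0.4987, abs=2e-4)

    def test_symmetry_about_centre(self):
        for k in (1, 2, 3):
            assert delta7_inhibition_profile(5 + k, 8, 0.8, 1.0) == pytest.approx(
                delta7_inhibition_profile(5 - k, 8, 0.8, 1.0))

    def test_nine_glomeruli(self):
        vals = [delta7_inhibition_profile(i, 9, 0.8, 1.0) for i in range(1, 10)]
        assert len(vals) == 9
        assert np.argmax(vals) in (4, 5)  # peak midway around the ring

    def test_input_validation(self):
        with pytest.raises(cc.CircuitError):
            delta7_inhibition_profile(0, 8, 0.8, 1.0)
        with pytest.raises(cc.CircuitError):
            delta7_inhibition_profile(3, 8, -0.1, 1.0)


@pytest.mark.parametrize("species,n", [("fly", 60), ("locust", 56),
                                       ("hybrid", 60)])
class TestSignPartition:
    def test_rows_match_presynaptic_class(self, species, n):
        cx = build_species_circuit(species, W)
        assert cx.M.shape == (n, n)
        for cls in ("E-PG", "P-EN", "P-EG"):
            assert np.all(cx.M[cx.class_indices(cls)] >= 0)
        assert np.all(cx.M[cx.class_indices("Delta7")] <= 0)
        assert np.all(np.diag(cx.M) == 0)


class TestProjectionRules:
    def test_fly_delta7_all_to_all(self):
        cx = build_species_circuit("fly", W)
        d7 = cx.class_indices("Delta7")
        block = cx.M[np.ix_(d7, d7)]
        assert np.count_nonzero(block) == 56   # 8 rows x 7 partners
        assert all(np.count_nonzero(block[i]) == 7 for i in range(8))

    def test_locust_pen_reciprocal_same_octant(self):
        cx = build_species_circuit("locust", W)
        octs = cx.neurons["octant"].to_numpy()
        for p in cx.class_indices("P-EN"):
            same = [e for e in cx.class_indices("E-PG") if octs[e] == octs[p]]
            assert any(cx.M[p, e] != 0 for e in same)

    def test_fly_pen_shifts_one_tile(self):
        cx = build_species_circuit("fly", W)
        octs = cx.neurons["octant"].to_numpy()
        hemi = cx.neurons["hemi"].to_numpy()
        for p in cx.class_indices("P-EN"):
            targets = {octs[e] for e in cx.class_indices("E-PG")
                       if cx.M[p, e] != 0}
            shift = 1 if hemi[p] == "L" else -1
            assert targets == {(octs[p] + shift) % 8}

    def test_fly_seam_tile_shared(self):
        # tile T1 is innervated by both E-PG_1 and E-PG_9
        cx = build_species_circuit("fly", W)
        octs = cx.neurons["octant"].to_numpy()
        gloms = cx.neurons["glom"].to_numpy()
        seam = [i for i in cx.class_indices("E-PG") if octs[i] == 0]
        assert sorted(gloms[seam].tolist()) == [1, 1, 9, 9]

    def test_locust_medial_cross_innervation(self):
        cx = build_species_circuit("locust", W)
        src = cx.index("E-PG", "L", 8)
        assert cx.M[src, cx.index("P-EN", "R", 1)] != 0
        assert cx.M[src, cx.index("P-EG", "R", 1)] != 0
        src = cx.index("E-PG", "R", 1)
        assert cx.M[src, cx.index("P-EN", "L", 8)] != 0

    def test_fly_epg_delta7_uniform_but_locust_profiled(self):
        fly = build_species_circuit("fly", W)
        locust = build_species_circuit("locust", W)
        fb = fly.M[np.ix_(fly.class_indices("E-PG"),
                          fly.class_indices("Delta7"))]
        lb = locust.M[np.ix_(locust.class_indices("E-PG"),
                             locust.class_indices("Delta7"))]
        assert np.allclose(fb, fb[0, 0])            # uniform
        assert np.unique(np.round(lb, 12)).size > 4  # Gaussian-graded

    def test_hybrid_replaces_inhibition_pattern_only(self):
        fly = build_species_circuit("fly", W)
        hyb = build_species_circuit("hybrid", W)
        exc = np.concatenate([fly.class_indices("P-EN"),
                              fly.class_indices("P-EG")])
        epg = fly.class_indices("E-PG")
        # excitatory EB pathways identical to the fly
        assert np.allclose(fly.M[np.ix_(exc, epg)], hyb.M[np.ix_(exc, epg)])
        d7 = fly.class_indices("Delta7")
        assert not np.allclose(fly.M[np.ix_(epg, d7)], hyb.M[np.ix_(epg, d7)])
        assert not np.allclose(fly.M[np.ix_(d7, d7)], hyb.M[np.ix_(d7, d7)])


@pytest.mark.parametrize("species", ["fly", "locust", "hybrid"])
class TestRingStructure:
    def test_eightfold_symmetry_up_to_seam(self, species):
        # rotating octant labels by one maps the unit-level digraph onto
        # itself, except at the documented seam (fly/hybrid: exact thanks to
        # the G1/G9 merge; locust: the medial cross-innervation edges)
        import networkx as nx
        cx = build_species_circuit(species, W)
        g = unit_graph(cx)
        mapping = {(cls, o): (cls, (o + 1) % 8) for cls, o in g.nodes}
        rotated = nx.relabel_nodes(g, mapping, copy=True)
        diff = set(rotated.edges) ^ set(g.edges)
        if species == "locust":
            seam = {0, 7}
            assert all(u[1] in seam or v[1] in seam for u, v in diff)
        else:
            assert diff == set()

    def test_ring_closure_through_pen(self, species):
        # E-PG -> P-EN -> E-PG reachability forms one cycle in each direction
        cx = build_species_circuit(species, W)
        trans = epg_transition_octants(cx)
        fwd = {(o, (o + 1) % 8) for o in range(8)}
        bwd = {(o, (o - 1) % 8) for o in range(8)}
        assert trans == fwd | bwd


class TestVariants:
    def test_remove_peg_shape(self):
        cx = remove_peg(build_species_circuit("fly", W))
        assert cx.n_neurons == 42
        assert "P-EG" not in set(cx.neurons["cls"])

    def test_full_asymmetry_zeroes_one_hemisphere(self):
        base = build_species_circuit("fly", W)
        cx = hemisphere_asymmetry(base, -1.0, "R")
        pre = ((cx.neurons["cls"] == "P-EN")
               & (cx.neurons["hemi"] == "R")).to_numpy()
        post = (cx.neurons["cls"] == "E-PG").to_numpy()
        assert np.all(cx.M[np.ix_(pre, post)] == 0)
        left = ((cx.neurons["cls"] == "P-EN")
                & (cx.neurons["hemi"] == "L")).to_numpy()
        assert np.any(cx.M[np.ix_(left, post)] != 0)

    def test_asymmetry_factor_range(self):
        base = build_species_circuit("fly", W)
        with pytest.raises(cc.CircuitError):
            hemisphere_asymmetry(base, 1.5)

    def test_zero_synaptic_noise_is_identity(self, rng):
        base = build_species_circuit("locust", W)
        assert np.array_equal(synaptic_noise(base, 0.0, rng).M, base.M)

    def test_synaptic_noise_preserves_sparsity(self, rng):
        base = build_species_circuit("locust", W)
        noisy = synaptic_noise(base, 30.0, rng)
        assert np.array_equal(noisy.M == 0, base.M == 0)
        assert not np.allclose(noisy.M, base.M)


class TestTinyAnalogue:
    def test_tiny_ring_same_invariants(self, tiny_fly, tiny_locust):
        for cx in (tiny_fly, tiny_locust):
            n = cx.n_octants
            for cls in ("E-PG", "P-EN", "P-EG"):
                assert np.all(cx.M[cx.class_indices(cls)] >= 0)
            assert np.all(cx.M[cx.class_indices("Delta7")] <= 0)
            trans = epg_transition_octants(cx)
            assert {(o, (o + 1) % n) for o in range(n)} <= trans
            assert {(o, (o - 1) % n) for o in range(n)} <= trans


class TestSerialisation:
    def test_csv_roundtrip(self, tmp_path):
        cx = build_species_circuit("locust", W)
        p = tmp_path / "m.csv"
        cx.to_csv(p)
        back = cc.ConnectivityMatrix.from_csv(p, species="locust")
        assert np.allclose(back.M, cx.M)
        assert back.labels == cx.labels

    def test_adjacency_and_dot(self, tmp_path, tiny_fly):
        tiny_fly.to_adjacency_json(tmp_path / "a.json")
        tiny_fly.to_dot(tmp_path / "a.dot")
        import json
        adj = json.loads((tmp_path / "a.json").read_text())
        assert len(adj["edges"]) == np.count_nonzero(tiny_fly.M)
        assert "digraph" in (tmp_path / "a.dot").read_text()
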