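import dataclasses

import numpy as np
import pytest

from rpfold.contacts import Contact, ContactMap
from rpfold.dynamics import Trajectory
from rpfold.errors import (AllBinsEmpty, DegenerateWeights, EmptyBin,
                           EmptyContactMap, NoTwoBasins, ZeroVariance)
from rpfold.landscape import (QSettings, RouteMap, average_contact_map_at_q,
                              fraction_native_contacts, free_energy_profile,
                              locate_basins, reweight_histogram,
                              route_similarity)


@pytest.fixture(scope="module")
def square_map():
    """Four contacts on a 10-residue chain, d_ij = 0.5 nm each."""
    return ContactMap(10, frozenset({
        Contact(1, 5, 0.5), Contact(2, 6, 0.5),
        Contact(3, 7, 0.5), Contact(4, 8, 0.5)}), 4.5, 3)


def _coords_with_formed(square_map, formed_pairs):
    x = np.zeros((10, 3))
    for k in range(10):
        x[k] = [0.0, 0.0, 10.0 * k]        # everything far apart
    for c in square_map.sorted_contacts():
        if c.pair in formed_pairs:
            x[c.j - 1] = x[c.i - 1] + [0.5, 0.0, 0.0]
    return x


class TestQ:
    def test_native_is_one(self, hairpin_topology, hairpin_map):
        q = fraction_native_contacts(hairpin_topology.native_coords,
                                     hairpin_map)
        assert q == 1.0

    def test_extended_is_zero(self, square_map):
        x = _coords_with_formed(square_map, set())
        assert fraction_native_contacts(x, square_map) == 0.0

    def test_partial_counting(self, square_map):
        x = _coords_with_formed(square_map, {(1, 5)})
        assert fraction_native_contacts(x, square_map) == 0.25

    def test_empty_map_rejected(self):
        with pytest.raises(EmptyContactMap):
            fraction_native_contacts(np.zeros((5, 3)),
                                     ContactMap(5, frozenset(), 4.5, 3))


class TestReweighting:
    def test_identity_at_same_temperature(self, rng):
        q = rng.uniform(0, 1, 2000)
        e = rng.normal(-10, 3, 2000)
        p = reweight_histogram(q, e, 1.0, 1.0)
        raw, _ = np.histogram(q, bins=QSettings().bin_edges)
        np.testing.assert_allclose(p, raw / raw.sum(), atol=1e-14)
        assert p.sum() == pytest.approx(1.0)

    def test_round_trip_recovers_histogram(self, rng):
        q = rng.uniform(0, 1, 2000)
        e = rng.normal(-10.0, 2.0, 2000)
        qs = QSettings()
        p0 = reweight_histogram(q, e, 1.0, 1.0, qs)
        # weights w(T->T') then w(T'->T) multiply back to 1 sample-wise;
        # verify via explicit two-step reweighting of per-sample weights
        b1, b2 = 1.0 / 1.0, 1.0 / 1.3
        w1 = np.exp(-(b2 - b1) * e)
        w2 = np.exp(-(b1 - b2) * e)
        hist, _ = np.histogram(q, bins=qs.bin_edges, weights=w1 * w2)
        np.testing.assert_allclose(hist / hist.sum(), p0, atol=1e-10)

    def test_two_level_boltzmann_ratio_exact(self):
        de, g_u, g_f = 3.0, 600, 200
        q = np.concatenate([np.full(g_u, 0.11), np.full(g_f, 0.89)])
        e = np.concatenate([np.zeros(g_u), np.full(g_f, -de)])
        t_target = 0.8
        p = reweight_histogram(q, e, 1.0, t_target)
        qs = QSettings()
        bin_u = np.searchsorted(qs.bin_edges, 0.11, side="right") - 1
        bin_f = np.searchsorted(qs.bin_edges, 0.89, side="right") - 1
        expected = (g_f / g_u) * np.exp(de / t_target - de / 1.0)
        assert p[bin_f] / p[bin_u] == pytest.approx(expected, abs=1e-12)

    def test_degenerate_weights_warn(self):
        q = np.linspace(0, 1, 50)
        e = np.concatenate([[-1000.0], np.zeros(49)])
        with pytest.warns(DegenerateWeights):
            reweight_histogram(q, e, 1.0, 0.2)


class TestFreeEnergyProfile:
    def test_uniform_population_is_flat(self):
        p = np.full(50, 1.0 / 50)
        prof = free_energy_profile(p, 1.0)
        np.testing.assert_allclose(prof.dG, 0.0, atol=1e-14)

    def test_two_equal_maxima_have_equal_dg(self):
        p = np.zeros(50)
        p[5] = p[44] = 0.4
        p[25] = 0.2
        prof = free_energy_profile(p / p.sum(), 1.0)
        assert prof.dG[5] == pytest.approx(prof.dG[44])
        assert np.isnan(prof.dG[0])        # empty bin flagged, not filled

    def test_recovers_constructed_potential(self):
        qs = QSettings()
        v = 4.0 * np.sin(np.pi * qs.bin_centers) ** 2
        p = np.exp(-v)
        p /= p.sum()
        prof = free_energy_profile(p, 1.0, qs)
        np.testing.assert_allclose(prof.dG, v - v.min(), atol=1e-10)

    def test_all_empty_rejected(self):
        with pytest.raises(AllBinsEmpty):
            free_energy_profile(np.zeros(50), 1.0)


def _profile_from_dg(dg):
    """FEP whose -ln P equals ``dg`` exactly (P = exp(-dg), normalized)."""
    p = np.exp(-np.asarray(dg, float))
    return free_energy_profile(p / p.sum(), 1.0)


class TestBasins:
    def _double_well(self, barrier=4.0):
        # flat-bottomed wells and a flat barrier top survive 3-bin
        # smoothing unchanged
        dg = np.empty(50)
        ramp_up = np.linspace(0.0, barrier, 16)
        dg[:5] = 0.0
        dg[5:21] = ramp_up
        dg[21:29] = barrier
        dg[29:45] = ramp_up[::-1]
        dg[45:] = 0.0
        return dg

    def test_double_well_barrier_height(self):
        rep = locate_basins(_profile_from_dg(self._double_well(4.0)))
        assert rep.barrier_fold == pytest.approx(4.0, abs=0.01)
        assert rep.barrier_unfold == pytest.approx(4.0, abs=0.01)
        assert rep.q_unfolded_min < rep.q_folded_min
        assert rep.intermediates == []

    def test_triple_well_reports_one_intermediate(self):
        dg = self._double_well(4.0)
        dg[23:27] = 3.0          # flat dip of depth 1.0 in the barrier
        rep = locate_basins(_profile_from_dg(dg))
        assert len(rep.intermediates) == 1
        q_i, prom = rep.intermediates[0]
        assert prom == pytest.approx(1.0, abs=0.05)
        assert 0.4 < q_i < 0.6

    def test_shallow_dip_below_prominence_ignored(self):
        dg = self._double_well(4.0)
        dg[24:26] = 3.8          # 0.2 k_BT dip < 0.5 prominence floor
        rep = locate_basins(_profile_from_dg(dg))
        assert rep.intermediates == []

    def test_monotone_profile_rejected(self):
        with pytest.raises(NoTwoBasins):
            locate_basins(_profile_from_dg(np.linspace(0, 5, 50)))


class TestRouteMaps:
    def _traj(self, square_map, formed_sets, q_values):
        coords = np.stack([_coords_with_formed(square_map, fs)
                           for fs in formed_sets])
        return Trajectory(steps=np.arange(len(formed_sets)),
                          q=np.array(q_values, dtype=float),
                          energy=np.zeros(len(formed_sets)),
                          temperature=1.0, seed=0, coords=coords)

    def test_all_native_snapshots(self, square_map):
        all_pairs = {c.pair for c in square_map.contacts}
        traj = self._traj(square_map, [all_pairs, all_pairs], [1.0, 1.0])
        route = average_contact_map_at_q(traj, square_map, 0.99)
        np.testing.assert_array_equal(route.C, 1.0)
        assert route.N_Q == 2

    def test_half_formed_contact(self, square_map):
        traj = self._traj(square_map,
                          [{(1, 5), (2, 6)}, {(1, 5)}], [0.5, 0.5])
        route = average_contact_map_at_q(traj, square_map, 0.5)
        by_pair = dict(zip(map(tuple, route.pairs), route.C))
        assert by_pair[(1, 5)] == 1.0
        assert by_pair[(2, 6)] == 0.5
        assert by_pair[(3, 7)] == 0.0

    def test_mean_formation_equals_bin_mean_q(self, square_map):
        formed = [{(1, 5)}, {(1, 5), (2, 6)}]
        # both snapshots land in the same wide bin
        qs = QSettings(n_bins=10)
        traj = self._traj(square_map, formed, [0.41, 0.45])
        route = average_contact_map_at_q(traj, square_map, 0.43, qs)
        assert route.C.mean() == pytest.approx(np.mean([0.25, 0.5]))

    def test_empty_bin_rejected(self, square_map):
        traj = self._traj(square_map, [{(1, 5)}], [0.25])
        with pytest.raises(EmptyBin):
            average_contact_map_at_q(traj, square_map, 0.9)


class TestRouteSimilarity:
    def _route(self, c_values, q_bin=0.5):
        pairs = np.array([[1, 5], [2, 6], [3, 7], [4, 8]])
        return RouteMap(q_bin, pairs, np.array(c_values, float), 10)

    def test_identical_routes(self):
        a = self._route([0.9, 0.7, 0.2, 0.1])
        assert route_similarity(a, a) == pytest.approx(1.0)

    def test_mirror_routes_anticorrelate(self):
        nterm_first = self._route([0.9, 0.8, 0.2, 0.1])
        cterm_first = self._route([0.1, 0.2, 0.8, 0.9])
        assert route_similarity(nterm_first, cterm_first) < 0.0

    def test_constant_vector_rejected(self):
        a = self._route([0.5, 0.5, 0.5, 0.5])
        b = self._route([0.9, 0.1, 0.4, 0.2])
        with pytest.raises(ZeroVariance):
            route_similarity(a, b)
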