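import numpy as np
import pytest

from rpfold.contacts import (Contact, ContactMap, composite_map,
                             compute_contact_map, difference_map,
                             read_contact_file, region_gain_loss,
                             sensitive_regions, write_contact_file,
                             CompositeMap)
from rpfold.errors import IncompatibleSizes
from rpfold.repack import permute_sequence, repack_side_chains
from rpfold.structure_io import (Atom, ProteinStructure, Residue,
                                 extract_backbone)


def _brute_force_pairs(s, cutoff, min_sep):
    entries = s.heavy_atoms()
    pairs = set()
    for x in range(len(entries)):
        for y in range(x + 1, len(entries)):
            ri, ai = entries[x]
            rj, aj = entries[y]
            if ri == rj:
                continue
            lo, hi = min(ri, rj), max(ri, rj)
            if hi - lo < min_sep:
                continue
            if np.linalg.norm(ai.coords - aj.coords) < cutoff:
                pairs.add((lo, hi))
    return pairs


def _random_structure(rng, n_res=8, atoms_per_res=4, box=12.0):
    residues = []
    for r in range(n_res):
        atoms = [Atom("CA" if k == 0 else f"X{k}", "C",
                      rng.uniform(0, box, 3))
                 for k in range(atoms_per_res)]
        residues.append(Residue(r + 1, "A", atoms))
    return ProteinStructure(residues, "random")


class TestComputeContactMap:
    def test_matches_brute_force_on_hairpin(self, hairpin, hairpin_map):
        assert hairpin_map.pairs == _brute_force_pairs(hairpin, 4.5, 3)

    @pytest.mark.parametrize("cutoff,min_sep", [(4.5, 3), (5.5, 3), (6.0, 4)])
    def test_matches_brute_force_on_random_structures(self, rng, cutoff,
                                                      min_sep):
        for _ in range(20):
            s = _random_structure(rng)
            cm = compute_contact_map(s, cutoff, min_sep)
            assert cm.pairs == _brute_force_pairs(s, cutoff, min_sep)

    def test_cutoff_monotonicity(self, hairpin, balanced, bulky):
        for s in (hairpin, balanced, bulky):
            m45 = compute_contact_map(s, 4.5).pairs
            m55 = compute_contact_map(s, 5.5).pairs
            m60 = compute_contact_map(s, 6.0).pairs
            assert m45 <= m55 <= m60

    def test_strict_cutoff_and_min_sep(self):
        def pair_structure(dist, gap):
            res = []
            for r in range(1, gap + 2):
                atoms = [Atom("CA", "C", [0, 100 * r, 0])]
                res.append(Residue(r, "A", atoms))
            res[0].atoms.append(Atom("CB", "C", [0, 0, 0]))
            res[-1].atoms.append(Atom("CB", "C", [dist, 0, 0]))
            return ProteinStructure(res, "pair")

        assert compute_contact_map(pair_structure(4.0, 4)).M == 1
        assert compute_contact_map(pair_structure(4.5, 4)).M == 0   # strict <
        assert compute_contact_map(pair_structure(4.6, 4)).M == 0
        # j - i = 2 fails the default min_sep of 3
        assert compute_contact_map(pair_structure(3.0, 2)).M == 0
        assert compute_contact_map(pair_structure(3.0, 3)).M == 1
        # the alternative reading (three intervening residues)
        assert compute_contact_map(pair_structure(3.0, 3), min_sep=4).M == 0

    def test_d_ij_is_ca_distance_in_nm(self, hairpin, hairpin_map):
        ca = hairpin.ca_coords() * 0.1
        for c in hairpin_map.contacts:
            assert c.d_ij == pytest.approx(
                np.linalg.norm(ca[c.j - 1] - ca[c.i - 1]))

    def test_backbone_driven_contacts_survive_permutation(self, hairpin):
        bb = extract_backbone(hairpin)
        bb_pairs = compute_contact_map(bb).pairs
        for seed in (1, 2, 3):
            seq = permute_sequence(hairpin.sequence, seed).permuted_sequence
            rp = repack_side_chains(bb, seq)
            assert bb_pairs <= compute_contact_map(rp).pairs


class TestMapAlgebra:
    def test_composite_identical_and_disjoint(self, hairpin_map):
        comp = composite_map([hairpin_map] * 5)
        assert set(comp.counts.values()) == {5}
        a = ContactMap(10, frozenset({Contact(1, 5, 1.0)}), 4.5, 3)
        b = ContactMap(10, frozenset({Contact(2, 7, 1.0)}), 4.5, 3)
        comp2 = composite_map([a, b])
        assert set(comp2.counts.values()) == {1}

    def test_composite_conserves_total(self, hairpin, balanced):
        maps = [compute_contact_map(s) for s in (hairpin,)]
        bb = extract_backbone(hairpin)
        for seed in (1, 2):
            seq = permute_sequence(hairpin.sequence, seed).permuted_sequence
            maps.append(compute_contact_map(repack_side_chains(bb, seq)))
        comp = composite_map(maps)
        assert sum(comp.counts.values()) == sum(m.M for m in maps)

    def test_incompatible_sizes(self, hairpin_map):
        other = ContactMap(99, frozenset({Contact(1, 5, 1.0)}), 4.5, 3)
        with pytest.raises(IncompatibleSizes):
            composite_map([hairpin_map, other])
        with pytest.raises(IncompatibleSizes):
            difference_map(hairpin_map, other)

    def test_difference_partitions(self, hairpin_map):
        d = difference_map(hairpin_map, hairpin_map)
        assert not d.wt_only and not d.rp_only
        assert d.common == hairpin_map.pairs
        empty = ContactMap(hairpin_map.n_residues, frozenset(), 4.5, 3)
        d2 = difference_map(hairpin_map, empty)
        assert d2.wt_only == hairpin_map.pairs
        assert len(d2.common) + len(d2.wt_only) == hairpin_map.M


class TestRegionAnalytics:
    def _map(self, pairs, n=20):
        return ContactMap(n, frozenset(Contact(i, j, 1.0) for i, j in pairs),
                          4.5, 3)

    def test_identical_maps_have_zero_turnover(self):
        wt = self._map([(1, 5), (2, 8), (11, 16)])
        out = region_gain_loss(wt, [wt], {"CORE": range(1, 11)})
        assert out.gained["CORE"] == [0.0]
        assert out.lost["CORE"] == [0.0]

    def test_hand_built_loss_fractions(self):
        # 6 WT contacts, 4 inside CORE; RP loses 2 CORE contacts and
        # gains 1 CORE contact and 1 periphery contact
        wt = self._map([(1, 5), (2, 8), (3, 7), (4, 9), (12, 16), (13, 18)])
        rp = self._map([(1, 5), (2, 8), (2, 9), (12, 16), (13, 18), (14, 19)])
        out = region_gain_loss(wt, [rp], {"CORE": range(1, 11),
                                          "PERI": range(11, 21)})
        assert out.lost["CORE"] == [pytest.approx(2 / 4)]
        assert out.gained["CORE"] == [pytest.approx(1 / 4)]
        assert out.lost["PERI"] == [0.0]
        assert out.gained["PERI"] == [pytest.approx(1 / 2)]

    def test_gain_in_empty_region_normalized_by_one(self):
        wt = self._map([(1, 5)])
        rp = self._map([(1, 5), (12, 16), (13, 17)])
        with pytest.warns(UserWarning):
            out = region_gain_loss(wt, [rp], {"CORE": range(1, 11),
                                              "EMPTY": range(11, 21)})
        assert out.gained["EMPTY"] == [2.0]
        assert out.lost["EMPTY"] == [0.0]

    def test_straddling_contact_goes_to_interface(self):
        wt = self._map([(5, 15)])
        rp = self._map([])
        out = region_gain_loss(wt, [rp], {"A": range(1, 11),
                                          "B": range(11, 21)})
        assert out.lost["interface"] == [1.0]
        assert out.lost["A"] == [0.0] and out.lost["B"] == [0.0]


class TestSensitiveRegions:
    def test_fully_conserved_composite_is_silent(self):
        counts = {(i, i + 5): 5 for i in range(1, 15)}
        comp = CompositeMap(20, counts, 5)
        wt = ContactMap(20, frozenset(), 4.5, 3)
        assert sensitive_regions(comp, wt) == []

    def test_engineered_variable_block_is_detected(self):
        counts = {}
        for i in range(1, 35):
            counts[(i, i + 5)] = 5
        for i in range(40, 51):       # block with single-RP contacts
            counts[(i, i + 6)] = 1
        comp = CompositeMap(60, counts, 5)
        wt = ContactMap(60, frozenset(), 4.5, 3)
        segs = sensitive_regions(comp, wt)
        assert len(segs) == 1
        lo, hi = segs[0]
        assert lo >= 40 and hi <= 56
        assert hi - lo + 1 >= 3


def test_contact_file_roundtrip(hairpin_map):
    text = write_contact_file(hairpin_map)
    again = read_contact_file(text)
    assert again.pairs == hairpin_map.pairs
    assert again.n_residues == hairpin_map.n_residues
    for a, b in zip(sorted(again.contacts), sorted(hairpin_map.contacts)):
        assert a.d_ij == pytest.approx(b.d_ij, abs=1e-6)
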