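import os
import stat
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rpfold.errors import (ExternalToolFailure, InvalidAlphabet,
                           LengthMismatch)
from rpfold.repack import (RepackSettings, count_clashes, permute_sequence,
                           probe_homopolymer, repack_side_chains, _excluded)
from rpfold.structure_io import (Atom, ProteinStructure, Residue, Segment,
                                 ToySpec, extract_backbone,
                                 make_toy_structure, write_structure)
from rpfold.contacts import compute_contact_map

AA = "ACDEFGHIKLMNPQRSTVWY"
seq_strategy = st.text(alphabet=AA, min_size=1, max_size=40)


class TestPermutation:
    @given(seq=seq_strategy, seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_composition_conserved_and_deterministic(self, seq, seed):
        rec = permute_sequence(seq, seed)
        assert Counter(rec.permuted_sequence) == Counter(seq)
        assert rec.permuted_sequence == permute_sequence(seq, seed).permuted_sequence
        assert sorted(rec.mapping) == list(range(len(seq)))

    def test_homopolymer_and_singleton_invariance(self):
        assert permute_sequence("A", 99).permuted_sequence == "A"
        assert permute_sequence("AAAA", 5).permuted_sequence == "AAAA"

    def test_invalid_alphabet(self):
        with pytest.raises(InvalidAlphabet):
            permute_sequence("ABZ", 0)
        with pytest.raises(InvalidAlphabet):
            permute_sequence("", 0)


class TestRepack:
    def test_backbone_preserved_exactly(self, hairpin):
        bb = extract_backbone(hairpin)
        out = repack_side_chains(bb, "W" * bb.n_residues)
        for rb, ro in zip(bb.residues, out.residues):
            for name in ("N", "CA", "C", "O"):
                np.testing.assert_array_equal(rb.atom(name).coords,
                                              ro.atom(name).coords)

    def test_polyglycine_has_no_side_chains(self, hairpin):
        bb = extract_backbone(hairpin)
        out = repack_side_chains(bb, "G" * bb.n_residues)
        assert all(not r.sidechain_atoms() for r in out.residues)

    def test_polyalanine_cb_geometry(self, helix10):
        bb = extract_backbone(helix10)
        out = probe_homopolymer(bb, "A")
        for r in out.residues:
            sc = r.sidechain_atoms()
            assert [a.name for a in sc] == ["CB"]
            d = np.linalg.norm(sc[0].coords - r.atom("CA").coords)
            assert d == pytest.approx(1.53, abs=0.02)

    def test_isolated_tryptophan_clash_free(self):
        s = make_toy_structure(ToySpec([Segment("strand", 4, "GWGG")]), 0)
        assert count_clashes(s) == 0

    def test_length_mismatch(self, hairpin):
        bb = extract_backbone(hairpin)
        with pytest.raises(LengthMismatch):
            repack_side_chains(bb, "AAA")

    def test_deterministic(self, hairpin):
        bb = extract_backbone(hairpin)
        a = repack_side_chains(bb, "LIVEWIRELIVERV")
        b = repack_side_chains(bb, "LIVEWIRELIVERV")
        for r1, r2 in zip(a.residues, b.residues):
            for a1, a2 in zip(r1.atoms, r2.atoms):
                np.testing.assert_array_equal(a1.coords, a2.coords)

    def test_average_side_chain_size_conserved(self, balanced):
        bb = extract_backbone(balanced)
        n_wt = len(balanced.heavy_atoms())
        for seed in (1, 2, 3):
            perm = permute_sequence(balanced.sequence, seed)
            rp = repack_side_chains(bb, perm.permuted_sequence)
            assert len(rp.heavy_atoms()) == n_wt

    def test_homopolymer_probe_contact_ordering(self, hairpin):
        # small side chains floor the map; bulky ones can only add to it
        bb = extract_backbone(hairpin)
        m_ala = compute_contact_map(probe_homopolymer(bb, "A")).M
        m_trp = compute_contact_map(probe_homopolymer(bb, "W")).M
        assert m_ala <= m_trp

    def test_polygly_probe_gives_backbone_contacts(self, hairpin):
        bb = extract_backbone(hairpin)
        gly = probe_homopolymer(bb, "G")
        assert compute_contact_map(gly).pairs == compute_contact_map(
            ProteinStructure([r for r in bb.residues], "bb")).pairs


class TestCompletion:
    def test_rebuilds_only_missing_side_chains(self, hairpin):
        from rpfold.repack import complete_missing_side_chains
        from rpfold.structure_io import find_missing_atoms
        broken = hairpin.copy()
        for idx in (1, 3):
            r = broken.residues[idx - 1]
            r.atoms = r.atoms[:-1]
        assert find_missing_atoms(broken)
        fixed = complete_missing_side_chains(broken)
        assert find_missing_atoms(fixed) == []
        for r0, r1 in zip(hairpin.residues, fixed.residues):
            if r0.index in (1, 3):
                continue
            for a0, a1 in zip(r0.atoms, r1.atoms):
                np.testing.assert_array_equal(a0.coords, a1.coords)

    def test_complete_structure_is_copied_unchanged(self, hairpin):
        from rpfold.repack import complete_missing_side_chains
        out = complete_missing_side_chains(hairpin)
        for r0, r1 in zip(hairpin.residues, out.residues):
            for a0, a1 in zip(r0.atoms, r1.atoms):
                np.testing.assert_array_equal(a0.coords, a1.coords)


class TestClashCounting:
    def _cloud_structure(self, rng, n_atoms=50):
        residues = []
        per_res = 5
        for r in range(n_atoms // per_res):
            atoms = [Atom(f"X{k}", "C", rng.uniform(0, 8, 3))
                     for k in range(per_res)]
            residues.append(Residue(r + 1, "A", atoms))
        return ProteinStructure(residues, "cloud")

    def test_two_close_atoms(self):
        s = ProteinStructure([
            Residue(1, "A", [Atom("CB", "C", [0, 0, 0])]),
            Residue(2, "A", [Atom("CB", "C", [1.0, 0, 0])]),
        ], "pair")
        assert count_clashes(s, 2.5) == 1

    def test_native_hairpin_clash_free(self, hairpin):
        assert count_clashes(hairpin) == 0

    def test_matches_brute_force_on_random_clouds(self, rng):
        for _ in range(10):
            s = self._cloud_structure(rng)
            entries = [(r.index, a.name, r.aa, a.coords)
                       for r in s.residues for a in r.atoms]
            brute = 0
            for x in range(len(entries)):
                for y in range(x + 1, len(entries)):
                    ri, ni, ai, ci = entries[x]
                    rj, nj, aj, cj = entries[y]
                    if np.linalg.norm(ci - cj) < 2.5 and \
                            not _excluded(ri, ni, ai, rj, nj, aj):
                        brute += 1
            assert count_clashes(s, 2.5) == brute


class TestExternalHook:
    def _write_tool(self, tmp_path, body):
        tool = tmp_path / "fakescwrl.py"
        tool.write_text("#!/usr/bin/env python\n" + body)
        tool.chmod(tool.stat().st_mode | stat.S_IXUSR)
        return str(tool)

    def test_failing_tool_raises(self, hairpin, tmp_path):
        tool = self._write_tool(tmp_path, "import sys; sys.exit(3)\n")
        bb = extract_backbone(hairpin)
        with pytest.raises(ExternalToolFailure):
            repack_side_chains(bb, "A" * bb.n_residues,
                               RepackSettings(external_tool=tool))

    def test_valid_tool_roundtrip(self, hairpin, tmp_path):
        body = (
            "import sys\n"
            "from pathlib import Path\n"
            "from rpfold.structure_io import read_structure, write_structure, extract_backbone\n"
            "from rpfold.repack import repack_side_chains\n"
            "args = dict(zip(sys.argv[1::2], sys.argv[2::2]))\n"
            "bb = extract_backbone(read_structure(Path(args['-i']).read_text()))\n"
            "seq = Path(args['-s']).read_text().strip().upper()\n"
            "Path(args['-o']).write_text(write_structure(repack_side_chains(bb, seq)))\n"
        )
        tool = self._write_tool(tmp_path, body)
        bb = extract_backbone(hairpin)
        out = repack_side_chains(bb, "L" * bb.n_residues,
                                 RepackSettings(external_tool=tool))
        assert out.sequence == "L" * bb.n_residues
        for rb, ro in zip(bb.residues, out.residues):
            np.testing.assert_allclose(rb.atom("CA").coords,
                                       ro.atom("CA").coords, atol=5e-3)
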