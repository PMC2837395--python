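"""Lattice geometry and thermodynamics: enumeration, folding, docking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mutatorsim as ms
from mutatorsim import lattice as L


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

class TestEnumeration:
    def test_conformations_fill_the_cube(self, tiny_set):
        """Every chain visits all 27 cube sites exactly once."""
        for path in tiny_set.paths:
            assert sorted(path.tolist()) == list(range(27))

    def test_chain_connectivity(self, tiny_set):
        """Consecutive residues occupy nearest-neighbour lattice sites."""
        coords = L._COORDS
        for path in tiny_set.paths:
            steps = np.abs(np.diff(coords[path.astype(int)], axis=0)).sum(axis=1)
            assert (steps == 1).all()

    def test_contact_maps_have_28_pairs(self, tiny_set):
        """54 cube edges minus 26 chain bonds leave 28 non-bonded contacts."""
        assert tiny_set.contact_maps.shape[1:] == (28, 2)
        coords = L._COORDS
        for path, cmap in zip(tiny_set.paths[:20], tiny_set.contact_maps[:20]):
            # brute-force recount of adjacent non-bonded pairs
            n = 0
            for i in range(27):
                for j in range(i + 2, 27):
                    d = np.abs(coords[path[i]] - coords[path[j]]).sum()
                    n += d == 1
            assert n == 28
            for a, b in cmap:
                assert b > a + 1
                assert np.abs(coords[path[a]] - coords[path[b]]).sum() == 1

    def test_no_two_conformations_symmetry_related(self, tiny_set):
        """Stored chains are distinct under all 48 cube symmetries."""
        seen = set()
        for path in tiny_set.paths:
            orbit = {tuple(perm[path.astype(int)]) for perm in L._SYM_PERMS}
            assert not (orbit & seen)
            seen |= orbit

    def test_deterministic_and_sorted_order(self, tiny_set):
        again = ms.enumerate_compact_conformations(limit=200)
        assert np.array_equal(again.paths, tiny_set.paths)
        as_tuples = [tuple(p) for p in tiny_set.paths]
        assert as_tuples == sorted(as_tuples)

    def test_limit_out_of_range(self):
        with pytest.raises(L.SizeError):
            ms.enumerate_compact_conformations(limit=0)

    def test_sampling_contract(self, tiny_set):
        sub = ms.sample_structure_set(tiny_set, 50, rng_seed=7)
        assert sub.count == 50
        sub2 = ms.sample_structure_set(tiny_set, 50, rng_seed=7)
        assert np.array_equal(sub.indices, sub2.indices)
        assert np.array_equal(
            ms.sample_structure_set(tiny_set, tiny_set.count, 0).paths,
            tiny_set.paths,
        )
        with pytest.raises(L.SizeError):
            ms.sample_structure_set(tiny_set, tiny_set.count + 1, 0)


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------

class TestFold:
    def test_homopolymer_fully_degenerate(self, tiny_set, em085):
        """All conformations have equal energy: p_nat = 1/|set|, tie to 0."""
        s = ms.fold("A" * 27, tiny_set, em085)
        assert s.native_index == 0
        assert s.p_nat == pytest.approx(1 / tiny_set.count, rel=1e-9)

    def test_boltzmann_low_T_limit(self, tiny_set):
        """With a unique minimum, p_nat -> 1 as T -> 0."""
        em = ms.load_mj_energy_model(0.85)
        seq = "LIVMFWCYAHTGSQNEDKRPLIVMFWC"
        p_prev = 0.0
        for T in (2.0, 1.0, 0.5, 0.1, 0.01, 0.001):
            s = ms.fold(seq, tiny_set, em.at_temperature(T))
            assert s.p_nat >= p_prev
            p_prev = s.p_nat
        assert p_prev > 0.999

    def test_p_nat_decreases_with_temperature(self, tiny_set, em085):
        seq = "LIVMFWCYAHTGSQNEDKRPLIVMFWC"
        ps = [
            ms.fold(seq, tiny_set, em085.at_temperature(T)).p_nat
            for T in (0.5, 0.85, 1.0, 1.5, 3.0)
        ]
        assert ps == sorted(ps, reverse=True)

    def test_partition_function_against_hand_sum(self, tiny_set):
        """Three-conformation set, two-letter energy table, direct sum."""
        sub = tiny_set.subset(np.array([0, 3, 7]))
        table = np.zeros((20, 20))
        ia, ic = L.AA_ALPHABET.index("A"), L.AA_ALPHABET.index("C")
        table[ia, ia] = -1.0
        table[ia, ic] = table[ic, ia] = -0.5
        table[ic, ic] = -2.0
        em = L.EnergyModel(table, temperature=0.7)
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("AC"), 27))
        # independent oracle: explicit per-conformation energy and weights
        energies = []
        for cmap in sub.contact_maps:
            e = sum(table[L.AA_ALPHABET.index(seq[a]), L.AA_ALPHABET.index(seq[b])]
                    for a, b in cmap)
            energies.append(e)
        energies = np.array(energies)
        w = np.exp(-energies / 0.7)
        expect = w[np.argmin(energies)] / w.sum()
        s = ms.fold(seq, sub, em)
        assert s.E0 == pytest.approx(energies.min())
        assert s.native_index == int(np.argmin(energies))
        assert s.p_nat == pytest.approx(expect, rel=1e-12)

    def test_invalid_residue_rejected(self, tiny_set, em085):
        with pytest.raises(L.AlphabetError):
            ms.fold("B" * 27, tiny_set, em085)

    def test_energy_offset_gauge_invariance(self, tiny_set, em085):
        """A constant shift of the contact table leaves p_nat, the native
        state and p_int unchanged; K scales by exp(-9c/T)."""
        seq = "LIVMFWCYAHTGSQNEDKRPLIVMFWC"
        c = 1.7
        em_shift = L.EnergyModel(em085.contact_energy + c, em085.temperature)
        s1 = ms.fold(seq, tiny_set, em085)
        s2 = ms.fold(seq, tiny_set, em_shift)
        assert s2.native_index == s1.native_index
        assert s2.p_nat == pytest.approx(s1.p_nat, rel=1e-9)
        e1, p1, k1 = ms.bind(s1, s1, tiny_set, em085)
        e2, p2, k2 = ms.bind(s2, s2, tiny_set, em_shift)
        assert p2 == pytest.approx(p1, rel=1e-9)
        assert e2 == pytest.approx(e1 + 9 * c)
        assert k2 == pytest.approx(k1 * np.exp(-9 * c / 0.85), rel=1e-6)


# ---------------------------------------------------------------------------
# docking
# ---------------------------------------------------------------------------

class TestDocking:
    def test_144_modes_with_9_interface_pairs(self):
        modes = ms.enumerate_docking_modes()
        assert len(modes) == 144
        combos = {(m.face_i, m.face_j, m.rotation) for m in modes}
        assert len(combos) == 144
        for m in modes:
            assert m.interface_pairs.shape == (9, 2)
            # each side of the interface uses 9 distinct face sites
            assert len(set(m.interface_pairs[:, 0].tolist())) == 9
            assert len(set(m.interface_pairs[:, 1].tolist())) == 9

    def test_mode_list_stable_under_reinvocation(self):
        a = ms.enumerate_docking_modes()
        b = ms.enumerate_docking_modes()
        assert all(
            np.array_equal(x.interface_pairs, y.interface_pairs)
            for x, y in zip(a, b)
        )

    def test_homopolymer_pair_degenerate(self, tiny_set, em085):
        s = ms.fold("A" * 27, tiny_set, em085)
        _e, p_int, _k = ms.bind(s, s, tiny_set, em085)
        assert p_int == pytest.approx(1 / 144, rel=1e-12)

    def test_bind_symmetric_in_arguments(self, tiny_set, em085):
        s1 = ms.fold("LIVMFWCYAHTGSQNEDKRPLIVMFWC", tiny_set, em085)
        s2 = ms.fold("AAAGGGSSSTTTPPPKKKEEEDDDNNN", tiny_set, em085)
        e12 = ms.bind(s1, s2, tiny_set, em085)
        e21 = ms.bind(s2, s1, tiny_set, em085)
        assert e12[0] == pytest.approx(e21[0])
        assert e12[1] == pytest.approx(e21[1], rel=1e-9)
        assert e12[2] == pytest.approx(e21[2], rel=1e-9)

    def test_binding_against_exhaustive_mode_oracle(self, tiny_set, em085):
        """Recompute all 144 interface energies by hand from the mode
        geometry and the native-conformation occupancies."""
        rng = np.random.default_rng(11)
        seq1 = "".join(rng.choice(list("AC"), 27))
        seq2 = "".join(rng.choice(list("AC"), 27))
        s1 = ms.fold(seq1, tiny_set, em085)
        s2 = ms.fold(seq2, tiny_set, em085)
        occ1 = tiny_set.occupants[s1.native_index]
        occ2 = tiny_set.occupants[s2.native_index]
        tab = em085.contact_energy
        alpha = L.AA_ALPHABET
        energies = []
        for mode in ms.enumerate_docking_modes():
            e = 0.0
            for cell_i, cell_j in mode.interface_pairs:
                ri = alpha.index(seq1[occ1[cell_i]])
                rj = alpha.index(seq2[occ2[cell_j]])
                e += tab[ri, rj]
            energies.append(e)
        energies = np.array(energies)
        e_min, p_int, k = ms.bind(s1, s2, tiny_set, em085)
        assert e_min == pytest.approx(energies.min())
        w = np.exp(-energies / 0.85)
        assert p_int == pytest.approx(w[np.argmin(energies)] / w.sum(), rel=1e-9)
        assert k == pytest.approx(np.exp(-energies.min() / 0.85), rel=1e-9)

    def test_mode_sum_convention(self, tiny_set, em085):
        s = ms.fold("LIVMFWCYAHTGSQNEDKRPLIVMFWC", tiny_set, em085)
        spec = L.binding_mode_energies(s, s, tiny_set, em085)
        _e, _p, k = ms.bind(s, s, tiny_set, em085, k_convention="mode_sum")
        assert k == pytest.approx(np.exp(-spec / 0.85).sum(), rel=1e-9)


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_boltzmann_probabilities_proper(seed):
    """P_nat and P_int are true probabilities of full distributions."""
    tiny = ms.enumerate_compact_conformations(limit=60)
    em = ms.load_mj_energy_model(0.85)
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list(L.AA_ALPHABET), 27))
    s = ms.fold(seq, tiny, em)
    assert 0 < s.p_nat <= 1
    w = np.exp(-(s.energies - s.E0) / 0.85)
    assert s.p_nat == pytest.approx(1.0 / w.sum(), rel=1e-9)
    spec = L.binding_mode_energies(s, s, tiny, em)
    _e, p_int, _k = ms.bind(s, s, tiny, em)
    assert 0 < p_int <= 1
    wi = np.exp(-(spec - spec.min()) / 0.85)
    assert p_int == pytest.approx(1.0 / wi.sum(), rel=1e-9)
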