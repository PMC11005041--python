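"""Fingerprint computation, standardization and bit-to-atom retro-mapping."""

import numpy as np
import pytest

from toxscope import (Family, SMILESError, compute_fingerprint,
                      family_length, fingerprint_matrix, map_bits_to_atoms,
                      standardize_smiles)
from toxscope import _pubchem


class TestStandardize:
    @pytest.mark.parametrize("a,b", [
        ("C1=CC=CC=C1", "c1ccccc1"),
        ("OCC", "CCO"),
        ("C(C)O", "OCC"),
    ])
    def test_canonicalization_invariance(self, a, b):
        assert standardize_smiles(a).canonical_smiles == \
            standardize_smiles(b).canonical_smiles

    def test_roundtrip_is_stable(self):
        rec = standardize_smiles("c1ccc(O)cc1")
        again = standardize_smiles(rec.canonical_smiles)
        assert again.canonical_smiles == rec.canonical_smiles

    @pytest.mark.parametrize("bad", ["", "   ", "C(C)(C)(C)(C)C", "not-smiles"])
    def test_rejects_invalid_input(self, bad):
        with pytest.raises(SMILESError):
            standardize_smiles(bad)

    def test_error_echoes_input(self):
        with pytest.raises(SMILESError, match="xyzzy"):
            standardize_smiles("xyzzy")

    def test_salt_stripping_keeps_largest_fragment(self):
        rec = standardize_smiles("CC(=O)O.[Na+]")
        assert rec.canonical_smiles == standardize_smiles("CC(=O)O").canonical_smiles


class TestFingerprints:
    @pytest.mark.parametrize("family,length", [
        (Family.MORGAN, 1024),
        (Family.PUBCHEM, 881),
        (Family.PATH_TOPOLOGICAL, 2048),
    ])
    def test_length_contract(self, parathion, family, length):
        fp = compute_fingerprint(parathion, family)
        assert fp.length == length == family_length(family)
        assert all(0 <= b < length for b in fp.bits)

    def test_deterministic(self, parathion):
        for family in Family:
            a = compute_fingerprint(parathion, family)
            b = compute_fingerprint(standardize_smiles(
                parathion.canonical_smiles), family)
            assert a.bits == b.bits

    def test_methane_has_single_morgan_environment(self):
        # one heavy atom -> only the radius-0 environment can hash
        rec = standardize_smiles("C")
        assert len(compute_fingerprint(rec, Family.MORGAN).bits) == 1

    def test_matrix_matches_individual_vectors(self, toluene, benzene):
        X = fingerprint_matrix([toluene, benzene], Family.MORGAN)
        assert X.shape == (2, 1024)
        assert set(np.flatnonzero(X[0])) == \
            set(compute_fingerprint(toluene, Family.MORGAN).bits)


class TestBitAtomMaps:
    def test_family_mismatch_rejected(self, toluene):
        fp = compute_fingerprint(toluene, Family.MORGAN)
        with pytest.raises(ValueError):
            map_bits_to_atoms(toluene, Family.PUBCHEM, fp)

    def test_morgan_covers_every_heavy_atom(self, parathion):
        # radius-0 environments exist for every atom
        fp = compute_fingerprint(parathion, Family.MORGAN)
        bam = map_bits_to_atoms(parathion, Family.MORGAN, fp)
        covered = {a for occs in bam.entries.values()
                   for occ in occs for a in occ}
        assert covered == set(range(parathion.n_atoms))

    def test_atom_indices_in_range(self, parathion):
        for family in Family:
            fp = compute_fingerprint(parathion, family)
            bam = map_bits_to_atoms(parathion, family, fp)
            for occs in bam.entries.values():
                assert len(occs) >= 1
                for occ in occs:
                    assert all(0 <= a < parathion.n_atoms for a in occ)

    def test_benzene_ring_bits_map_to_all_six_carbons(self, benzene):
        fp = compute_fingerprint(benzene, Family.PUBCHEM)
        bam = map_bits_to_atoms(benzene, Family.PUBCHEM, fp)
        lo, hi = _pubchem.RING_SECTION
        ring_bits = [b for b in bam.entries if lo <= b < hi]
        assert ring_bits
        for b in ring_bits:
            for occ in bam.entries[b]:
                assert sorted(occ) == list(range(6))

    def test_pubchem_occurrence_counts_match_substructure_matches(self):
        # two hydroxyl oxygens -> the ">=1 oxygen" bit has two singleton
        # occurrences, one per matching atom
        rec = standardize_smiles("OCCO")
        fp = compute_fingerprint(rec, Family.PUBCHEM)
        bam = map_bits_to_atoms(rec, Family.PUBCHEM, fp)
        defs = _pubchem.bit_definitions()
        o_bits = [i for i, d in enumerate(defs)
                  if d.kind == "element" and d.anum == 8 and d.min_count == 1]
        (bit,) = o_bits
        assert bam.n_occ(bit) == 2
        assert all(len(occ) == 1 for occ in bam.entries[bit])

    def test_pubchem_bit_definitions_are_well_formed(self):
        defs = _pubchem.bit_definitions()
        assert len(defs) == 881
        clusters = _pubchem.ring_bit_clusters()
        covered = sorted(b for bits in clusters.values() for b in bits)
        assert covered == list(range(115, 263))
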