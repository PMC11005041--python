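"""Shapley attribution against an exact enumeration oracle, and the
atom retro-mapping arithmetic."""

import itertools
import math

import numpy as np
import pytest

from toxscope import (AtomWeightMap, Family, FeatureScoreVector,
                      aggregate_over_models, atom_weights, cluster_ring_bits,
                      kernel_shap, render_atom_weights, standardize_smiles)
from toxscope import _pubchem
from toxscope.fingerprints import BitAtomMap


def exact_shapley(f, x, background):
    """Brute-force Shapley values of v(S) = E_b f(x_S, b_!S) by subset
    enumeration; independent of the kernel-regression path."""
    x = np.asarray(x, dtype=float)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    d = x.size
    varying = [j for j in range(d) if np.any(background[:, j] != x[j])]
    m = len(varying)
    cache = {}

    def v(subset):
        key = frozenset(subset)
        if key not in cache:
            rows = background.copy()
            cols = [varying[i] for i in subset]
            rows[:, cols] = x[cols]
            cache[key] = float(f(rows).mean())
        return cache[key]

    phi = np.zeros(d)
    for i in range(m):
        others = [j for j in range(m) if j != i]
        total = 0.0
        for s in range(m):
            w = math.factorial(s) * math.factorial(m - s - 1) / math.factorial(m)
            for subset in itertools.combinations(others, s):
                total += w * (v(subset + (i,)) - v(subset))
        phi[varying[i]] = total
    return phi


def _toy_model(d, seed=0, interaction=0.5):
    rng = np.random.default_rng(seed)
    w = rng.normal(scale=1.5, size=d)

    def f(X):
        X = np.atleast_2d(X)
        z = X @ w + interaction * X[:, 0] * X[:, 1] - 0.3
        return 1.0 / (1.0 + np.exp(-z))

    return f


class TestKernelShap:
    def test_matches_exact_enumeration_oracle(self):
        d = 10
        f = _toy_model(d, seed=1)
        rng = np.random.default_rng(2)
        x = np.ones(d)
        background = rng.integers(0, 2, size=(8, d)).astype(float)
        phi, base, fx = kernel_shap(f, x, background, seed=0)
        oracle = exact_shapley(f, x, background)
        assert np.abs(phi - oracle).max() < 1e-2
        assert abs(fx - base - phi.sum()) < 1e-8

    def test_sampling_path_approximates_oracle(self):
        d = 12
        f = _toy_model(d, seed=3, interaction=0.3)
        x = np.ones(d)
        rng = np.random.default_rng(4)
        background = rng.integers(0, 2, size=(6, d)).astype(float)
        phi, base, fx = kernel_shap(f, x, background, seed=7,
                                    n_samples=2500, max_exact_features=5)
        oracle = exact_shapley(f, x, background)
        assert np.abs(phi - oracle).max() < 1e-2
        # local accuracy is enforced by construction
        assert abs(fx - base - phi.sum()) < 1e-8

    def test_constant_model_gets_zero_scores(self):
        f = lambda X: np.full(np.atleast_2d(X).shape[0], 0.7)
        phi, base, fx = kernel_shap(f, np.ones(6), np.zeros((3, 6)), seed=0)
        assert np.abs(phi).max() < 1e-10

    def test_single_bit_stump_carries_full_mass(self):
        k = 3

        def stump(X):
            return np.where(np.atleast_2d(X)[:, k] >= 0.5, 0.9, 0.2)

        x = np.zeros(8)
        x[k] = 1
        x[5] = 1  # a second on-bit the model ignores
        phi, base, fx = kernel_shap(stump, x, np.zeros((4, 8)), seed=0)
        assert phi[k] == pytest.approx(fx - base, abs=1e-10)
        assert abs(phi[5]) < 1e-10

    def test_non_varying_features_score_zero(self):
        d = 6
        f = _toy_model(d, seed=5)
        x = np.array([1, 0, 1, 1, 0, 1], dtype=float)
        background = np.tile(x, (3, 1))
        background[:, 2] = 0  # only feature 2 varies
        phi, base, fx = kernel_shap(f, x, background, seed=0)
        assert np.flatnonzero(phi).tolist() == [2]


class TestRingBitClustering:
    def _fsv(self, scores881):
        return FeatureScoreVector(model_id="RF_PUBCHEM", family=Family.PUBCHEM,
                                  scores=scores881, base=0.3, ps=0.8)

    def test_keeps_only_max_score_per_cluster(self):
        clusters = _pubchem.ring_bit_clusters()
        bits = next(b for b in clusters.values() if len(b) >= 3)
        b1, b2, b3 = bits[0], bits[1], bits[-1]
        scores = np.zeros(881)
        scores[b1], scores[b2], scores[b3] = 0.2, 0.5, 0.1
        out = cluster_ring_bits(self._fsv(scores))
        assert out.scores[b2] == 0.5
        assert out.scores[b1] == 0.0 and out.scores[b3] == 0.0

    def test_tie_keeps_lowest_bit_index(self):
        clusters = _pubchem.ring_bit_clusters()
        bits = next(iter(clusters.values()))
        scores = np.zeros(881)
        scores[bits[0]] = scores[bits[1]] = 0.4
        out = cluster_ring_bits(self._fsv(scores))
        assert out.scores[bits[0]] == 0.4 and out.scores[bits[1]] == 0.0

    def test_non_ring_bits_untouched(self):
        scores = np.zeros(881)
        scores[3], scores[500] = 0.7, -0.2
        out = cluster_ring_bits(self._fsv(scores))
        assert out.scores[3] == 0.7 and out.scores[500] == -0.2

    def test_other_families_pass_through(self):
        fsv = FeatureScoreVector(model_id="RF_MORGAN", family=Family.MORGAN,
                                 scores=np.ones(1024), base=0.0, ps=1.0)
        assert cluster_ring_bits(fsv) is fsv


class TestAtomWeights:
    def _scores(self, mapping, length=1024):
        s = np.zeros(length)
        for bit, val in mapping.items():
            s[bit] = val
        return FeatureScoreVector(model_id="RF_MORGAN", family=Family.MORGAN,
                                  scores=s, base=0.2, ps=0.9)

    def test_single_feature_two_atoms_one_occurrence(self):
        rec = standardize_smiles("CCO")
        bam = BitAtomMap(Family.MORGAN, {10: [(0, 1)]})
        aw = atom_weights(rec, bam, self._scores({10: 0.30}))
        assert aw.weights[0] == pytest.approx(0.15)
        assert aw.weights[1] == pytest.approx(0.15)
        assert aw.weights[2] == 0.0

    def test_two_occurrences_scale_by_n_occ(self):
        rec = standardize_smiles("OCCCO")
        bam = BitAtomMap(Family.MORGAN, {10: [(0, 1), (3, 4)]})
        aw = atom_weights(rec, bam, self._scores({10: 0.30}))
        for a in (0, 1, 3, 4):
            assert aw.weights[a] == pytest.approx(0.075)

    def test_overlapping_features_add(self):
        rec = standardize_smiles("CCO")
        bam = BitAtomMap(Family.MORGAN, {1: [(0, 1)], 2: [(1, 2)]})
        aw = atom_weights(rec, bam, self._scores({1: 0.2, 2: 0.4}))
        assert aw.weights[1] == pytest.approx(0.1 + 0.2)
        assert aw.provenance[1] == (1, 2)

    def test_conservation_for_disjoint_single_occurrence_features(self):
        rec = standardize_smiles("CCOCC")
        bam = BitAtomMap(Family.MORGAN, {1: [(0, 1)], 2: [(2,)], 3: [(3, 4)]})
        scores = {1: 0.25, 2: -0.1, 3: 0.05}
        aw = atom_weights(rec, bam, self._scores(scores))
        assert aw.weights.sum() == pytest.approx(sum(scores.values()))

    def test_sign_preserved_for_purely_positive_features(self):
        rec = standardize_smiles("CCO")
        bam = BitAtomMap(Family.MORGAN, {1: [(0, 1)], 2: [(0,)]})
        aw = atom_weights(rec, bam, self._scores({1: 0.2, 2: 0.3}))
        assert (aw.weights >= 0).all()

    def test_family_mismatch_rejected(self):
        rec = standardize_smiles("CCO")
        bam = BitAtomMap(Family.PUBCHEM, {1: [(0,)]})
        with pytest.raises(ValueError):
            atom_weights(rec, bam, self._scores({1: 0.2}))


class TestAggregateAndRender:
    def _map(self, weights):
        return AtomWeightMap(canonical_smiles="CCO",
                             weights=np.asarray(weights, dtype=float),
                             provenance={})

    def test_mean_of_opposite_weights_is_zero(self):
        agg = aggregate_over_models([self._map([0.2, 0, 0]),
                                     self._map([-0.2, 0, 0])])
        assert agg.weights[0] == 0.0
        assert agg.n_models == 2

    def test_single_map_identity(self):
        m = self._map([0.1, 0.2, 0.3])
        agg = aggregate_over_models([m])
        assert np.array_equal(agg.weights, m.weights)

    def test_molecule_mismatch_rejected(self):
        other = AtomWeightMap("CCC", np.zeros(3), {})
        with pytest.raises(ValueError):
            aggregate_over_models([self._map([0, 0, 0]), other])

    def test_render_zero_map_produces_svg(self, tmp_path):
        rec = standardize_smiles("CCO")
        out = tmp_path / "mol.svg"
        doc = render_atom_weights(
            rec, AtomWeightMap(rec.canonical_smiles, np.zeros(3), {}),
            path=out)
        assert "<svg" in doc
        assert out.exists()

    def test_render_signed_weights(self):
        rec = standardize_smiles("CCO")
        doc = render_atom_weights(
            rec, AtomWeightMap(rec.canonical_smiles,
                               np.array([0.4, -0.2, 0.0]), {}))
        assert "<svg" in doc
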