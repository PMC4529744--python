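import numpy as np
import pytest
from scipy import stats

from messi.variant_association import (
    KinshipMatrix,
    filter_variants,
    kinship,
    mixed_model_scan,
    permutation_adjust,
)

from conftest import make_genotypes


class TestFilterVariants:
    def test_singleton_at_21_strains_removed(self, rng):
        g = np.zeros((1, 21), dtype=int)
        g[0, 3] = 1  # AF = 1/21 ~ 0.048 < 0.05
        gm = filter_variants(make_genotypes(g), min_af=0.05)
        assert gm.n_variants == 0

    def test_doubleton_at_21_strains_kept(self):
        g = np.zeros((1, 21), dtype=int)
        g[0, [3, 7]] = 1  # AF ~ 0.095
        gm = filter_variants(make_genotypes(g), min_af=0.05)
        assert gm.n_variants == 1

    def test_near_fixed_variant_removed(self):
        g = np.ones((1, 21), dtype=int)
        g[0, 0] = 0  # presence 20/21 > 0.95
        assert filter_variants(make_genotypes(g)).n_variants == 0

    def test_effect_class_filter(self):
        g = np.tile([0, 1, 0, 1, 1, 0], (3, 1))
        gm = make_genotypes(g, effects=["missense", "upstream", "missense"])
        out = filter_variants(gm, min_af=0.05, effect_classes={"missense"})
        assert out.n_variants == 2
        assert all(v.effect_class == "missense" for v in out.variants)

    def test_empty_result_warns_not_raises(self, caplog):
        g = np.zeros((1, 21), dtype=int)
        g[0, 0] = 1
        with caplog.at_level("WARNING"):
            out = filter_variants(make_genotypes(g))
        assert out.n_variants == 0
        assert "removed every variant" in caplog.text


class TestKinship:
    def test_identical_strains_full_similarity(self):
        gm = make_genotypes([[0, 0, 1], [1, 1, 0]])
        K = kinship(gm).K
        assert np.isclose(K[0, 1], 1.0)

    def test_opposite_strains_zero_similarity(self):
        gm = make_genotypes([[0, 1], [1, 0]])
        assert np.isclose(kinship(gm).K[0, 1], 0.0)

    def test_ibs_fraction(self):
        gm = make_genotypes([[0, 0], [0, 1], [1, 1], [1, 0]])
        assert np.isclose(kinship(gm).K[0, 1], 0.5)

    def test_psd_and_unit_diagonal(self, rng):
        gm = make_genotypes(rng.integers(0, 2, size=(30, 10)))
        K = kinship(gm).K
        assert np.allclose(np.diag(K), 1.0)
        assert np.linalg.eigvalsh(K).min() > -1e-10

    def test_single_variant_rejected(self):
        with pytest.raises(ValueError):
            kinship(make_genotypes([[0, 1]]))


class TestMixedModelScan:
    def test_identity_kinship_reduces_to_ols(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 11))
            g = rng.integers(0, 2, size=(1, n))
            while len(np.unique(g)) < 2:
                g = rng.integers(0, 2, size=(1, n))
            y = rng.standard_normal(n)
            gm = make_genotypes(g)
            res = mixed_model_scan(y, gm, KinshipMatrix(np.eye(n)))
            ols = stats.linregress(g[0].astype(float), y)
            assert abs(res[0].p_value - ols.pvalue) < 1e-6

    def test_planted_effect_attains_min_p(self, rng):
        n = 21
        G = rng.integers(0, 2, size=(30, n))
        y = G[13].astype(float) + rng.normal(scale=0.2, size=n)
        gm = make_genotypes(G)
        K = kinship(gm)
        res = mixed_model_scan(y, gm, K)
        best = min(res, key=lambda a: a.p_value)
        assert best.variant_key == gm.variants[13].key

    def test_genotype_flip_negates_beta_keeps_p(self, rng):
        n = 12
        G = rng.integers(0, 2, size=(5, n))
        y = rng.standard_normal(n)
        gm1 = make_genotypes(G)
        K = kinship(gm1)
        G2 = G.copy()
        G2[2] = 1 - G2[2]
        gm2 = make_genotypes(G2)
        r1 = mixed_model_scan(y, gm1, K)
        r2 = mixed_model_scan(y, gm2, K)
        assert np.isclose(r1[2].beta, -r2[2].beta, atol=1e-8)
        assert np.isclose(r1[2].p_value, r2[2].p_value, atol=1e-8)

    def test_monomorphic_variant_skipped(self, rng):
        G = np.vstack([np.zeros(8, dtype=int), rng.integers(0, 2, size=(2, 8))])
        gm = make_genotypes(G)
        res = mixed_model_scan(rng.standard_normal(8), gm, KinshipMatrix(np.eye(8)))
        keys = {a.variant_key for a in res}
        assert gm.variants[0].key not in keys

    def test_missing_genotype_strainwise_exclusion(self, rng):
        n = 10
        g = rng.integers(0, 2, size=n)
        g_missing = g.copy()
        g_missing[4] = -1
        gm = make_genotypes(np.vstack([g_missing, g, 1 - g]))
        y = rng.standard_normal(n)
        res = mixed_model_scan(y, gm, KinshipMatrix(np.eye(n)))
        keep = np.arange(n) != 4
        ols = stats.linregress(g[keep].astype(float), y[keep])
        assert abs(res[0].p_value - ols.pvalue) < 1e-6


class TestPermutationAdjust:
    def _setup(self, rng, n=10, m=4):
        G = rng.integers(0, 2, size=(m, n))
        while any(len(np.unique(r)) < 2 for r in G):
            G = rng.integers(0, 2, size=(m, n))
        gm = make_genotypes(G)
        return gm, kinship(gm)

    def test_extreme_observation_gets_floor(self, rng):
        gm, K = self._setup(rng)
        y = gm.presence[0].astype(float) * 10  # perfect separation
        adj = permutation_adjust(y, gm, K, n_permutations=99, seed=5)
        # observed P beaten by none of the 99 permutations -> 1/100
        assert adj[0] == pytest.approx(1 / 100)

    def test_adjusted_p_at_most_one(self, rng):
        gm, K = self._setup(rng)
        y = rng.standard_normal(10)
        adj = permutation_adjust(y, gm, K, n_permutations=19, seed=5)
        assert np.nanmax(adj) <= 1.0
        assert np.nanmin(adj) >= 1 / 20

    def test_deterministic_under_seed(self, rng):
        gm, K = self._setup(rng)
        y = rng.standard_normal(10)
        a1 = permutation_adjust(y, gm, K, n_permutations=29, seed=11)
        a2 = permutation_adjust(y, gm, K, n_permutations=29, seed=11)
        assert np.array_equal(a1, a2, equal_nan=True)

    def test_zero_permutations_rejected(self, rng):
        gm, K = self._setup(rng)
        with pytest.raises(ValueError):
            permutation_adjust(np.zeros(10), gm, K, n_permutations=0)

    def test_family_wise_at_least_pointwise(self, rng):
        gm, K = self._setup(rng, n=12, m=6)
        y = rng.standard_normal(12)
        pw = permutation_adjust(y, gm, K, n_permutations=49, seed=3)
        fw = permutation_adjust(y, gm, K, n_permutations=49, seed=3, family_wise=True)
        ok = ~np.isnan(pw)
        assert (fw[ok] >= pw[ok] - 1e-12).all()
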