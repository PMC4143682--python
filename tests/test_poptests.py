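import numpy as np
import pytest
from scipy import stats

from regassoc.pedigree import PedigreeSet, Person, kinship
from regassoc.poptests import (
    KernelSpec,
    NullModel,
    _kernel_matrix,
    gcta_region_test,
    genotype_pcs,
    region_grm,
    select_unrelated,
    skat_test,
)
from tests.conftest import make_gm


def random_cohort(rng, n=150, m=8, maf_low=0.05, maf_high=0.4):
    mafs = rng.uniform(maf_low, maf_high, m)
    G = rng.binomial(2, mafs, size=(n, m)).astype(float)
    return make_gm(G)


class TestSkat:
    def test_single_marker_reduces_to_chi2_score_test(self, rng):
        gm = random_cohort(rng, n=200, m=1, maf_low=0.2)
        y = rng.standard_normal(200) + 0.3 * gm.dosages[:, 0]
        cov = rng.standard_normal(200)
        res = skat_test(gm, y, covariates=cov, kernel_spec=KernelSpec(weight_params=(1.0, 1.0)))
        # independent score-test oracle from the projection algebra
        X = np.column_stack([np.ones(200), cov])
        P0 = np.eye(200) - X @ np.linalg.inv(X.T @ X) @ X.T
        r = P0 @ y
        g = gm.dosages[:, 0]
        sigma2 = (r @ r) / (200 - 2)
        z2 = (r @ g) ** 2 / (sigma2 * (g @ P0 @ g))
        assert res.p_value == pytest.approx(stats.chi2.sf(z2, df=1), rel=1e-8)

    def test_weighting_is_scale_free_for_single_marker(self, rng):
        gm = random_cohort(rng, n=120, m=1)
        y = rng.standard_normal(120)
        p1 = skat_test(gm, y, kernel_spec=KernelSpec(weight_params=(1.0, 1.0))).p_value
        p2 = skat_test(gm, y, kernel_spec=KernelSpec(weight_params=(1.0, 25.0))).p_value
        assert p1 == pytest.approx(p2, rel=1e-8)

    def test_detects_strong_region_signal(self, rng):
        gm = random_cohort(rng, n=300, m=5)
        y = rng.standard_normal(300) + 0.4 * gm.dosages.sum(axis=1)
        # flat weights: the default Beta(1,25) deliberately downweights the
        # common variants that carry this signal
        res = skat_test(gm, y, kernel_spec=KernelSpec(weight_params=(1.0, 1.0)))
        assert res.p_value < 1e-4

    def test_null_p_not_extreme(self, rng):
        gm = random_cohort(rng, n=300, m=5)
        y = rng.standard_normal(300)
        assert skat_test(gm, y).p_value > 0.001

    def test_monomorphic_markers_skipped(self, rng):
        from regassoc.fbat import RegionSkipped

        gm = make_gm(np.zeros((50, 2)))
        with pytest.raises(RegionSkipped):
            skat_test(gm, rng.standard_normal(50))

    def test_missing_dosages_mean_imputed(self, rng):
        gm = random_cohort(rng, n=100, m=3)
        gm.dosages[0, 0] = np.nan
        res = skat_test(gm, rng.standard_normal(100))
        assert np.isfinite(res.p_value)

    @pytest.mark.parametrize("kind", ["linear_weighted", "IBS", "gaussian"])
    def test_kernels_are_symmetric_psd(self, rng, kind):
        gm = random_cohort(rng, n=60, m=6)
        G = gm.dosages
        maf = G.mean(axis=0) / 2
        K = _kernel_matrix(G, maf, KernelSpec(kind=kind))
        assert np.allclose(K, K.T)
        w = np.linalg.eigvalsh(K)
        assert w.min() >= -1e-8 * max(abs(w).max(), 1.0)


class TestGcta:
    def test_recovers_genetic_variance_share(self, rng):
        # y = Z gamma + e with sigma_g^2 = 0.3 of unit total variance
        n, m, h2 = 400, 30, 0.3
        est = []
        for _ in range(8):
            gm = random_cohort(rng, n=n, m=m, maf_low=0.1)
            A = region_grm(gm.dosages)
            p = gm.dosages.mean(axis=0) / 2
            Z = (gm.dosages - 2 * p) / np.sqrt(2 * p * (1 - p))
            gamma = rng.normal(0, np.sqrt(h2 / m), m)
            y = Z @ gamma + rng.normal(0, np.sqrt(1 - h2), n)
            est.append(gcta_region_test(gm, y).sigma2_g)
        assert np.mean(est) == pytest.approx(h2, abs=0.12)

    def test_null_fit_small_lrt(self, rng):
        gm = random_cohort(rng, n=300, m=10)
        res = gcta_region_test(gm, rng.standard_normal(300))
        assert res.lrt >= 0.0
        assert res.p_value > 0.01
        assert res.sigma2_g >= 0.0 and res.sigma2_e > 0.0

    def test_flat_likelihood_when_grm_is_zero(self):
        # degenerate region relatedness: LRT must vanish and p = 1
        from regassoc.poptests import _reml_profile

        rng = np.random.default_rng(0)
        n = 50
        lam = np.zeros(n)
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        ll0 = _reml_profile(0.0, lam, y, X)
        ll5 = _reml_profile(0.5, lam, y, X)
        assert ll5 <= ll0 + 1e-9

    def test_strong_signal_small_p(self, rng):
        gm = random_cohort(rng, n=300, m=10)
        y = 0.5 * gm.dosages.sum(axis=1) + rng.standard_normal(300)
        assert gcta_region_test(gm, y).p_value < 1e-3

    def test_lrt_nonnegative_and_h2_in_range(self, rng):
        gm = random_cohort(rng, n=150, m=5)
        res = gcta_region_test(gm, rng.standard_normal(150))
        assert 0.0 <= res.h2 < 1.0


class TestGenotypePcs:
    def test_two_subpopulations_separate_on_pc1(self, rng):
        from sklearn.metrics import silhouette_score

        n_half, m = 60, 40
        p1, p2 = rng.uniform(0.1, 0.3, m), rng.uniform(0.4, 0.5, m)
        G = np.vstack(
            [rng.binomial(2, p1, (n_half, m)), rng.binomial(2, p2, (n_half, m))]
        ).astype(float)
        pcs = genotype_pcs(make_gm(G), 2)
        labels = np.repeat([0, 1], n_half)
        assert silhouette_score(pcs[:, :1], labels) > 0.5

    def test_k_zero_empty_block(self, rng):
        gm = random_cohort(rng, n=20, m=5)
        assert genotype_pcs(gm, 0).shape == (20, 0)

    def test_duplicated_samples_identical_coordinates(self, rng):
        gm = random_cohort(rng, n=30, m=10)
        D = np.vstack([gm.dosages, gm.dosages[:1]])
        pcs = genotype_pcs(make_gm(D), 2)
        np.testing.assert_allclose(pcs[0], pcs[-1], atol=1e-8)

    def test_k_beyond_rank_warns_and_truncates(self, rng):
        G = np.tile(rng.binomial(2, 0.3, (10, 1)).astype(float), (1, 4))
        with pytest.warns(UserWarning, match="rank"):
            pcs = genotype_pcs(make_gm(G), 3)
        assert pcs.shape[1] == 1

    def test_sign_convention_deterministic(self, rng):
        gm = random_cohort(rng, n=40, m=12)
        a = genotype_pcs(gm, 3)
        b = genotype_pcs(gm, 3)
        np.testing.assert_array_equal(a, b)


class TestSelectUnrelated:
    def test_trio_founders(self):
        from regassoc.simulate import make_pedigrees

        ped = make_pedigrees("trio", 20)
        founders = select_unrelated(ped, "founders_only")
        assert len(founders) == 40
        greedy = select_unrelated(ped, "max_unrelated_greedy")
        assert len(greedy) == 40  # founders across pedigrees are unrelated

    def test_greedy_matches_exhaustive_on_small_pedigree(self):
        ped = PedigreeSet(
            [
                Person("F", "gf", sex=1),
                Person("F", "gm", sex=2),
                Person("F", "p1", father="gf", mother="gm", sex=1),
                Person("F", "p2", father="gf", mother="gm", sex=2),
                Person("F", "s1", sex=2),
                Person("F", "s2", sex=1),
                Person("F", "k1", father="p1", mother="s1"),
                Person("F", "k2", father="s2", mother="p2"),
            ]
        )
        km = kinship(ped)
        chosen = select_unrelated(ped, "max_unrelated_greedy")
        for a in chosen:
            for b in chosen:
                if a != b:
                    assert km.coeff(a, b) == 0.0
        # exhaustive maximum independent set in the kinship graph
        ids = km.ids
        best = 0
        for mask in range(1 << len(ids)):
            sub = [i for i in range(len(ids)) if mask >> i & 1]
            if all(km.phi[a, b] == 0 for ai, a in enumerate(sub) for b in sub[ai + 1:]):
                best = max(best, len(sub))
        assert len(chosen) == best

    def test_empty_pedigree_set(self):
        assert select_unrelated(PedigreeSet([]), "founders_only") == []


class TestNullModel:
    def test_residuals_orthogonal_to_covariates(self, rng):
        y = rng.standard_normal(80)
        cov = rng.standard_normal((80, 2))
        nm = NullModel.fit(y, cov)
        assert np.abs(nm.X.T @ nm.residuals).max() < 1e-8
        assert nm.sigma2 > 0
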