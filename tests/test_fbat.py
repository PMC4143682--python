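from itertools import product

import numpy as np
import pytest

from regassoc.fbat import (
    RegionSkipped,
    build_region_scores,
    conditional_distribution,
    empirical_variance,
    fbat_l,
    fbat_lmm,
    fbat_m,
    fbat_v,
)
from regassoc.pedigree import PedigreeSet, Person
from tests.conftest import make_gm


def enumeration_oracle(f, m):
    """Offspring dosage distribution by exhaustive transmission enumeration.

    Each parental dosage corresponds to an unordered allele pair; every
    (paternal allele, maternal allele) transmission combination is equally
    likely.
    """
    alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    probs = np.zeros(3)
    for a, b in product(alleles[f], alleles[m]):
        probs[a + b] += 0.25
    mean = sum(k * probs[k] for k in range(3))
    var = sum(k * k * probs[k] for k in range(3)) - mean**2
    return probs, mean, var


def sibship_pedset(n_fam, n_sibs):
    persons = []
    for i in range(n_fam):
        fid = f"F{i}"
        persons += [Person(fid, f"{fid}_f", sex=1), Person(fid, f"{fid}_m", sex=2)]
        persons += [
            Person(fid, f"{fid}_c{j}", father=f"{fid}_f", mother=f"{fid}_m")
            for j in range(n_sibs)
        ]
    return PedigreeSet(persons)


def trio_scores(parent_dosages, child_dosages, traits, n_markers=1):
    """Scores for independent trios; each dosage entry is a marker vector."""
    ped = sibship_pedset(len(traits), 1)
    rows, samples, tmap = [], [], {}
    for i, ((fd, md), cd, t) in enumerate(zip(parent_dosages, child_dosages, traits)):
        fid = f"F{i}"
        samples += [f"{fid}_f", f"{fid}_m", f"{fid}_c0"]
        rows += [np.atleast_1d(fd), np.atleast_1d(md), np.atleast_1d(cd)]
        tmap[f"{fid}_c0"] = t
    gm = make_gm(np.vstack(rows), samples=samples)
    return build_region_scores(gm, ped, tmap, center_trait_warn=False)


class TestConditionalDistribution:
    @pytest.mark.parametrize("f,m", list(product([0, 1, 2], repeat=2)))
    def test_matches_enumeration_exactly(self, f, m):
        probs, mean, var = conditional_distribution(f, m)
        eprobs, emean, evar = enumeration_oracle(f, m)
        np.testing.assert_array_equal(probs, eprobs)
        assert mean == emean and var == evar

    def test_het_by_het_and_het_by_hom(self):
        probs, mean, var = conditional_distribution(1, 1)
        np.testing.assert_array_equal(probs, [0.25, 0.5, 0.25])
        assert (mean, var) == (1.0, 0.5)
        probs, mean, var = conditional_distribution(0, 1)
        np.testing.assert_array_equal(probs, [0.5, 0.5, 0.0])
        assert (mean, var) == (0.5, 0.25)

    def test_hom_by_hom_noninformative(self):
        probs, mean, var = conditional_distribution(0, 0)
        np.testing.assert_array_equal(probs, [1.0, 0.0, 0.0])
        assert var == 0.0

    def test_missing_parent_sentinel(self):
        probs, mean, var = conditional_distribution(None, 1)
        assert probs is None and np.isnan(mean)


class TestFamilyScores:
    def test_single_trio_analytic(self):
        sc = trio_scores([(1, 1), (0, 0)], [2, 0], [1.0, 0.5])
        # second trio is noninformative (hom x hom) and contributes nothing
        assert sc.n_informative_families == 1
        assert sc.U.sum() == pytest.approx(1.0)   # 1 * (2 - 1)
        assert sc.Vdiag.sum() == pytest.approx(0.5)

    def test_trait_sign_equivariance(self):
        up = trio_scores([(1, 1)] * 2, [2, 0], [1.0, 1.0])
        dn = trio_scores([(1, 1)] * 2, [2, 0], [-1.0, -1.0])
        assert up.U.sum() == -dn.U.sum()
        assert fbat_v(up).statistic == pytest.approx(-fbat_v(dn).statistic)
        assert fbat_v(up).p_value == pytest.approx(fbat_v(dn).p_value)

    def test_two_sibs_cancel(self):
        ped = sibship_pedset(1, 2)
        gm = make_gm(
            np.array([[1.0], [1.0], [2.0], [0.0]]),
            samples=["F0_f", "F0_m", "F0_c0", "F0_c1"],
        )
        sc = build_region_scores(gm, ped, {"F0_c0": 1.0, "F0_c1": 1.0}, center_trait_warn=False)
        assert sc.U.sum() == pytest.approx(0.0)  # (2-1) + (0-1)

    def test_missing_offspring_genotype_contributes_nothing(self):
        sc = trio_scores([(1, 1), (1, 1)], [np.nan, 2], [1.0, 1.0])
        assert sc.U.sum() == pytest.approx(1.0)

    def test_mendel_violation_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="Mendelian"):
            sc = trio_scores([(0, 0), (1, 1)], [2, 2], [1.0, 1.0])
        assert sc.U.sum() == pytest.approx(1.0)  # only the consistent trio scores

    def test_monomorphic_region_skipped(self):
        with pytest.raises(RegionSkipped):
            trio_scores([(0, 0)], [0], [1.0])

    def test_uncentered_trait_warns_and_centers(self):
        ped = sibship_pedset(2, 1)
        gm = make_gm(
            np.array([[1.0], [1.0], [2.0], [1.0], [1.0], [0.0]]),
            samples=["F0_f", "F0_m", "F0_c0", "F1_f", "F1_m", "F1_c0"],
        )
        with pytest.warns(UserWarning, match="centering"):
            sc = build_region_scores(gm, ped, {"F0_c0": 3.0, "F1_c0": 1.0})
        # centered traits are (+1, -1)
        np.testing.assert_allclose(sc.U[:, 0], [1.0, 1.0])


class TestEmpiricalVariance:
    def test_zero_scores_zero_matrix(self):
        V = empirical_variance(np.zeros((4, 2)), aggregate_by_pedigree=False)
        np.testing.assert_array_equal(V, np.zeros((2, 2)))

    def test_pedigree_aggregation_vs_independent(self):
        # two families per pedigree, each with score +1: a pedigree
        # contributes (1+1)^2 = 4, against 1^2 + 1^2 = 2 if families were
        # wrongly treated as independent
        U = np.ones((4, 1))
        same_ped = empirical_variance(U, True, ped_codes=[0, 0, 1, 1])
        indep = empirical_variance(U, False)
        assert same_ped[0, 0] == pytest.approx(8.0)
        assert indep[0, 0] == pytest.approx(4.0)

    def test_single_pedigree_is_an_error(self):
        with pytest.raises(ValueError, match="2 aggregation units"):
            empirical_variance(np.ones((3, 1)), True, ped_codes=[0, 0, 0])

    def test_converges_to_model_variance_on_independent_trios(self, rng):
        # under the null with independent families the two estimators agree
        n = 3000
        parents = [(1, 1)] * n
        kids = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=n)
        traits = rng.standard_normal(n)
        traits -= traits.mean()
        sc = trio_scores(parents, kids, traits)
        emp = empirical_variance(sc)[0, 0]
        model = sc.Vdiag.sum()
        assert emp / model == pytest.approx(1.0, abs=0.08)


class TestRegionTests:
    def test_fbat_v_trio_z_and_p(self):
        sc = trio_scores([(1, 1)], [2], [1.0])
        res = fbat_v(sc)
        assert res.statistic == pytest.approx(1.0 / np.sqrt(0.5), abs=1e-4)
        assert res.p_value == pytest.approx(0.1573, abs=2e-4)

    def test_fbat_v_zero_variance_diagnostic(self):
        sc = trio_scores([(1, 1)], [2], [1.0])
        sc.Vdiag[:] = 0.0
        res = fbat_v(sc, "model")
        assert np.isnan(res.statistic) and "diagnostic" in res.extras

    def test_fbat_m_single_marker_equals_z_squared(self, rng):
        kids = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=30)
        traits = rng.standard_normal(30)
        traits -= traits.mean()
        sc = trio_scores([(1, 1)] * 30, kids, traits)
        v = fbat_v(sc)
        m = fbat_m(sc)
        assert m.statistic == pytest.approx(v.statistic**2, rel=1e-10)
        assert m.df == 1
        assert m.p_value == pytest.approx(v.p_value, rel=1e-10)

    def test_fbat_m_duplicated_marker_rank_deficient(self, rng):
        kids = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=30)
        traits = rng.standard_normal(30)
        traits -= traits.mean()
        single = trio_scores([(1, 1)] * 30, kids, traits)
        dup = trio_scores(
            [(np.array([1, 1]), np.array([1, 1]))] * 30,
            [np.array([k, k]) for k in kids],
            traits,
            n_markers=2,
        )
        # the empirical variance sees the perfect cross-marker correlation,
        # so the duplicated column adds no rank
        res = fbat_m(dup, variance_mode="empirical")
        assert res.df == 1
        assert res.p_value == pytest.approx(
            fbat_m(single, variance_mode="empirical").p_value, rel=1e-8
        )

    def test_fbat_l_equal_weights_reduces_to_burden(self, rng):
        kids = [np.array(v) for v in rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=(40, 3))]
        parents = [(np.ones(3), np.ones(3))] * 40
        traits = rng.standard_normal(40)
        traits -= traits.mean()
        sc = trio_scores(parents, kids, traits, n_markers=3)
        lres = fbat_l(sc, weights=np.ones(3))
        vres = fbat_v(sc)
        assert lres.statistic == pytest.approx(vres.statistic, rel=1e-10)
        assert lres.p_value == pytest.approx(vres.p_value, rel=1e-10)

    def test_fbat_l_weight_sign_flip_invariance(self, rng):
        kids = [np.array(v) for v in rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=(40, 2))]
        parents = [(np.ones(2), np.ones(2))] * 40
        traits = rng.standard_normal(40)
        traits -= traits.mean()
        sc = trio_scores(parents, kids, traits, n_markers=2)
        w = np.array([0.7, -0.2])
        a, b = fbat_l(sc, weights=w), fbat_l(sc, weights=-w)
        assert abs(a.statistic) == pytest.approx(abs(b.statistic), rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_fbat_l_all_zero_weights_falls_back(self, rng):
        kids = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=20)
        traits = rng.standard_normal(20)
        traits -= traits.mean()
        sc = trio_scores([(1, 1)] * 20, kids, traits)
        with pytest.warns(UserWarning, match="falling back"):
            res = fbat_l(sc, weights=np.zeros(1))
        assert res.extras["unweighted_fallback"]
        assert res.p_value == pytest.approx(fbat_v(sc).p_value, rel=1e-12)


class TestFbatLmm:
    def _scores(self, rng, n=40):
        kids = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=n)
        traits = rng.standard_normal(n)
        traits -= traits.mean()
        return trio_scores([(1, 1)] * n, kids, traits)

    def test_deterministic_given_seed(self, rng):
        sc = self._scores(rng)
        p1 = fbat_lmm(sc, n_perm=300, seed=11).p_value
        p2 = fbat_lmm(sc, n_perm=300, seed=11).p_value
        assert p1 == p2

    def test_p_value_bounds_and_add_one_rule(self, rng):
        sc = self._scores(rng)
        res = fbat_lmm(sc, n_perm=200, seed=5)
        assert 1.0 / 201.0 <= res.p_value <= 1.0

    def test_zero_observed_statistic_ties_give_p_of_one(self):
        # every offspring sits at its conditional mean (het x het, x = 1), so
        # Q_obs = 0 while families stay informative; permuted Q* >= 0 always
        # and ties count as exceedances
        # the (2,0) family keeps the marker polymorphic but is itself
        # noninformative (conditional variance 0)
        sc = trio_scores([(1, 1)] * 6 + [(2, 0)], [1] * 7, [1.0, -1.0] * 3 + [1.0])
        assert fbat_lmm(sc, n_perm=100, seed=1).statistic == 0.0
        assert fbat_lmm(sc, n_perm=100, seed=1).p_value == 1.0

    def test_statistic_invariant_to_family_relabeling(self, rng):
        kids = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=20)
        traits = rng.standard_normal(20)
        traits -= traits.mean()
        fwd = trio_scores([(1, 1)] * 20, kids, traits)
        rev = trio_scores([(1, 1)] * 20, kids[::-1], traits[::-1])
        assert fbat_lmm(fwd, n_perm=100, seed=3).statistic == pytest.approx(
            fbat_lmm(rev, n_perm=100, seed=3).statistic, rel=1e-12
        )

    def test_n_perm_floor(self, rng):
        with pytest.raises(ValueError):
            fbat_lmm(self._scores(rng), n_perm=10)
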