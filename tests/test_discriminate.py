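"""Tumor features, normality check, paired t-test, separability."""

import dataclasses
import math
from itertools import product

import numpy as np
import pytest
from scipy import stats

from spectramct import (
    DegenerateVarianceError,
    TumorFeatures,
    discrimination_report,
    ks_normality,
    linearly_separable,
    paired_t_test,
    student_t_sf,
    tumor_features,
)
from conftest import make_volume


def ks_statistic_oracle(d):
    """Direct order-statistic enumeration, independent of the implementation."""
    z = (np.asarray(d, float) - np.mean(d)) / np.std(d, ddof=1)
    zs = sorted(z)
    n = len(zs)
    best = 0.0
    for i, v in enumerate(zs, start=1):
        phi = stats.norm.cdf(v)
        best = max(best, i / n - phi, phi - (i - 1) / n)
    return best


class TestTumorFeatures:
    def test_uniform_tumor(self):
        data = np.zeros((4, 4, 4, 5))
        data[..., 1:4] = 0.7
        v = make_volume(data)
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        f = tumor_features(v, mask, "t1", "m1", "A")
        np.testing.assert_allclose(f.mean, 0.7)
        np.testing.assert_allclose(f.std, 0.0, atol=1e-12)
        assert f.n_voxels == 8 and not f.partial_coverage

    def test_axial_boundary_tumor_flagged_partial(self):
        data = np.zeros((4, 4, 4, 5))
        v = make_volume(data)
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 0] = True
        assert tumor_features(v, mask).partial_coverage

    def test_punctate_density_raises_std(self):
        from spectramct.phantom import default_phantom_config, build_phantom
        base = default_phantom_config(seed=0)
        def mean_std(density, seeds):
            out = []
            for s in seeds:
                tum = dataclasses.replace(base.tumors[0], regime="punctate_np",
                                          agent="barium_agent",
                                          dot_density=density)
                cfg = dataclasses.replace(base, tumors=(tum,), seed=s)
                v, rois, _ = build_phantom(cfg)
                out.append(tumor_features(v, rois.masks["tumor_left"]).std)
            return np.mean(out, axis=0)
        dense = mean_std(0.009, range(100, 106))
        sparse = mean_std(0.0015, range(200, 206))
        assert np.all(dense > sparse)

    def test_diffuse_tumor_std_is_noise_dominated(self):
        from spectramct.phantom import (default_phantom_config, build_phantom,
                                        bin_attenuation, DEFAULT_MATERIALS)
        cfg = default_phantom_config(seed=4)
        v, rois, _ = build_phantom(cfg)
        f = tumor_features(v, rois.masks["tumor_left"])
        sigma = bin_attenuation(DEFAULT_MATERIALS["muscle"], cfg.binning)[1:4] / 20.0
        np.testing.assert_allclose(f.std, sigma, rtol=0.15)


class TestKSNormality:
    @pytest.mark.parametrize("n", [3, 4, 5, 6, 8])
    def test_statistic_equals_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        d = rng.normal(2.0, 3.0, n)
        r = ks_normality(d)
        assert r.statistic == pytest.approx(ks_statistic_oracle(d), abs=1e-12)

    def test_three_point_symmetric_fixture(self):
        r = ks_normality([-1.0, 0.0, 1.0])
        assert r.statistic == pytest.approx(ks_statistic_oracle([-1, 0, 1]),
                                            abs=1e-12)

    def test_matches_scipy_asymptotic_on_standardized_data(self, rng):
        d = rng.normal(0, 1, 25)
        r = ks_normality(d)
        z = (d - d.mean()) / d.std(ddof=1)
        ref = stats.kstest(z, "norm", mode="asymp")
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_large_normal_sample_passes(self):
        rng = np.random.default_rng(0)
        r = ks_normality(rng.normal(0, 1, 2000))
        assert r.statistic < 0.05 and r.p_value > 0.2

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            ks_normality([2.0, 2.0, 2.0])

    def test_lilliefors_option_reduces_p(self, rng):
        d = rng.normal(0, 1, 20)
        plain = ks_normality(d, lilliefors=False)
        lf = ks_normality(d, lilliefors=True)
        assert lf.lilliefors and 0 <= lf.p_value <= 1
        # estimating the parameters makes the plain p-value conservative
        assert plain.p_value >= lf.p_value - 0.05


class TestPairedT:
    def test_constant_shift_is_degenerate(self):
        x2 = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(DegenerateVarianceError):
            paired_t_test(x2 + 0.5, x2)

    def test_symmetric_differences_give_t_zero_p_one(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 1.0, -1.0])
        x2 = np.zeros(6)
        r = paired_t_test(d + x2, x2)
        assert r.t == 0.0 and r.p_value == 1.0 and r.df == 5

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_student_t_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(0.4, 1.0, 6)
        x2 = rng.normal(0.0, 1.0, 6)
        r = paired_t_test(x1, x2)
        ref = stats.ttest_rel(x1, x2)
        assert r.df == 5
        assert r.t == pytest.approx(ref.statistic, abs=1e-12)
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_swap_negates_t_keeps_p(self, rng):
        x1 = rng.normal(1, 1, 6)
        x2 = rng.normal(0, 1, 6)
        a = paired_t_test(x1, x2)
        b = paired_t_test(x2, x1)
        assert a.t == pytest.approx(-b.t)
        assert a.p_value == pytest.approx(b.p_value)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_p_value_ordering_agrees_with_sign_permutation_test(self):
        def sign_perm_p(d):
            obs = abs(np.mean(d))
            hits = total = 0
            for signs in product((-1, 1), repeat=len(d)):
                total += 1
                if abs(np.mean(np.array(signs) * d)) >= obs - 1e-12:
                    hits += 1
            return hits / total

        rng = np.random.default_rng(9)
        t_ps, perm_ps = [], []
        for _ in range(6):
            d = rng.normal(0.5, 1.0, 7)
            t_ps.append(paired_t_test(d, np.zeros(7)).p_value)
            perm_ps.append(sign_perm_p(d))
        # the permutation p has 1/2^7 granularity: require order agreement
        # wherever the permutation test itself distinguishes two datasets
        gran = 1 / 2**7
        for i in range(6):
            for j in range(6):
                if perm_ps[i] < perm_ps[j] - gran:
                    assert t_ps[i] < t_ps[j]

    def test_student_t_sf_tails(self):
        assert student_t_sf(0.0, 5) == 0.5
        assert student_t_sf(-2.0, 5) == pytest.approx(1 - student_t_sf(2.0, 5))
        assert student_t_sf(2.0, 5) == pytest.approx(stats.t.sf(2.0, 5), abs=1e-12)


class TestSeparability:
    def test_disjoint_bounding_boxes_separable(self):
        a = np.array([[0, 0], [1, 0.5], [0.5, 1]])
        b = a + np.array([5.0, 5.0])
        assert linearly_separable(a, b)

    def test_interleaved_clouds_not_separable(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, (8, 2))
        b = rng.normal(0, 1, (8, 2))
        assert not linearly_separable(a, b)

    def test_degenerate_sets(self):
        assert linearly_separable([[0.0, 0.0]], [[1.0, 1.0]])
        assert linearly_separable([[0, 0], [0, 1]], [[2, 0], [2, 1]])
        assert not linearly_separable([[0, 0], [2, 2]], [[1, 1]])


def synthetic_features(mouse, model, mean, std):
    return TumorFeatures(tumor_id=f"{model}_{mouse}", mouse_id=f"m{mouse}",
                         model=model, mean=np.asarray(mean, float),
                         std=np.asarray(std, float), n_voxels=100)


class TestDiscriminationReport:
    def test_strongly_separated_cohort(self):
        feats = []
        rng = np.random.default_rng(2)
        for i in range(6):
            feats.append(synthetic_features(i, "A",
                                            rng.normal(0.40, 0.005, 3),
                                            rng.normal(0.12, 0.004, 3)))
            feats.append(synthetic_features(i, "B",
                                            rng.normal(0.33, 0.005, 3),
                                            rng.normal(0.06, 0.004, 3)))
        rep = discrimination_report(feats, "A", "B")
        assert rep.n_pairs == 6
        assert rep.tests.reject.all()
        assert all(rep.separable.values()) and rep.separable_highlight
        assert set(rep.tests.feature) == {"mean", "std"}
        assert sorted(rep.tests.channel.unique()) == [1, 2, 3]

    def test_unpaired_design_rejected(self):
        feats = [synthetic_features(0, "A", [1, 1, 1], [0.1, 0.1, 0.1]),
                 synthetic_features(0, "B", [1, 1, 1], [0.1, 0.1, 0.1]),
                 synthetic_features(1, "A", [1, 1, 1], [0.1, 0.1, 0.1])]
        with pytest.raises(ValueError):
            discrimination_report(feats, "A", "B")

    def test_duplicate_model_per_mouse_rejected(self):
        feats = [synthetic_features(0, "A", [1, 1, 1], [0.1] * 3),
                 synthetic_features(0, "A", [1, 1, 1], [0.1] * 3)]
        with pytest.raises(ValueError):
            discrimination_report(feats, "A", "B")
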