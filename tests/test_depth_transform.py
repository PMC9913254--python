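"""Depth definitions, profiles, view correlations and rank agreement."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import lesionforest as lf
from lesionforest.core_model_io import FeatureGroupMap, LesionRecord
from lesionforest.depth_transform import (
    ViewReference,
    _robust_standardise,
    depth_ranking,
    sequential_rank_agreement,
)

TINY_MAP = FeatureGroupMap(
    view_names=("A", "B"),
    assignment={"f1": "A", "f2": "B", "f3": "B"},
    conventional_names=("SUV_max",),
)


def _tiny_lesion(lid, f1, f2=0.0, f3=1.0):
    return LesionRecord("P1", lid, "bone", {"f1": f1, "f2": f2, "f3": f3},
                        suv_max=1.0, tla=1.0, glcm_entropy=1.0)


def brute_force_depth(x, X):
    """Independent oracle: explicit inverse of the n-1 covariance."""
    mu = X.mean(axis=0)
    sigma = np.cov(X, rowvar=False, ddof=1)
    d2 = (x - mu) @ np.linalg.inv(np.atleast_2d(sigma)) @ (x - mu)
    return 1.0 / (1.0 + d2)


class TestViewReference:
    def test_hand_computed_mean_and_variance(self):
        lesions = [_tiny_lesion(f"L{i}", v, f2=float(i), f3=float(i * i))
                   for i, v in enumerate([0.0, 1.0, 2.0])]
        ref = lf.fit_view_reference(lesions, "A", TINY_MAP)
        assert ref.mean[0] == pytest.approx(1.0)
        assert ref.covariance[0, 0] == pytest.approx(1.0)  # denominator n-1
        assert ref.regularization == 0.0

    def test_identical_lesions_get_ridge(self):
        lesions = [_tiny_lesion(f"L{i}", 3.0) for i in range(4)]
        ref = lf.fit_view_reference(lesions, "A", TINY_MAP)
        assert ref.regularization > 0

    def test_singular_view_without_ridge_names_feature(self):
        lesions = [_tiny_lesion(f"L{i}", 3.0) for i in range(4)]
        with pytest.raises(ValueError, match="f1"):
            lf.fit_view_reference(lesions, "A", TINY_MAP, ridge=False)

    def test_large_sample_recovers_generator_moments(self, rng):
        n = 10000
        mean, sd = 2.0, 3.0
        vals = rng.normal(mean, sd, n)
        lesions = [_tiny_lesion(f"L{i}", v, f2=float(i % 7), f3=rng.normal())
                   for i, v in enumerate(vals)]
        ref = lf.fit_view_reference(lesions, "A", TINY_MAP)
        assert ref.mean[0] == pytest.approx(mean, abs=3 * sd / np.sqrt(n))
        assert ref.covariance[0, 0] == pytest.approx(sd**2, abs=3 * sd**2 * np.sqrt(2 / n))


class TestMahalanobisDepth:
    def test_center_has_depth_one(self):
        ref = ViewReference("A", ("f1",), np.array([1.0]), np.array([[1.0]]), 0.0, 3)
        assert lf.mahalanobis_depth(np.array([1.0]), ref) == pytest.approx(1.0)

    def test_one_dim_closed_form(self):
        # mean 1, variance 1, x=0 -> 1/(1+1) = 0.5
        ref = ViewReference("A", ("f1",), np.array([1.0]), np.array([[1.0]]), 0.0, 3)
        assert lf.mahalanobis_depth(np.array([0.0]), ref) == pytest.approx(0.5)

    def test_dimension_mismatch(self):
        ref = ViewReference("A", ("f1",), np.array([1.0]), np.array([[1.0]]), 0.0, 3)
        with pytest.raises(ValueError, match="dimension mismatch"):
            lf.mahalanobis_depth(np.array([0.0, 1.0]), ref)

    @pytest.mark.parametrize("d", [1, 3, 6])
    def test_matches_brute_force_oracle(self, d, rng):
        for _ in range(20):
            X = rng.standard_normal((30, d)) @ rng.standard_normal((d, d))
            names = tuple(f"g{j}" for j in range(d))
            gm = FeatureGroupMap(("V",), {n: "V" for n in names}, ())
            lesions = [
                LesionRecord("P", f"L{i}", "bone", dict(zip(names, row)), 1, 1, 1)
                for i, row in enumerate(X)
            ]
            ref = lf.fit_view_reference(lesions, "V", gm)
            x = rng.standard_normal(d)
            assert lf.mahalanobis_depth(x, ref) == pytest.approx(
                brute_force_depth(x, X), abs=1e-10
            )

    def test_affine_invariance(self, rng):
        d = 4
        X = rng.standard_normal((50, d))
        A = rng.standard_normal((d, d)) + 3 * np.eye(d)
        b = rng.standard_normal(d)
        x = rng.standard_normal(d)
        names = tuple(f"g{j}" for j in range(d))
        gm = FeatureGroupMap(("V",), {n: "V" for n in names}, ())

        def depth_of(Xm, xv):
            lesions = [LesionRecord("P", f"L{i}", "bone", dict(zip(names, r)), 1, 1, 1)
                       for i, r in enumerate(Xm)]
            return lf.mahalanobis_depth(xv, lf.fit_view_reference(lesions, "V", gm))

        d0 = depth_of(X, x)
        d1 = depth_of(X @ A.T + b, A @ x + b)
        assert d0 == pytest.approx(d1, abs=1e-9)


class TestOtherDepths:
    def test_spatial_unit_vectors_cancel(self):
        assert lf.spatial_depth(np.array([0.0]), np.array([[-1.0], [1.0]])) == pytest.approx(1.0)

    def test_spatial_far_point_approaches_zero(self, rng):
        sample = rng.standard_normal((100, 3))
        assert lf.spatial_depth(np.full(3, 1e6), sample) < 1e-3

    def test_spatial_median_of_symmetric_sample_is_deep(self, rng):
        z = rng.standard_normal((500, 2))
        sample = np.vstack([z, -z])  # exactly centro-symmetric
        assert lf.spatial_depth(np.zeros(2), sample) == pytest.approx(1.0, abs=1e-12)

    def test_projection_deterministic_given_seed(self, rng):
        sample = rng.standard_normal((60, 4))
        x = rng.standard_normal(4)
        a = lf.projection_depth(x, sample, n_directions=64, seed=11)
        b = lf.projection_depth(x, sample, n_directions=64, seed=11)
        assert a == b

    def test_projection_axis_oracle(self, rng):
        """With the coordinate axes as directions, matches the exhaustive axis sup."""
        sample = rng.standard_normal((41, 3)) * np.array([1.0, 5.0, 0.2])
        x = np.array([0.7, -2.0, 0.4])
        axes = np.eye(3)
        got = lf.projection_depth(x, sample, directions=axes)
        outs = []
        for j in range(3):
            proj = sample[:, j]
            med = np.median(proj)
            mad = np.median(np.abs(proj - med))
            outs.append(abs(x[j] - med) / mad)
        assert got == pytest.approx(1.0 / (1.0 + max(outs)), abs=1e-12)

    def test_projection_median_is_deep(self, rng):
        z = rng.standard_normal((200, 2))
        sample = np.vstack([z, -z])
        assert lf.projection_depth(np.zeros(2), sample, n_directions=100, seed=0) > 0.95


class TestDepthProfiles:
    def test_one_profile_per_lesion_in_unit_interval(self, default_dataset, default_profiles):
        assert len(default_profiles) == len(default_dataset.lesions)
        assert default_profiles.shape[1] == 6
        vals = default_profiles.to_numpy()
        assert (vals > 0).all() and (vals <= 1).all()
        assert np.isfinite(vals).all()

    def test_duplicate_lesions_share_profiles(self, default_sim):
        import copy

        lesions = [copy.deepcopy(l) for l in default_sim.lesions]
        twin = copy.deepcopy(lesions[0])
        twin.lesion_id = "DUP"
        lesions.append(twin)
        ds = lf.validate_cohort(lesions, default_sim.clinical)
        frame = lf.profiles_frame(lf.compute_depth_profiles(ds))
        a = frame.loc[(twin.patient_id, lesions[0].lesion_id)].to_numpy()
        b = frame.loc[(twin.patient_id, "DUP")].to_numpy()
        assert a == pytest.approx(b, abs=1e-12)

    def test_per_view_affine_rescaling_leaves_profiles_unchanged(self, default_sim):
        import copy

        base = default_sim.dataset()
        frame0 = lf.profiles_frame(lf.compute_depth_profiles(base))
        lesions = [copy.deepcopy(l) for l in default_sim.lesions]
        gm = base.group_map
        scaled_feats = gm.features_in_view("GLCM")
        for l in lesions:
            for f in scaled_feats:
                l.features[f] = 7.5 * l.features[f] - 11.0
        ds = lf.validate_cohort(lesions, default_sim.clinical, gm)
        frame1 = lf.profiles_frame(lf.compute_depth_profiles(ds))
        np.testing.assert_allclose(frame0.to_numpy(), frame1.to_numpy(), atol=1e-9)


class TestViewCorrelation:
    def test_duplicated_view_correlates_fully(self, rng):
        x = rng.uniform(0.1, 1.0, 50)
        frame = pd.DataFrame({"A": x, "B": x, "C": rng.uniform(0.1, 1, 50)})
        corr = lf.view_correlation_matrix(frame)
        assert corr.loc["A", "B"] == pytest.approx(1.0)
        assert np.allclose(corr.values, corr.values.T)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_independent_views_near_zero(self, rng):
        frame = pd.DataFrame(rng.uniform(0.0, 1.0, (5000, 6)),
                             columns=list("ABCDEF"))
        corr = lf.view_correlation_matrix(frame).to_numpy()
        off = corr[np.triu_indices(6, 1)]
        assert np.abs(off).max() < 0.05

    def test_constant_column_reported_missing(self):
        frame = pd.DataFrame({"A": [0.5, 0.5, 0.5, 0.5], "B": [0.1, 0.2, 0.3, 0.4]})
        corr = lf.view_correlation_matrix(frame)
        assert np.isnan(corr.loc["A", "B"])


class TestSequentialRankAgreement:
    def test_identical_lists_agree_perfectly(self):
        lists = [list("abcdef")] * 3
        assert sequential_rank_agreement(lists) == pytest.approx(np.zeros(6))

    def test_reversed_pair_hand_computation(self):
        # ranks: a(1,4) b(2,3) c(3,2) d(4,1); variances 4.5, .5, .5, 4.5
        curve = sequential_rank_agreement([list("abcd"), list("dcba")], 4)
        expected = [np.sqrt(4.5), np.sqrt(2.5), np.sqrt(2.5), np.sqrt(2.5)]
        assert curve == pytest.approx(expected)

    def test_mismatched_item_sets_rejected(self):
        with pytest.raises(ValueError, match="different item sets"):
            sequential_rank_agreement([list("abc"), list("abd")])

    def test_random_permutations_match_simulated_null(self, rng):
        """Mean SRA at full depth matches a permutation-oracle estimate."""
        n, L = 30, 2
        items = list(range(n))

        def sra_full(perms):
            return sequential_rank_agreement(perms, n)[-1]

        observed = np.mean([
            sra_full([list(rng.permutation(items)) for _ in range(L)])
            for _ in range(60)
        ])
        # Oracle: variance of the difference of two uniform ranks, pooled.
        null = np.mean([
            np.sqrt(np.mean([np.var([a, b], ddof=1) for a, b in
                             zip(rng.permutation(n), rng.permutation(n))]))
            for _ in range(300)
        ])
        assert observed == pytest.approx(null, rel=0.1)

    def test_depth_ranking_orders_by_mean_depth(self, default_profiles):
        order = depth_ranking(default_profiles.head(10))
        means = default_profiles.head(10).mean(axis=1)
        assert means.loc[order[0]] == means.max()


def test_robust_standardise_handles_constant_columns():
    X = np.column_stack([np.ones(10), np.arange(10.0)])
    Z = _robust_standardise(X)
    assert np.isfinite(Z).all()
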