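"""EM mixture fitting, model selection, and cluster extraction."""

import numpy as np
import pytest

from clonetrace.clustering import (
    FLAG_DEGENERATE,
    build_vaf_matrix,
    extract_clusters,
    fit_em,
    select_k,
)
from clonetrace.io_formats import CnaState
from clonetrace.vaf_correction import CorrectedVariant


def _cv(vid, vaf):
    from fractions import Fraction

    return CorrectedVariant(
        variant_id=vid,
        raw_vaf=vaf,
        cna_state=CnaState.NEUTRAL,
        ref_adj=Fraction(1),
        alt_adj=Fraction(1),
        corrected_vaf=vaf,
        cellular_proportion=min(2 * vaf, 1.0),
    )


class TestBuildVafMatrix:
    def test_shared_variant_keeps_both_coordinates(self):
        ids, m, dropped = build_vaf_matrix([_cv("v1", 0.4)], [_cv("v1", 0.35)])
        assert ids == ["v1"] and dropped == []
        np.testing.assert_allclose(m, [[0.4, 0.35]])

    def test_absent_variant_sits_at_zero(self):
        ids, m, _ = build_vaf_matrix([_cv("v1", 0.3)], [])
        np.testing.assert_allclose(m, [[0.3, 0.0]])

    def test_uncovered_sites_dropped_with_report(self):
        ids, m, dropped = build_vaf_matrix(
            [_cv("v1", 0.3), _cv("v2", 0.2)],
            [],
            depth_b={"v1": 100, "v2": 3},
        )
        assert ids == ["v1"] and dropped == ["v2"]

    def test_rows_sorted_by_variant_id(self):
        ids, _, _ = build_vaf_matrix([_cv("b", 0.1), _cv("a", 0.2)], [])
        assert ids == ["a", "b"]

    def test_no_variants_errors(self):
        with pytest.raises(ValueError, match="no variants"):
            build_vaf_matrix([], [])


class TestFitEm:
    def test_degenerate_identical_points(self):
        X = np.full((50, 2), 0.4)
        model = fit_em(X, k=3, seed=0)
        assert model.k == 1 and FLAG_DEGENERATE in model.flags
        np.testing.assert_allclose(model.means, [[0.4, 0.4]])

    def test_two_separated_components_recovered(self):
        rng = np.random.default_rng(2)
        X = np.concatenate(
            [rng.normal(0.10, 0.01, 100), rng.normal(0.45, 0.01, 100)]
        )[:, None]
        model = fit_em(X, k=2, seed=3)
        means = sorted(float(m) for m in model.means[:, 0])
        assert abs(means[0] - 0.10) < 0.02 and abs(means[1] - 0.45) < 0.02

    def test_loglik_trace_non_decreasing_on_random_fixtures(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n = int(rng.integers(20, 120))
            d = int(rng.integers(1, 3))
            X = rng.random((n, d))
            k = int(rng.integers(1, 4))
            model = fit_em(X, k=k, seed=int(rng.integers(0, 2**31)))
            trace = np.array(model.loglik_trace)
            tol = 1e-6 * max(1.0, np.abs(trace).max())
            assert np.all(np.diff(trace) >= -tol)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            fit_em(np.zeros((3, 1)) + [[0.1], [0.2], [0.3]], k=5, seed=0)

    def test_agrees_with_sklearn_on_separated_fixture(self):
        """Independent cross-check: our EM matches sklearn's GMM fit."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(4)
        X = np.concatenate(
            [
                rng.normal([0.1, 0.1], 0.01, (150, 2)),
                rng.normal([0.4, 0.4], 0.01, (150, 2)),
            ]
        )
        ours = fit_em(X, k=2, seed=0)
        theirs = GaussianMixture(2, covariance_type="diag", random_state=0).fit(X)
        ours_means = sorted(map(tuple, np.round(ours.means, 3)))
        theirs_means = sorted(map(tuple, np.round(theirs.means_, 3)))
        np.testing.assert_allclose(ours_means, theirs_means, atol=0.01)
        # mean per-point loglik agrees
        assert ours.loglik / len(X) == pytest.approx(
            theirs.score(X), abs=0.02
        )


class TestSelectK:
    def test_single_component(self):
        rng = np.random.default_rng(10)
        X = rng.normal(0.3, 0.02, (150, 1))
        assert select_k(X, seed=1).k == 1

    def test_three_components_selected_across_seeds(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = np.concatenate(
                [
                    rng.normal(c, 0.02, (100, 1))
                    for c in (0.10, 0.28, 0.45)
                ]
            )
            if select_k(X, seed=seed).k == 3:
                hits += 1
        assert hits >= 9

    def test_unresolvable_close_components_collapse_to_one(self):
        rng = np.random.default_rng(11)
        X = np.concatenate(
            [rng.normal(0.300, 0.02, (100, 1)), rng.normal(0.305, 0.02, (100, 1))]
        )
        assert select_k(X, seed=2).k == 1

    def test_center_multiset_stable_across_seeds(self):
        rng = np.random.default_rng(12)
        X = np.concatenate(
            [rng.normal([0.1, 0.4], 0.01, (100, 2)), rng.normal([0.4, 0.1], 0.01, (100, 2))]
        )
        centers = set()
        for seed in range(5):
            model = select_k(X, seed=seed)
            centers.add(tuple(sorted(map(tuple, np.round(model.means, 2)))))
        assert len(centers) == 1


class TestExtractClusters:
    def test_presence_flags(self):
        rng = np.random.default_rng(13)
        X = np.concatenate(
            [
                rng.normal([0.38, 0.41], 0.01, (60, 2)),
                np.column_stack([rng.normal(0.27, 0.01, 60), np.zeros(60)]),
            ]
        )
        ids = [f"v{i}" for i in range(len(X))]
        model = fit_em(X, k=2, seed=0)
        clusters = extract_clusters(model, X, ids)
        by_presence = {c.presence: c for c in clusters}
        assert (True, True) in by_presence and (True, False) in by_presence

    def test_members_partition_variants(self):
        rng = np.random.default_rng(14)
        X = rng.random((80, 2))
        ids = [f"v{i}" for i in range(80)]
        clusters = extract_clusters(fit_em(X, k=3, seed=1), X, ids)
        all_members = [vid for c in clusters for vid in c.member_variant_ids]
        assert sorted(all_members) == sorted(ids)

    def test_cluster_ids_follow_sorted_centers(self):
        rng = np.random.default_rng(15)
        X = np.concatenate(
            [rng.normal(0.5, 0.01, (50, 1)), rng.normal(0.1, 0.01, (50, 1))]
        )
        clusters = extract_clusters(fit_em(X, k=2, seed=0), X, [f"v{i}" for i in range(100)])
        assert clusters[0].center[0] < clusters[1].center[0]
        assert clusters[0].cluster_id == 0
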