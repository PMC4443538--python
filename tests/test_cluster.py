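import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_t
from sklearn.metrics import adjusted_rand_score

from capsuledyn import (
    ClusterModelConfig,
    SimulationConfig,
    agglomerate,
    classify_trend,
    cluster_centers,
    coeffs_from_trajectory,
    filter_absent,
    filter_low_expression,
    generate_expression_dataset,
    inclusion_filter,
    log2_ratio_profiles,
    marginal_log_likelihood,
    median_by_timepoint,
    select_clusters,
)
from capsuledyn.cluster import Cluster, _ConjugateModel

WEEKS = [2, 4, 8, 16]


def frame(rows, ids=None):
    ids = ids or [f"p{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=ids, columns=WEEKS, dtype=float)


class TestMarginalLikelihood:
    @pytest.mark.parametrize("order", [0, 1, 2, 3])
    def test_matches_student_t_density(self, order):
        """The closed form must equal the multivariate Student-t evidence
        y ~ t_{2a0}(X m0, (b0/a0)(I + tau^2 X X')) computed by scipy."""
        cfg = ClusterModelConfig(
            polynomial_order=order, prior_scale=1.3,
            noise_prior_shape=1.5, noise_prior_rate=0.2,
        )
        model = _ConjugateModel(WEEKS, cfg)
        rng = np.random.default_rng(order)
        y = rng.normal(0.0, 1.5, size=4)
        shape = (cfg.noise_prior_rate / cfg.noise_prior_shape) * (
            np.eye(4) + cfg.prior_scale**2 * model.X @ model.X.T
        )
        expected = multivariate_t.logpdf(
            y, loc=model.X @ model.m0, shape=shape, df=2 * cfg.noise_prior_shape
        )
        assert model.logml(y) == pytest.approx(expected, abs=1e-9)

    def test_identical_profiles_favor_merging(self):
        v = frame([[1.0, 2.0, 2.0, 1.0]])
        joint = marginal_log_likelihood(pd.concat([v, v]))
        single = marginal_log_likelihood(v)
        assert joint - 2 * single > 0

    def test_opposite_profiles_disfavor_merging(self):
        v = [1.0, 2.0, 2.0, 1.0]
        joint = marginal_log_likelihood(frame([v, [-x for x in v]]))
        single = marginal_log_likelihood(frame([v]))
        assert joint - 2 * single < 0

    def test_row_stacking_order_invariance(self):
        rng = np.random.default_rng(5)
        rows = rng.normal(0, 1, size=(6, 4))
        base = marginal_log_likelihood(frame(rows.tolist()))
        for perm_seed in range(3):
            perm = np.random.default_rng(perm_seed).permutation(6)
            assert marginal_log_likelihood(
                frame(rows[perm].tolist())
            ) == pytest.approx(base, abs=1e-10)

    def test_finite_for_extreme_inputs(self):
        for v in ([0.0] * 4, [50.0, -50.0, 50.0, -50.0], [1e-8] * 4):
            assert np.isfinite(marginal_log_likelihood(frame([v])))


class TestInclusionFilter:
    def test_strict_threshold_boundary(self):
        prof = frame(
            [[0.5, 0.9, -0.2, 0.1], [1.2, 0, 0, 0], [-1.0001, 0, 0, 0], [-1.0, 0, 0, 0]],
            ids=["a", "b", "c", "d"],
        )
        kept = inclusion_filter(prof)
        assert list(kept.index) == ["b", "c"]


class TestAgglomeration:
    def test_identical_pair_merges_opposites_stay_apart(self):
        v = [1.0, 2.0, 2.0, 1.0]
        part = agglomerate(frame([v, v]))
        assert part.n_clusters == 1 and part.clusters[0].size == 2
        part = agglomerate(frame([v, [-x for x in v]]))
        assert part.n_clusters == 2

    def test_merge_trace_log_bayes_factors_positive(self):
        rng = np.random.default_rng(2)
        rows = np.vstack(
            [
                [1.5, 2.0, 2.0, 1.5] + rng.normal(0, 0.05, 4)
                for _ in range(5)
            ]
            + [
                [-1.0, -2.0, -2.5, -2.0] + rng.normal(0, 0.05, 4)
                for _ in range(5)
            ]
        )
        part = agglomerate(frame(rows.tolist()))
        assert all(m.log_bf > 0 for m in part.merge_trace)
        # total evidence never decreases along the trace
        assert part.n_clusters == 2

    def test_exchangeability_under_input_permutation(self):
        rng = np.random.default_rng(3)
        rows = np.vstack(
            [[2.0, 1.5, 1.2, 2.0] + rng.normal(0, 0.1, 4) for _ in range(4)]
            + [[-2.0, -1.5, -1.0, -1.8] + rng.normal(0, 0.1, 4) for _ in range(4)]
        )
        ids = [f"p{i}" for i in range(8)]
        base = agglomerate(frame(rows.tolist(), ids))
        perm = np.random.default_rng(9).permutation(8)
        shuffled = agglomerate(frame(rows[perm].tolist(), [ids[i] for i in perm]))
        as_sets = lambda p: {frozenset(c.members) for c in p.clusters}
        assert as_sets(base) == as_sets(shuffled)


class TestCentersSelectionTrend:
    def test_center_is_member_mean_and_idempotent(self):
        prof = frame([[1, 1, 1, 1], [3, 3, 3, 3]])
        part = agglomerate(prof)
        part2 = cluster_centers(part)
        for a, b in zip(part.clusters, part2.clusters):
            assert np.allclose(a.center, b.center)
        if part.n_clusters == 1:
            assert np.allclose(part.clusters[0].center, [2, 2, 2, 2])

    def test_singleton_center_equals_profile(self):
        prof = frame([[0.3, -0.7, 1.4, 0.1]])
        part = cluster_centers(agglomerate(prof))
        assert np.allclose(part.clusters[0].center, prof.iloc[0])

    @pytest.mark.parametrize(
        "center,selected",
        [([0.5, 0.9, -0.2, 0.1], False), ([-1.3, -0.5, 0, 0], True),
         ([1.0, 1.0, 1.0, 1.0], False)],  # strict: |center| must exceed 1
    )
    def test_selection_threshold(self, center, selected):
        part = select_clusters(agglomerate(frame([center])))
        assert part.clusters[0].selected is selected

    @pytest.mark.parametrize(
        "center,trend",
        [
            ([0.2, 0.8, 1.5, 2.0], "increased"),
            ([-0.1, -1.2, -2.0, -1.8], "decreased"),
            ([1.5, -1.5, 1.0, 0], "variable"),
            ([0.1, 0.2, 0.3, 0.2], "variable"),
        ],
    )
    def test_trend_classes(self, center, trend):
        cl = Cluster(1, ("p0",), pd.Series(center, index=WEEKS), logml=0.0)
        assert classify_trend(cl) == trend


class TestPlantedRecovery:
    def test_center_recovery_within_standard_error(self):
        target = [1.5, 2.0, 2.0, 1.5]
        spec = [(coeffs_from_trajectory(target), 60)]
        cfg = SimulationConfig(
            n_probes=60, cluster_spec=spec, groups=("immobilized",),
            absent_fraction=0.0, low_floor_fraction=0.0, seed=4,
        )
        ds, truth = generate_expression_dataset(cfg)
        med = median_by_timepoint(
            filter_low_expression(filter_absent(ds.for_group("immobilized")).dataset).dataset
        )
        part = agglomerate(inclusion_filter(log2_ratio_profiles(med)))
        assert part.n_clusters == 1
        center = part.clusters[0].center.to_numpy()
        # replicate noise sd 0.1 -> median-of-4 ratio noise well under 0.2;
        # 3 standard errors of the 60-member mean
        se = 3 * 0.2 / np.sqrt(60)
        assert np.all(np.abs(center - np.array(target)) < 3 * se + 0.05)

    def test_two_cluster_ari_recovery(self):
        spec = [
            (coeffs_from_trajectory([1.5, 2.0, 2.0, 1.5]), 100),
            (coeffs_from_trajectory([-1.0, -2.0, -2.5, -2.0]), 100),
        ]
        cfg = SimulationConfig(
            n_probes=200, cluster_spec=spec, groups=("immobilized",),
            absent_fraction=0.0, low_floor_fraction=0.0,
            replicate_noise_sd=0.1, seed=11,
        )
        ds, truth = generate_expression_dataset(cfg)
        med = median_by_timepoint(ds.for_group("immobilized"))
        part = agglomerate(inclusion_filter(log2_ratio_profiles(med)))
        labels = part.labels()
        ari = adjusted_rand_score(
            truth.labels["immobilized"].loc[labels.index], labels
        )
        assert ari >= 0.9
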