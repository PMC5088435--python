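"""Staged clustering, cluster weights, risk curves, and Bayesian updates."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dynaprof.profiling import (
    BetaPrior,
    RiskCurve,
    StageFeatureTable,
    assign_new_patient,
    bayes_update,
    build_partitions,
    cluster_stage,
    cluster_weight,
    risk_curve,
    stage_features,
)


def brute_force_wcss(X, k):
    """Minimal within-cluster sum of squares over every labeling (oracle)."""
    n = len(X)
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        wcss = 0.0
        for c in set(labels):
            members = X[[i for i in range(n) if labels[i] == c]]
            wcss += np.sum((members - members.mean(axis=0)) ** 2)
        best = min(best, wcss)
    return best


def feature_table(X, columns=None, stage=0):
    frame = pd.DataFrame(np.asarray(X, dtype=float))
    frame.columns = columns or (["gcs"] + [f"f{i}" for i in range(frame.shape[1] - 1)])
    frame.index = [f"P{i}" for i in range(len(frame))]
    means = frame.mean()
    sds = frame.std(ddof=0).replace(0.0, 1.0)
    return StageFeatureTable(stage, (frame - means) / sds, means, sds)


class TestClusterWeight:
    def test_hand_computed_example(self):
        w = cluster_weight([1, 1, 4, 5])
        assert w.red_flags == 2 and w.size == 4
        assert w.gos_mean == pytest.approx(2.75)
        assert w.gos_sd == pytest.approx(2.0616, abs=1e-4)
        assert w.prob_death == pytest.approx(0.5)

    def test_four_deaths_of_eleven(self):
        w = cluster_weight([1, 1, 1, 1, 2, 3, 4, 4, 5, 5, 5])
        assert w.prob_death == pytest.approx(4 / 11)

    def test_all_favorable(self):
        w = cluster_weight([5, 5, 5])
        assert w.red_flags == 0 and w.prob_death == 0.0 and w.gos_sd == 0.0

    def test_singleton_sd_zero(self):
        assert cluster_weight([3]).gos_sd == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cluster_weight([])


class TestClusterStage:
    def test_separated_triplets_match_brute_force(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        X = np.vstack([c + 0.1 * rng.normal(size=(3, 2)) for c in centers])
        part = cluster_stage(feature_table(X), k=3, seed=0)
        # each triplet is one cluster
        labels = [part.assignment[f"P{i}"] for i in range(9)]
        assert len({tuple(labels[i : i + 3]) for i in range(0, 9, 3)}) == 3
        for i in range(0, 9, 3):
            assert len(set(labels[i : i + 3])) == 1
        table = feature_table(X)
        assert part.inertia == pytest.approx(
            brute_force_wcss(table.frame.to_numpy(), 3), rel=1e-9
        )

    def test_k1_recovers_total_variance(self, rng):
        X = rng.normal(size=(6, 3))
        table = feature_table(X)
        part = cluster_stage(table, k=1, seed=0)
        Z = table.frame.to_numpy()
        assert part.inertia == pytest.approx(np.sum((Z - Z.mean(0)) ** 2))

    def test_determinism(self, rng):
        X = rng.normal(size=(12, 4))
        a = cluster_stage(feature_table(X), k=3, seed=5)
        b = cluster_stage(feature_table(X), k=3, seed=5)
        assert a.assignment == b.assignment

    def test_labels_canonical_by_mean_gcs(self, rng):
        gcs = np.concatenate([np.full(4, 3.0), np.full(4, 8.0), np.full(4, 13.0)])
        X = np.column_stack([gcs, 0.01 * rng.normal(size=12)])
        part = cluster_stage(feature_table(X), k=3, seed=1)
        by_cluster = {}
        for i, g in enumerate(gcs):
            by_cluster.setdefault(part.assignment[f"P{i}"], []).append(g)
        means = [np.mean(by_cluster[c]) for c in sorted(by_cluster)]
        assert means == sorted(means)

    def test_spectral_separates_clean_groups(self, rng):
        centers = np.array([[0.0, 0.0], [12.0, 0.0], [0.0, 12.0]])
        X = np.vstack([c + 0.2 * rng.normal(size=(5, 2)) for c in centers])
        part = cluster_stage(feature_table(X), k=3, method="spectral", seed=0)
        labels = [part.assignment[f"P{i}"] for i in range(15)]
        for i in range(0, 15, 5):
            assert len(set(labels[i : i + 5])) == 1

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            cluster_stage(feature_table(np.ones((5, 2))), k=2)
        with pytest.raises(ValueError, match="clusters"):
            cluster_stage(feature_table(np.eye(2)), k=3)


class TestStageFeatures:
    def test_stage_minus1_is_gcs_only(self, small_cohort):
        table = stage_features(small_cohort, -1)
        assert list(table.frame.columns) == ["gcs"]
        assert len(table.frame) == len(small_cohort)

    def test_stage0_adds_clinical(self, small_cohort):
        table = stage_features(small_cohort, 0)
        assert "age" in table.frame.columns and "infection" in table.frame.columns
        assert not any("." in c for c in table.frame.columns)

    def test_stage1_has_readings_but_no_trends(self, small_cohort):
        table = stage_features(small_cohort, 1)
        assert any(c.endswith(".r1") for c in table.frame.columns)
        assert not any(c.endswith((".T0", ".L", ".Q")) for c in table.frame.columns)

    def test_dimension_constant_from_stage2(self, small_cohort):
        """The clustering dimension is bounded: trend degree is capped at d
        no matter how much history exists, so stages 2.. all share one
        feature dimension."""
        dims = {
            stage: stage_features(small_cohort, stage, degree=2).frame.shape[1]
            for stage in range(2, small_cohort.max_round + 1)
        }
        assert len(set(dims.values())) == 1
        # 1 gcs + 7 clinical + 13*(d+1) trends + 13 readings
        assert set(dims.values()) == {1 + 6 + 39 + 13}

    def test_standardized_columns(self, small_cohort):
        frame = stage_features(small_cohort, 0).frame
        np.testing.assert_allclose(frame.mean(), 0.0, atol=1e-10)
        for col in frame.columns:
            sd = frame[col].std(ddof=0)
            assert sd == pytest.approx(1.0, abs=1e-10) or sd == pytest.approx(0.0)

    def test_patients_lacking_round_excluded(self, small_cohort):
        last = small_cohort.max_round
        table = stage_features(small_cohort, last)
        missing = [p.id for p in small_cohort if not p.has_round(last)]
        assert set(table.excluded) == set(missing)
        assert set(table.frame.index) == set(small_cohort.ids) - set(missing)

    def test_stage_beyond_data_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="exceeds"):
            stage_features(small_cohort, small_cohort.max_round + 1)


class TestPartitions:
    def test_exhaustive_and_conserving(self, medium_cohort):
        cohort, _ = medium_cohort
        partitions, _ = build_partitions(cohort, seed=2, n_restarts=5)
        total_deaths = sum(1 for p in cohort if p.gos == 1)
        for part in partitions:
            sizes = sum(w.size for w in part.weights.values())
            assert sizes == len(part.assignment)
            included_deaths = sum(
                1 for pid in part.assignment if cohort.get(pid).gos == 1
            )
            assert sum(w.red_flags for w in part.weights.values()) == included_deaths
            assert all(0 <= w.prob_death <= 1 for w in part.weights.values())
        # stage -1 includes everyone
        assert len(partitions[0].assignment) == len(cohort)
        assert total_deaths == sum(
            w.red_flags for w in partitions[0].weights.values()
        )


class TestRiskCurve:
    def test_lone_survivor_flat_zero(self):
        parts = []
        for stage in (-1, 0, 1):
            part = cluster_stage(
                feature_table(np.arange(8).reshape(4, 2), stage=stage), k=3, seed=0
            )
            part.weights = {c: cluster_weight([5]) for c in range(3)}
            parts.append(part)
        curve = risk_curve("P0", parts)
        assert curve.probs == [0.0, 0.0, 0.0]

    def test_missing_stage_omitted(self, medium_cohort):
        cohort, _ = medium_cohort
        partitions, _ = build_partitions(cohort, seed=2, n_restarts=5)
        short = min(cohort, key=lambda p: p.n_rounds)
        curve = risk_curve(short.id, partitions)
        assert max(curve.stages) <= short.n_rounds
        assert curve.stages[0] == -1
        assert all(0 <= p <= 1 for p in curve.probs)

    def test_unknown_patient_rejected(self, medium_cohort):
        cohort, _ = medium_cohort
        partitions, _ = build_partitions(cohort, max_stage=0, seed=2, n_restarts=5)
        with pytest.raises(KeyError):
            risk_curve("nobody", partitions)


class TestAssignNewPatient:
    def _partition(self, rng):
        X = np.vstack(
            [c + 0.1 * rng.normal(size=(4, 2)) for c in
             [np.zeros(2), np.array([8.0, 0.0]), np.array([0.0, 8.0])]]
        )
        table = feature_table(X)
        part = cluster_stage(table, k=3, seed=0)
        gos = {0: [1, 1, 2, 3], 1: [4, 5, 5, 5], 2: [1, 4, 5, 5]}
        part.weights = {c: cluster_weight(g) for c, g in gos.items()}
        return part, table

    def test_centroid_row_maps_to_its_cluster(self, rng):
        part, table = self._partition(rng)
        for c in range(3):
            raw = part.centroids[c] * part.sds.to_numpy() + part.means.to_numpy()
            label, prob = assign_new_patient(
                part, pd.Series(raw, index=part.features_used)
            )
            assert label == c
            assert prob == part.weights[c].prob_death

    def test_existing_member_maps_to_own_cluster(self, rng):
        part, table = self._partition(rng)
        pid = "P5"
        raw = table.frame.loc[pid] * part.sds + part.means
        label, _ = assign_new_patient(part, raw)
        assert label == part.assignment[pid]

    def test_equidistant_tie_prefers_lower_label(self):
        frame = pd.DataFrame(
            {"gcs": [-1.0, -1.0, 1.0, 1.0]}, index=["P0", "P1", "P2", "P3"]
        )
        table = StageFeatureTable(
            -1, frame, pd.Series({"gcs": 0.0}), pd.Series({"gcs": 1.0})
        )
        part = cluster_stage(table, k=2, seed=0)
        part.weights = {0: cluster_weight([1, 2]), 1: cluster_weight([4, 5])}
        label, _ = assign_new_patient(part, pd.Series({"gcs": 0.0}))
        assert label == 0

    def test_missing_feature_rejected(self, rng):
        part, _ = self._partition(rng)
        with pytest.raises(ValueError, match="lacks"):
            assign_new_patient(part, pd.Series({"gcs": 1.0}))


class TestBayesUpdate:
    def test_conjugate_example(self):
        post, mean = bayes_update(BetaPrior(1, 1), cluster_weight([1] * 4 + [4] * 7))
        assert (post.alpha, post.beta) == (5, 8)
        assert mean == pytest.approx(5 / 13)

    def test_posterior_between_prior_and_empirical(self, rng):
        for _ in range(200):
            alpha, beta = rng.uniform(0.1, 10, size=2)
            size = int(rng.integers(1, 30))
            red = int(rng.integers(0, size + 1))
            gos = [1] * red + [4] * (size - red)
            prior = BetaPrior(alpha, beta)
            w = cluster_weight(gos)
            _, mean = bayes_update(prior, w)
            lo, hi = sorted([prior.mean, w.prob_death])
            assert lo - 1e-12 <= mean <= hi + 1e-12

    def test_limits(self):
        w = cluster_weight([1] * 3 + [4] * 7)
        _, m_data = bayes_update(BetaPrior(1e-8, 1e-8), w)
        assert m_data == pytest.approx(0.3, abs=1e-6)
        _, m_prior = bayes_update(BetaPrior(1e8, 1e8), w)
        assert m_prior == pytest.approx(0.5, abs=1e-6)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            BetaPrior(0.0, 1.0)
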