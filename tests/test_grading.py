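"""Grade classification: cohort assembly, leak-proof splits, evaluation,
permutation significance and additive attribution."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from replicamap.core import CommonRepresentation, SampleMeta, TissueMask
from replicamap.errors import ParameterError
from replicamap.grading import (
    CohortTable,
    audit_splits,
    build_cohort,
    cross_infer,
    evaluate,
    linear_attribution,
    make_splits,
    permutation_test,
    train_grade_model,
)


def _sample_rep(sample_id, patient, batch, grade, values, kind="section"):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    coords = np.array([[i % 4, i // 4] for i in range(n)])
    meta = SampleMeta(sample_id, kind, patient_id=patient, batch_id=batch, grade=grade)
    rep = CommonRepresentation(
        matrix=values,
        feature_mz=600.0 + np.arange(values.shape[1]) * 10.0,
        coords=coords,
        meta=meta,
    )
    ny, nx = rep.grid_shape
    return rep, TissueMask(np.ones((ny, nx), dtype=bool))


def _toy_cohort(n_patients=8, pixels=20, n_features=5, effect=3.0, seed=0,
                kind="section", n_batches=4):
    """Small synthetic cohort with one informative feature."""
    rng = np.random.default_rng(seed)
    items = []
    for p in range(n_patients):
        grade = "high" if p % 2 == 0 else "low"
        shift = effect if grade == "high" else 0.0
        X = rng.normal(0, 1, (pixels, n_features))
        X[:, 0] += shift
        items.append(
            _sample_rep(f"s{p}", f"P{p}", f"B{p % n_batches}", grade, X, kind=kind)
        )
    return build_cohort(items)


class TestBuildCohort:
    def test_row_count_sums_tissue_pixels(self):
        a = _sample_rep("a", "P0", "B0", "high", np.ones((10, 3)))
        b = _sample_rep("b", "P1", "B1", "low", np.ones((10, 3)))
        cohort = build_cohort([a, b])
        assert cohort.X.shape == (20, 3)
        assert list(cohort.meta["sample_id"].unique()) == ["a", "b"]

    def test_unlabelled_sample_excluded_with_warning(self, caplog):
        a = _sample_rep("a", "P0", "B0", "high", np.ones((4, 2)))
        b = _sample_rep("b", "P1", "B1", None, np.ones((4, 2)))
        with caplog.at_level("WARNING"):
            cohort = build_cohort([a, b])
        assert set(cohort.meta["sample_id"]) == {"a"}
        assert any("no grade" in r.message for r in caplog.records)

    def test_empty_mask_contributes_no_rows(self, caplog):
        rep, _ = _sample_rep("a", "P0", "B0", "high", np.ones((4, 2)))
        empty = TissueMask(np.zeros(rep.grid_shape, dtype=bool))
        b = _sample_rep("b", "P1", "B1", "low", np.ones((4, 2)))
        with caplog.at_level("WARNING"):
            cohort = build_cohort([(rep, empty), b])
        assert set(cohort.meta["sample_id"]) == {"b"}

    def test_features_restricted_to_lipid_range(self):
        rep, mask = _sample_rep("a", "P0", "B0", "high", np.ones((4, 3)))
        rep.feature_mz = np.array([500.0, 700.0, 950.0])
        cohort = build_cohort([(rep, mask)])
        assert np.array_equal(cohort.feature_mz, [700.0])
        assert cohort.X.shape == (4, 1)


class TestSplits:
    def test_distinct_patients_and_batches_train_on_rest(self):
        cohort = _toy_cohort(n_patients=3, n_batches=3)
        splits = make_splits(cohort)
        assert len(splits) == 3
        for split in splits:
            test_pat = cohort.meta.loc[split.test_rows[0], "patient_id"]
            train_pats = set(cohort.meta.loc[split.train_rows, "patient_id"])
            assert test_pat not in train_pats
            assert len(train_pats) == 2

    def test_shared_batch_excluded_from_training(self):
        # two samples in one batch: each split must exclude both
        items = [
            _sample_rep("a", "P0", "B0", "high", np.ones((4, 2))),
            _sample_rep("b", "P1", "B0", "low", np.ones((4, 2))),
            _sample_rep("c", "P2", "B1", "high", np.ones((4, 2))),
            _sample_rep("d", "P3", "B2", "low", np.ones((4, 2))),
        ]
        cohort = build_cohort(items)
        splits = {s.test_sample_id: s for s in make_splits(cohort)}
        train_sids = set(cohort.meta.loc[splits["a"].train_rows, "sample_id"])
        assert train_sids == {"c", "d"}

    def test_audit_detects_no_leakage_on_phantom_cohort(self, grading_cohort):
        audit = audit_splits(grading_cohort["sections"], grading_cohort["splits"])
        assert len(audit) == 23
        assert (audit["n_train"] > 0).all()

    def test_audit_raises_on_contaminated_split(self):
        cohort = _toy_cohort(n_patients=3, n_batches=3)
        splits = make_splits(cohort)
        splits[0].train_rows = np.concatenate(
            [splits[0].train_rows, splits[0].test_rows]
        )
        with pytest.raises(Exception, match="leakage"):
            audit_splits(cohort, splits)


class TestTrainModel:
    def test_separable_toy_fits_perfectly(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1]])
        y = np.array([0, 0, 1, 1])
        model = train_grade_model(X, y, seed=0)
        assert (model.predict(X) == y).all()

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            train_grade_model(np.ones((4, 2)), np.zeros(4, dtype=int))

    def test_pure_noise_auc_near_chance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2000, 4))
        y = rng.integers(0, 2, 2000)
        model = train_grade_model(X[:1000], y[:1000], seed=0)
        auc = roc_auc_score(y[1000:], model.predict_proba(X[1000:])[:, 1])
        assert abs(auc - 0.5) < 0.1

    @pytest.mark.parametrize("kind", ["tree", "boosted"])
    def test_alternative_model_kinds_fit(self, kind):
        cohort = _toy_cohort()
        model = train_grade_model(cohort.X, cohort.y, model_kind=kind, seed=0)
        assert roc_auc_score(cohort.y, model.predict_proba(cohort.X)[:, 1]) > 0.8


class TestEvaluate:
    def test_separable_cohort_perfect_auc_zero_sd(self):
        cohort = _toy_cohort(effect=50.0)
        report = evaluate(cohort, make_splits(cohort), seeds=[0, 1, 2])
        assert report.mean_auc == 1.0 and report.sd_auc == 0.0
        assert (report.per_sample["predicted_grade"] == report.per_sample["grade"]).all()

    def test_sample_level_shuffle_gives_chance_auc(self):
        cohort = _toy_cohort(n_patients=20, pixels=30, effect=3.0, seed=1)
        splits = make_splits(cohort)
        grades = cohort.meta.groupby("sample_id")["grade"].first()
        aucs = []
        for s in range(5):
            rng = np.random.default_rng(s)
            shuffled = dict(zip(grades.index, rng.permutation(grades.to_numpy())))
            report = evaluate(cohort.with_labels(shuffled), splits, seeds=[0])
            aucs.append(report.mean_auc)
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_strong_effect_phantom_cohort_auc(self, grading_cohort):
        """Leak-proof CV on the 23-patient cohort keeps AUC high and stable."""
        report = evaluate(
            grading_cohort["sections"], grading_cohort["splits"],
            seeds=list(range(3)),
        )
        assert report.mean_auc >= 0.9
        assert report.sd_auc <= 0.05

    def test_auc_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        scores = rng.normal(size=200) + y
        assert roc_auc_score(y, scores) == pytest.approx(
            roc_auc_score(y, np.exp(scores))
        )


class TestCrossInference:
    def test_identical_target_matches_source_auc(self):
        cohort = _toy_cohort(effect=3.0)
        mean_auc, sd, aucs = cross_infer(cohort, cohort, seeds=[0, 1])
        model = train_grade_model(cohort.X, cohort.y, seed=0)
        direct = roc_auc_score(cohort.y, model.predict_proba(cohort.X)[:, 1])
        assert mean_auc == pytest.approx(direct)

    def test_unrelated_target_near_chance(self):
        source = _toy_cohort(effect=3.0, seed=0)
        target = _toy_cohort(effect=0.0, seed=99, kind="replica")
        mean_auc, _sd, _ = cross_infer(source, target, seeds=[0])
        assert abs(mean_auc - 0.5) < 0.15

    def test_axis_mismatch_rejected(self):
        a = _toy_cohort(n_features=5)
        b = _toy_cohort(n_features=6)
        with pytest.raises(ParameterError):
            cross_infer(a, b, seeds=[0])

    def test_section_replica_cross_close_to_within(self, grading_cohort):
        within = evaluate(
            grading_cohort["replicas"], make_splits(grading_cohort["replicas"]),
            seeds=[0],
        ).mean_auc
        cross, _sd, _ = cross_infer(
            grading_cohort["sections"], grading_cohort["replicas"], seeds=[0]
        )
        assert abs(cross - within) <= 0.1


class TestPermutation:
    def test_unreachable_observed_gives_minimal_p(self):
        cohort = _toy_cohort(effect=50.0, n_patients=10)
        splits = make_splits(cohort)
        p, observed, medians = permutation_test(
            cohort, splits, n_perm=99, seed=0
        )
        assert observed == 1.0
        assert p == pytest.approx(1.0 / 100.0, abs=0.02)

    def test_null_cohort_p_not_significant(self):
        cohort = _toy_cohort(effect=0.0, n_patients=10, seed=3)
        splits = make_splits(cohort)
        p, _obs, _med = permutation_test(cohort, splits, n_perm=49, seed=0)
        assert p > 0.05


class TestAttribution:
    def _fit(self, cohort):
        model = train_grade_model(cohort.X, cohort.y, seed=0)
        mean = cohort.X.mean(axis=0)
        return model, linear_attribution(model, cohort.X, cohort.feature_mz, mean)

    def test_row_at_training_mean_contributes_zero(self):
        cohort = _toy_cohort()
        model = train_grade_model(cohort.X, cohort.y, seed=0)
        mean = cohort.X.mean(axis=0)
        att = linear_attribution(model, mean[None, :], cohort.feature_mz, mean)
        assert np.allclose(att.contributions, 0.0)

    def test_hand_computed_contributions(self):
        cohort = _toy_cohort(n_features=2)
        model = train_grade_model(cohort.X, cohort.y, seed=0)
        model.coef_ = np.array([[1.0, -1.0]])
        model.intercept_ = np.array([0.0])
        mean = np.zeros(2)
        att = linear_attribution(model, np.array([[2.0, 2.0]]), cohort.feature_mz, mean)
        assert np.allclose(att.contributions, [[2.0, -2.0]])
        assert att.contributions.sum() == pytest.approx(0.0)

    def test_local_accuracy_identity(self, grading_cohort):
        cohort = grading_cohort["sections"]
        model = train_grade_model(cohort.X, cohort.y, seed=0)
        mean = cohort.X.mean(axis=0)
        att = linear_attribution(model, cohort.X, cohort.feature_mz, mean)
        logits = model.decision_function(cohort.X)
        recon = att.baseline + att.contributions.sum(axis=1)
        assert np.abs(logits - recon).max() < 1e-8

    def test_planted_markers_rank_top_ten_with_correct_signs(self, grading_cohort):
        cohort = grading_cohort["sections"]
        model = train_grade_model(cohort.X, cohort.y, seed=0)
        att = linear_attribution(
            model, cohort.X, cohort.feature_mz, cohort.X.mean(axis=0)
        )
        top = att.top_features(10).set_index("mz")
        expectations = {  # marker -> sign pushing toward high grade
            885.5498: 1, 788.55: 1, 790.55: -1, 834.53: -1,
        }
        axis = cohort.feature_mz
        for mz, sign in expectations.items():
            feature = axis[int(np.argmin(np.abs(axis - mz)))]
            assert feature in top.index
            assert top.loc[feature, "sign"] == sign

    def test_nonlinear_model_falls_back_labelled(self):
        cohort = _toy_cohort()
        model = train_grade_model(cohort.X, cohort.y, model_kind="tree", seed=0)
        att = linear_attribution(
            model, cohort.X, cohort.feature_mz, cohort.X.mean(axis=0)
        )
        assert att.method == "permutation_importance"
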