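"""Single-spectrum glioma grade classification.

Each tissue pixel's spectrum (features restricted to the lipid range
m/z 600–900) is one classification instance; the label is the sample's
grade (low/high). Validation is leave-one-batch-and-patient-out: for
every test sample, training excludes all spectra sharing the test
sample's patient *or* imaging session, so neither patient identity nor
batch structure can leak. Performance is the ROC AUC over pooled
held-out spectra, repeated over random seeds; significance comes from a
sample-level label permutation test, and feature importance from exact
additive attribution of the (reference) logistic model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .core import CommonRepresentation, TissueMask
from .errors import ParameterError, ValidationError

__all__ = [
    "CohortTable",
    "CVSplit",
    "ClassifierReport",
    "AttributionResult",
    "build_cohort",
    "make_splits",
    "audit_splits",
    "train_grade_model",
    "evaluate",
    "cross_infer",
    "permutation_test",
    "linear_attribution",
]

logger = logging.getLogger(__name__)

LIPID_RANGE = (600.0, 900.0)
META_COLUMNS = ["sample_id", "patient_id", "batch_id", "kind", "grade"]


@dataclass
class CohortTable:
    """Tissue pixels × lipid features with per-row sample provenance."""

    X: np.ndarray
    feature_mz: np.ndarray
    meta: pd.DataFrame  # one row per pixel; columns META_COLUMNS

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.meta):
            raise ValidationError("feature matrix and metadata row counts differ")
        missing = set(META_COLUMNS) - set(self.meta.columns)
        if missing:
            raise ValidationError(f"cohort metadata lacks columns {sorted(missing)}")

    @property
    def y(self) -> np.ndarray:
        """Binary labels: 1 = high grade."""
        return (self.meta["grade"].to_numpy() == "high").astype(int)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.meta["sample_id"].unique()

    def with_labels(self, grade_by_sample: dict[str, str]) -> "CohortTable":
        """Copy with grades replaced per sample (used by permutation tests)."""
        meta = self.meta.copy()
        meta["grade"] = meta["sample_id"].map(grade_by_sample)
        return CohortTable(self.X, self.feature_mz, meta)


def build_cohort(
    items: list[tuple[CommonRepresentation, TissueMask]],
    mz_range: tuple[float, float] = LIPID_RANGE,
) -> CohortTable:
    """Assemble tissue pixels from preprocessed samples into one table.

    Every representation must share the feature axis and carry complete
    metadata; samples without a grade are excluded with a warning.
    """
    if not items:
        raise ParameterError("no samples supplied")
    axis = items[0][0].feature_mz
    keep_features = (axis >= mz_range[0]) & (axis < mz_range[1])
    blocks, meta_rows = [], []
    for rep, mask in items:
        if rep.feature_mz.shape != axis.shape or not np.allclose(rep.feature_mz, axis):
            raise ParameterError("samples do not share a common feature axis")
        m = rep.meta
        if m is None or m.grade is None:
            logger.warning(
                "sample %s has no grade label; excluded from the cohort",
                m.sample_id if m else "<unknown>",
            )
            continue
        tissue = mask.pixel_flags(rep.coords)
        if not tissue.any():
            logger.warning("sample %s has an empty tissue mask", m.sample_id)
            continue
        blocks.append(rep.matrix[np.ix_(tissue, np.flatnonzero(keep_features))])
        n = int(tissue.sum())
        meta_rows.append(
            pd.DataFrame(
                {
                    "sample_id": m.sample_id,
                    "patient_id": m.patient_id,
                    "batch_id": m.batch_id,
                    "kind": m.kind.value,
                    "grade": m.grade.value,
                },
                index=range(n),
            )
        )
    if not blocks:
        raise ParameterError("no labelled samples with tissue pixels")
    return CohortTable(
        X=np.vstack(blocks),
        feature_mz=axis[keep_features],
        meta=pd.concat(meta_rows, ignore_index=True),
    )


@dataclass
class CVSplit:
    """One leave-one-batch-and-patient-out fold."""

    test_sample_id: str
    test_rows: np.ndarray
    train_rows: np.ndarray
    excluded_rows: np.ndarray  # rows dropped for sharing patient or batch with test


def make_splits(cohort: CohortTable) -> list[CVSplit]:
    """One split per sample; training excludes the test patient and batch."""
    meta = cohort.meta
    if meta["patient_id"].nunique() < 2 or meta["batch_id"].nunique() < 2:
        raise ParameterError("need at least two patients and two batches")
    splits = []
    for sample_id, rows in meta.groupby("sample_id").groups.items():
        test_rows = np.asarray(rows)
        patient = meta.loc[test_rows[0], "patient_id"]
        batch = meta.loc[test_rows[0], "batch_id"]
        conflict = (meta["patient_id"] == patient) | (meta["batch_id"] == batch)
        train_rows = np.flatnonzero(~conflict)
        excluded = np.setdiff1d(np.flatnonzero(conflict), test_rows)
        if train_rows.size == 0:
            raise ParameterError(
                f"split for sample {sample_id} would have an empty training set"
            )
        splits.append(
            CVSplit(
                test_sample_id=str(sample_id),
                test_rows=test_rows,
                train_rows=train_rows,
                excluded_rows=excluded,
            )
        )
    return splits


def audit_splits(cohort: CohortTable, splits: list[CVSplit]) -> pd.DataFrame:
    """Leakage audit: assert no train row shares patient or batch with test.

    Returns a per-split summary; raises :class:`ValidationError` on any
    leakage.
    """
    rows = []
    for split in splits:
        test_patients = set(cohort.meta.loc[split.test_rows, "patient_id"])
        test_batches = set(cohort.meta.loc[split.test_rows, "batch_id"])
        train_patients = set(cohort.meta.loc[split.train_rows, "patient_id"])
        train_batches = set(cohort.meta.loc[split.train_rows, "batch_id"])
        patient_leak = test_patients & train_patients
        batch_leak = test_batches & train_batches
        if patient_leak or batch_leak:
            raise ValidationError(
                f"leakage in split {split.test_sample_id}: "
                f"patients {patient_leak}, batches {batch_leak}"
            )
        rows.append(
            {
                "test_sample_id": split.test_sample_id,
                "n_test": split.test_rows.size,
                "n_train": split.train_rows.size,
                "n_excluded": split.excluded_rows.size,
            }
        )
    return pd.DataFrame(rows)


_LOGISTIC_DEFAULTS = {"C": 1.0, "max_iter": 2000}
_TREE_DEFAULTS = {"max_depth": 6}
_BOOSTED_DEFAULTS = {"n_estimators": 200, "learning_rate": 0.1, "max_depth": 4}


def train_grade_model(
    X: np.ndarray,
    y: np.ndarray,
    model_kind: str = "logistic",
    hyperparams: dict | None = None,
    seed: int = 0,
):
    """Fit one grade classifier; deterministic given the seed.

    ``logistic`` (L2-regularized, class-weighted) is the reference model;
    ``tree`` and ``boosted`` (XGBoost if importable, otherwise
    scikit-learn histogram gradient boosting) are optional variants.
    """
    if len(np.unique(y)) < 2:
        raise ParameterError("training set contains a single class")
    hp = dict(hyperparams or {})
    if model_kind == "logistic":
        params = {**_LOGISTIC_DEFAULTS, **hp}
        # L2 penalty (sklearn's default) with strength 1/C
        model = LogisticRegression(
            class_weight="balanced",
            random_state=seed,
            **params,
        )
    elif model_kind == "tree":
        params = {**_TREE_DEFAULTS, **hp}
        model = DecisionTreeClassifier(
            class_weight="balanced", random_state=seed, **params
        )
    elif model_kind == "boosted":
        params = {**_BOOSTED_DEFAULTS, **hp}
        try:
            from xgboost import XGBClassifier

            model = XGBClassifier(
                n_estimators=params["n_estimators"],
                learning_rate=params["learning_rate"],
                max_depth=params["max_depth"],
                random_state=seed,
                verbosity=0,
            )
        except ImportError:  # pragma: no cover - depends on optional extra
            from sklearn.ensemble import HistGradientBoostingClassifier

            model = HistGradientBoostingClassifier(
                max_iter=params["n_estimators"],
                learning_rate=params["learning_rate"],
                max_depth=params["max_depth"],
                random_state=seed,
            )
    else:
        raise ParameterError(f"unknown model kind {model_kind!r}")
    model.fit(X, y)
    return model


def tune_hyperparams(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    model_kind: str = "logistic",
    budget: int = 10,
    seed: int = 0,
) -> dict:
    """Seeded random search over a declared grid, optimizing held-out AUC.

    The validation fold is a group-aware 80/20 split (groups = sample
    ids) so tuning respects the no-pixel-leakage rule.
    """
    from sklearn.model_selection import GroupShuffleSplit

    rng = np.random.default_rng(seed)
    splitter = GroupShuffleSplit(n_splits=1, test_size=0.2, random_state=seed)
    (tr, va), = splitter.split(X, y, groups=groups)
    if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
        return {}
    best_hp, best_auc = {}, -np.inf
    for _ in range(budget):
        if model_kind == "logistic":
            hp = {"C": float(10 ** rng.uniform(-3, 3))}
        elif model_kind == "tree":
            hp = {"max_depth": int(rng.integers(2, 12))}
        else:
            hp = {
                "n_estimators": int(rng.integers(50, 400)),
                "learning_rate": float(10 ** rng.uniform(-2, -0.3)),
                "max_depth": int(rng.integers(2, 8)),
            }
        model = train_grade_model(X[tr], y[tr], model_kind, hp, seed)
        auc = roc_auc_score(y[va], _scores(model, X[va]))
        if auc > best_auc:
            best_hp, best_auc = hp, auc
    return best_hp


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


@dataclass
class ClassifierReport:
    """Multi-seed cross-validated performance summary."""

    per_seed_auc: list[float]
    mean_auc: float
    sd_auc: float
    per_sample: pd.DataFrame  # sample_id, grade, mean_probability, predicted_grade
    skipped_splits: list[str] = field(default_factory=list)
    skipped_seeds: list[int] = field(default_factory=list)
    model_kind: str = "logistic"

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "per_seed_auc": list(map(float, self.per_seed_auc)),
            "mean_auc": float(self.mean_auc),
            "sd_auc": float(self.sd_auc),
            "skipped_splits": self.skipped_splits,
            "skipped_seeds": self.skipped_seeds,
        }


def evaluate(
    cohort: CohortTable,
    splits: list[CVSplit],
    model_kind: str = "logistic",
    seeds: list[int] | None = None,
    hyperparams: dict | None = None,
    tune_budget: int = 0,
) -> ClassifierReport:
    """Cross-validated pixel-level ROC AUC, repeated across seeds.

    Per seed: fit one model per split on its training rows, score the
    held-out rows, pool all held-out scores, and compute the pixel-level
    AUC. Per-sample grade calls are the mean predicted probability over
    the sample's pixels (across seeds), thresholded at 0.5. Seeds with
    degenerate pooled labels are skipped and reported.
    """
    if seeds is None:
        seeds = list(range(100))
    y = cohort.y
    per_seed_auc: list[float] = []
    skipped_seeds: list[int] = []
    skipped_splits: set[str] = set()
    sample_prob_sum = pd.Series(0.0, index=cohort.sample_ids)
    sample_prob_n = pd.Series(0, index=cohort.sample_ids)

    for seed in seeds:
        pooled_scores = np.full(len(y), np.nan)
        for split in splits:
            y_train = y[split.train_rows]
            if len(np.unique(y_train)) < 2:
                skipped_splits.add(split.test_sample_id)
                continue
            hp = dict(hyperparams or {})
            if tune_budget > 0:
                tuned = tune_hyperparams(
                    cohort.X[split.train_rows],
                    y_train,
                    cohort.meta.loc[split.train_rows, "sample_id"].to_numpy(),
                    model_kind,
                    budget=tune_budget,
                    seed=seed,
                )
                hp.update(tuned)
            model = train_grade_model(
                cohort.X[split.train_rows], y_train, model_kind, hp, seed
            )
            scores = _scores(model, cohort.X[split.test_rows])
            pooled_scores[split.test_rows] = scores
            sample_prob_sum[split.test_sample_id] += float(np.mean(scores))
            sample_prob_n[split.test_sample_id] += 1
        have = ~np.isnan(pooled_scores)
        if have.sum() == 0 or len(np.unique(y[have])) < 2:
            skipped_seeds.append(seed)
            continue
        per_seed_auc.append(float(roc_auc_score(y[have], pooled_scores[have])))

    mean_prob = (sample_prob_sum / sample_prob_n.replace(0, np.nan)).rename(
        "mean_probability"
    )
    grades = cohort.meta.groupby("sample_id")["grade"].first()
    per_sample = pd.DataFrame(
        {
            "grade": grades,
            "mean_probability": mean_prob,
            "predicted_grade": np.where(mean_prob > 0.5, "high", "low"),
        }
    ).reset_index(names="sample_id")
    if not per_seed_auc:
        raise ParameterError("no seed produced a defined AUC")
    return ClassifierReport(
        per_seed_auc=per_seed_auc,
        mean_auc=float(np.mean(per_seed_auc)),
        sd_auc=float(np.std(per_seed_auc)),
        per_sample=per_sample,
        skipped_splits=sorted(skipped_splits),
        skipped_seeds=skipped_seeds,
        model_kind=model_kind,
    )


def cross_infer(
    source: CohortTable,
    target: CohortTable,
    model_kind: str = "logistic",
    seeds: list[int] | None = None,
    hyperparams: dict | None = None,
) -> tuple[float, float, list[float]]:
    """Train on one specimen kind, score the other (pooled pixel AUC).

    Per seed a model is fitted on all source rows and evaluated on all
    target rows. Returns (mean, sd, per-seed AUCs).
    """
    if source.feature_mz.shape != target.feature_mz.shape or not np.allclose(
        source.feature_mz, target.feature_mz
    ):
        raise ParameterError("source and target cohorts use different feature axes")
    if seeds is None:
        seeds = list(range(100))
    aucs = []
    for seed in seeds:
        model = train_grade_model(source.X, source.y, model_kind, hyperparams, seed)
        aucs.append(float(roc_auc_score(target.y, _scores(model, target.X))))
    return float(np.mean(aucs)), float(np.std(aucs)), aucs


def permutation_test(
    cohort: CohortTable,
    splits: list[CVSplit],
    model_kind: str = "logistic",
    n_perm: int = 199,
    seed: int = 0,
    eval_seeds: tuple[int, ...] = (0,),
) -> tuple[float, float, np.ndarray]:
    """Sample-level label-permutation significance of the classifier.

    Grades are shuffled across samples (all pixels of a sample move
    together), the cross-validated median AUC recomputed per
    permutation, and the p-value is
    ``(1 + #{perm median AUC >= observed}) / (n_perm + 1)``.

    Returns (p_value, observed median AUC, permuted median AUCs).
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    observed = float(
        np.median(evaluate(cohort, splits, model_kind, list(eval_seeds)).per_seed_auc)
    )
    grades = cohort.meta.groupby("sample_id")["grade"].first()
    rng = np.random.default_rng(seed)
    perm_medians = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = dict(zip(grades.index, rng.permutation(grades.to_numpy())))
        perm_cohort = cohort.with_labels(shuffled)
        try:
            report = evaluate(perm_cohort, splits, model_kind, list(eval_seeds))
            perm_medians[i] = np.median(report.per_seed_auc)
        except ParameterError:
            # a permutation can leave every split single-class; count it as
            # chance-level so it never inflates significance
            perm_medians[i] = 0.5
    p = (1.0 + float(np.sum(perm_medians >= observed))) / (n_perm + 1.0)
    return p, observed, perm_medians


@dataclass
class AttributionResult:
    """Exact additive feature attribution for a linear model.

    For a logistic model the contribution of feature j on row x is
    ``w_j (x_j - mean_j)`` with ``mean_j`` the training-set feature
    mean; contributions plus the baseline reproduce the model logit
    exactly (local accuracy). Positive values push toward the
    high-grade class.
    """

    contributions: np.ndarray  # rows × features
    baseline: float
    table: pd.DataFrame  # mz, mean_abs_contribution, sign, rank
    method: str = "linear"

    def top_features(self, n: int = 10) -> pd.DataFrame:
        return self.table.nsmallest(n, "rank")


def linear_attribution(
    model,
    X: np.ndarray,
    feature_mz: np.ndarray,
    training_mean: np.ndarray,
) -> AttributionResult:
    """Additive per-feature contributions for a fitted model.

    Exact for linear models; non-linear models fall back to permutation
    importance, explicitly labelled in ``method``.
    """
    if isinstance(model, LogisticRegression):
        w = model.coef_.ravel()
        contributions = (X - training_mean) * w
        baseline = float(model.intercept_[0] + w @ training_mean)
        mean_abs = np.abs(contributions).mean(axis=0)
        table = pd.DataFrame(
            {
                "mz": feature_mz,
                "mean_abs_contribution": mean_abs,
                "sign": np.sign(w).astype(int),
            }
        )
        table["rank"] = (
            table["mean_abs_contribution"].rank(ascending=False, method="first").astype(int)
        )
        return AttributionResult(contributions, baseline, table, method="linear")

    from sklearn.inspection import permutation_importance

    logger.warning(
        "model %s is not linear; falling back to permutation importance",
        type(model).__name__,
    )
    y_hat = model.predict(X)
    result = permutation_importance(model, X, y_hat, n_repeats=5, random_state=0)
    table = pd.DataFrame(
        {
            "mz": feature_mz,
            "mean_abs_contribution": result.importances_mean,
            "sign": 0,
        }
    )
    table["rank"] = (
        table["mean_abs_contribution"].rank(ascending=False, method="first").astype(int)
    )
    return AttributionResult(
        np.zeros_like(X), 0.0, table, method="permutation_importance"
    )
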