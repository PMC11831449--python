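"""Family-aware nested cross-validation for phenotype prediction.

The outer loop is a k-fold CV whose folds never split a family; per fold the
feature models are fitted on training subjects only, hyperparameters chosen
by an inner family-aware grid search, and held-out subjects projected
through the training models (see :mod:`topf.features`).  Also houses the
scoring rules, subject-level permutation test, Benjamini–Hochberg FDR, the
corrected resampled paired t-test, and data-length utilities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import Ridge, RidgeClassifier
from sklearn.metrics import balanced_accuracy_score
from sklearn.svm import SVC, SVR
from statsmodels.stats.multitest import multipletests

from topf.dataio import RunConfig
from topf.features import FeatureMatrix, extract_train_features, project_test_features
from topf.synthdata import ClipDataset, CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "FoldScheme",
    "FoldRecord",
    "PredictionResult",
    "make_family_folds",
    "run_nested_cv",
    "score",
    "permutation_test",
    "fdr_adjust",
    "corrected_resampled_ttest",
    "length_sweep",
    "concatenate_clips",
]


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------

@dataclass
class FoldScheme:
    """Assignment of every subject to one of k folds, families intact."""

    repeat_index: int
    assignment: pd.Series  # subject_id -> fold in 1..k
    k: int
    seed: int

    def test_subjects(self, fold: int) -> list[str]:
        return self.assignment.index[self.assignment == fold].tolist()

    def train_subjects(self, fold: int) -> list[str]:
        return self.assignment.index[self.assignment != fold].tolist()


def make_family_folds(
    cohort: CohortTable, k: int, seed: int, repeat_index: int = 0
) -> FoldScheme:
    """Shuffle families by seed, then assign each to the currently smallest
    fold, so that all members of a family share a fold."""
    families = cohort.table.groupby("family_id")["subject_id"].apply(list)
    if len(families) < k:
        raise ValueError(f"{len(families)} families cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(families))
    sizes = np.zeros(k, dtype=int)
    assignment: dict[str, int] = {}
    for idx in order:
        members = families.iloc[idx]
        fold = int(np.argmin(sizes))  # ties -> lowest fold index
        sizes[fold] += len(members)
        for subject in members:
            assignment[subject] = fold + 1
    series = pd.Series(assignment, name="fold").reindex(cohort.subject_ids)
    return FoldScheme(repeat_index=repeat_index, assignment=series, k=k, seed=seed)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def score(predicted, observed, task: str) -> float:
    """Balanced accuracy (classification) or Pearson r (regression)."""
    predicted = np.asarray(predicted)
    observed = np.asarray(observed)
    if predicted.shape != observed.shape:
        raise ValueError("predicted/observed length mismatch")
    if len(observed) < 2:
        raise ValueError("need at least 2 observations")
    if task == "classification":
        return float(balanced_accuracy_score(observed, predicted))
    if task == "regression":
        if np.ptp(observed) == 0:
            raise ValueError("observed vector is constant; correlation undefined")
        r = stats.pearsonr(predicted.astype(float), observed.astype(float)).statistic
        return float(r)
    raise ValueError(f"unknown task {task!r}")


def _safe_inner_score(predicted, observed, task: str) -> float:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            value = score(predicted, observed, task)
    except ValueError:
        return -np.inf
    return value if np.isfinite(value) else -np.inf


# ---------------------------------------------------------------------------
# estimators and grids
# ---------------------------------------------------------------------------

def _median_heuristic_gamma(x: np.ndarray, max_rows: int = 200) -> float:
    """1 / (2 * median squared pairwise distance) on (a subsample of) x."""
    if len(x) > max_rows:
        x = x[np.linspace(0, len(x) - 1, max_rows, dtype=int)]
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    if med <= 0:
        med = 1.0
    return 1.0 / (2.0 * med)


def _grid(config: RunConfig, x_train: np.ndarray) -> list[dict]:
    """Candidate hyperparameters, ordered from stronger to weaker
    regularisation so that score ties resolve toward stronger."""
    name = config.estimator
    overrides = config.grids.get(name) if config.grids else None
    if overrides is not None:
        return [dict(p) for p in overrides]
    if name == "ridge":
        return [{"alpha": a} for a in np.logspace(3, -3, 7)]
    if name == "svm_linear":
        return [{"C": c} for c in np.logspace(-2, 2, 5)]
    if name == "svm_rbf":
        g0 = _median_heuristic_gamma(x_train)
        return [
            {"C": c, "gamma": g}
            for c in np.logspace(-2, 2, 5)
            for g in (0.1 * g0, g0, 10 * g0)
        ]
    if name == "rf":
        return [{"max_features": m} for m in ("sqrt", 0.1, 0.3)]
    raise ValueError(f"unknown estimator {name!r}")


def _make_estimator(config: RunConfig, params: dict, seed: int):
    name, task = config.estimator, config.task
    if name == "ridge":
        cls = RidgeClassifier if task == "classification" else Ridge
        return cls(alpha=params["alpha"])
    if name == "svm_linear":
        if task == "classification":
            return SVC(kernel="linear", C=params["C"])
        return SVR(kernel="linear", C=params["C"])
    if name == "svm_rbf":
        if task == "classification":
            return SVC(kernel="rbf", C=params["C"], gamma=params["gamma"])
        return SVR(kernel="rbf", C=params["C"], gamma=params["gamma"])
    if name == "rf":
        cls = RandomForestClassifier if task == "classification" else RandomForestRegressor
        return cls(
            n_estimators=config.rf_n_trees,
            max_features=params["max_features"],
            random_state=seed,
            n_jobs=1,
        )
    raise ValueError(f"unknown estimator {name!r}")


# ---------------------------------------------------------------------------
# nested CV
# ---------------------------------------------------------------------------

@dataclass
class FoldRecord:
    repeat: int
    fold: int
    score: float
    best_params: dict
    n_train: int
    n_test: int
    test_subjects: list[str]
    predictions: np.ndarray
    observed: np.ndarray
    estimator: object = field(default=None, repr=False)
    feature_models: dict = field(default=None, repr=False)
    train_features: FeatureMatrix = field(default=None, repr=False)
    test_features: FeatureMatrix = field(default=None, repr=False)


@dataclass
class PredictionResult:
    phenotype: str
    estimator: str
    n_pcs: int
    task: str
    records: list[FoldRecord]
    config: RunConfig

    def scores(self) -> np.ndarray:
        return np.array([r.score for r in self.records])

    def mean_score(self) -> float:
        return float(np.nanmean(self.scores()))

    def fold_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "repeat": [r.repeat for r in self.records],
                "fold": [r.fold for r in self.records],
                "score": [r.score for r in self.records],
                "n_train": [r.n_train for r in self.records],
                "n_test": [r.n_test for r in self.records],
            }
        )

    def out_of_fold_predictions(self, repeat: int = 0) -> pd.Series:
        chunks = {}
        for rec in self.records:
            if rec.repeat == repeat:
                chunks.update(dict(zip(rec.test_subjects, rec.predictions)))
        return pd.Series(chunks, name="prediction")


def _fold_features(data, train_ids, test_ids, config):
    """Leakage-free (train, test) feature pair for one outer fold."""
    if isinstance(data, ClipDataset):
        fm_train, models = extract_train_features(
            data.subset_subjects(train_ids), config.n_pcs
        )
        fm_test = project_test_features(
            data.subset_subjects(test_ids), models, fm_train,
            norm=config.test_feature_norm,
        )
        return fm_train, fm_test, models
    if isinstance(data, FeatureMatrix):
        frame = data.to_frame()
        train = frame.loc[train_ids].to_numpy()
        test = frame.loc[test_ids].to_numpy()
        mean, sd = train.mean(axis=0), train.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        fm_train = FeatureMatrix((train - mean) / sd, list(data.feature_index),
                                 list(train_ids), mean_=mean, sd_=sd)
        fm_test = FeatureMatrix((test - mean) / sd, list(data.feature_index),
                                list(test_ids), mean_=mean, sd_=sd)
        return fm_train, fm_test, None
    raise TypeError("data must be a ClipDataset or FeatureMatrix")


def _inner_select(
    x: np.ndarray, y: np.ndarray, train_cohort: CohortTable, config: RunConfig,
    seed: int,
) -> dict:
    candidates = _grid(config, x)
    if len(candidates) == 1:
        return candidates[0]
    k = min(config.k_inner,
            train_cohort.table["family_id"].nunique())
    scheme = make_family_folds(train_cohort, k, seed)
    index = {s: i for i, s in enumerate(train_cohort.subject_ids)}
    splits = []
    for fold in range(1, k + 1):
        te = [index[s] for s in scheme.test_subjects(fold)]
        tr = [index[s] for s in scheme.train_subjects(fold)]
        if config.task == "classification" and len(np.unique(y[tr])) < 2:
            continue
        splits.append((tr, te))
    best, best_score = candidates[0], -np.inf
    for params in candidates:
        fold_scores = []
        for tr, te in splits:
            est = _make_estimator(config, params, seed)
            est.fit(x[tr], y[tr])
            fold_scores.append(_safe_inner_score(est.predict(x[te]), y[te],
                                                 config.task))
        mean = np.mean(fold_scores) if fold_scores else -np.inf
        if mean > best_score:  # strict: ties keep the earlier (stronger) entry
            best, best_score = params, mean
    return best


def run_nested_cv(data, cohort: CohortTable, config: RunConfig) -> PredictionResult:
    """Repeated family-aware nested CV of one clip (or feature matrix).

    Per outer fold, features are fitted on the training subjects only and the
    held-out subjects are projected through those models; an inner
    family-aware ``k_inner``-fold grid search selects the regularisation.
    Deterministic given ``config.seed``.
    """
    y_all = pd.Series(cohort.phenotype(config.phenotype),
                      index=cohort.subject_ids)
    records: list[FoldRecord] = []
    for rep in range(config.n_repeats):
        scheme = make_family_folds(cohort, config.k_outer,
                                   seed=config.seed + rep, repeat_index=rep)
        for fold in range(1, config.k_outer + 1):
            train_ids = scheme.train_subjects(fold)
            test_ids = scheme.test_subjects(fold)
            y_train = y_all.loc[train_ids].to_numpy()
            y_test = y_all.loc[test_ids].to_numpy()
            if config.task == "classification" and len(np.unique(y_train)) < 2:
                logger.warning("repeat %d fold %d: single-class training set, "
                               "fold skipped", rep, fold)
                continue
            fm_train, fm_test, models = _fold_features(
                data, train_ids, test_ids, config
            )
            fold_seed = config.seed + 7919 * rep + 104729 * fold
            params = _inner_select(fm_train.values, y_train,
                                   cohort.subset(train_ids), config, fold_seed)
            est = _make_estimator(config, params, fold_seed)
            est.fit(fm_train.values, y_train)
            predictions = est.predict(fm_test.values)
            try:
                fold_score = score(predictions, y_test, config.task)
            except ValueError:
                fold_score = np.nan
            records.append(
                FoldRecord(
                    repeat=rep,
                    fold=fold,
                    score=fold_score,
                    best_params=params,
                    n_train=len(train_ids),
                    n_test=len(test_ids),
                    test_subjects=test_ids,
                    predictions=np.asarray(predictions),
                    observed=y_test,
                    estimator=est if config.keep_models else None,
                    feature_models=models if config.keep_models else None,
                    train_features=fm_train if config.keep_models else None,
                    test_features=fm_test if config.keep_models else None,
                )
            )
    return PredictionResult(
        phenotype=config.phenotype,
        estimator=config.estimator,
        n_pcs=config.n_pcs,
        task=config.task,
        records=records,
        config=config,
    )


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def permutation_test(pipeline, labels, n_perm: int, seed: int,
                     observed_score: float | None = None):
    """Label-shuffling significance test of a prediction pipeline.

    ``pipeline`` maps a label vector to a performance score and is rerun in
    full for every permutation; labels are shuffled at subject level.
    Returns ``(p, observed, permuted_scores)`` with
    p = #{permuted >= observed} / n_perm.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    if observed_score is None:
        observed_score = pipeline(labels)
    rng = np.random.default_rng(seed)
    permuted = np.array(
        [pipeline(rng.permutation(labels)) for _ in range(n_perm)]
    )
    p = float(np.mean(permuted >= observed_score))
    return p, float(observed_score), permuted


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def corrected_resampled_ttest(scores_a, scores_b, n_train: int, n_test: int):
    """Paired t-test over CV folds with the fold-overlap variance correction.

    t = mean(d) / sqrt((1/k + n_test/n_train) * var(d)) with unbiased var and
    k - 1 degrees of freedom; two-sided p.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score lists must have equal length")
    k = len(a)
    if k < 2:
        raise ValueError("need at least 2 folds")
    d = a - b
    var = d.var(ddof=1)
    if var == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t = d.mean() / np.sqrt((1.0 / k + n_test / n_train) * var)
    p = 2.0 * stats.t.sf(abs(t), df=k - 1)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# data length
# ---------------------------------------------------------------------------

def sweep_lengths(total_trs: int, start: int, step: int) -> list[int]:
    if start < 1 or step < 1:
        raise ValueError("start and step must be positive")
    if start > total_trs:
        raise ValueError("start exceeds the total TR count")
    return list(range(start, total_trs + 1, step))


def length_sweep(
    dataset: ClipDataset, start: int, step: int, cohort: CohortTable,
    config: RunConfig,
) -> dict[int, PredictionResult]:
    """One nested-CV run per data length, truncating from the end."""
    out = {}
    for length in sweep_lengths(dataset.n_trs, start, step):
        out[length] = run_nested_cv(dataset.take_trs(length), cohort, config)
    return out


def concatenate_clips(
    clips: list[ClipDataset], target_lengths: list[int]
) -> list[ClipDataset]:
    """Concatenate clips along time (presentation order), truncate to each
    target length."""
    if not clips:
        raise ValueError("need at least one clip")
    subjects = {tuple(c.subject_ids) for c in clips}
    rois = {tuple(c.roi_ids) for c in clips}
    if len(subjects) != 1 or len(rois) != 1:
        raise ValueError("clips must share subject order and ROI set")
    combined = np.concatenate([c.data for c in clips], axis=2)
    total = combined.shape[2]
    out = []
    for target in target_lengths:
        if target < 1 or target > total:
            raise ValueError(f"target length {target} outside [1, {total}]")
        out.append(
            ClipDataset(
                clip_id=f"concat-{target}",
                data=combined[:, :, :target].copy(),
                subject_ids=list(clips[0].subject_ids),
                roi_ids=list(clips[0].roi_ids),
                roi_network=list(clips[0].roi_network),
                tr_seconds=clips[0].tr_seconds,
            )
        )
    return out
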