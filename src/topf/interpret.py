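"""Model interpretation: permutation importance, predictive-feature sets,
Jaccard overlap, consistency across clips, and sign-harmonised cross-clip
model transfer."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from topf.features import FeatureMatrix
from topf.prediction import PredictionResult, score
from topf.synchrony import SharedResponseModel, apply_sign_convention

logger = logging.getLogger(__name__)

__all__ = [
    "ImportanceMap",
    "permutation_importance",
    "aggregate_importance",
    "jaccard",
    "consistency_map",
    "harmonise_signs",
    "cross_predict",
    "cross_predict_matrix",
]


@dataclass
class ImportanceMap:
    """Mean permutation importance per feature plus ROI-level predictive flags."""

    mean_importance: np.ndarray
    feature_index: list[tuple[str, int]]
    n_shuffles: int
    n_models: int
    roi_rule: str = "any"

    def feature_frame(self) -> pd.DataFrame:
        rois, pcs = zip(*self.feature_index)
        return pd.DataFrame(
            {"roi_id": rois, "pc_rank": pcs, "importance": self.mean_importance}
        )

    def predictive_rois(self) -> set[str]:
        """ROIs flagged predictive: positive mean importance combined over the
        ROI's PC features by the configured rule (any / all / sum)."""
        frame = self.feature_frame()
        grouped = frame.groupby("roi_id")["importance"]
        if self.roi_rule == "any":
            flags = grouped.apply(lambda v: bool((v > 0).any()))
        elif self.roi_rule == "all":
            flags = grouped.apply(lambda v: bool((v > 0).all()))
        elif self.roi_rule == "sum":
            flags = grouped.sum() > 0
        else:
            raise ValueError(f"unknown roi_rule {self.roi_rule!r}")
        return set(flags.index[flags])


def permutation_importance(
    model,
    test_features: FeatureMatrix,
    observed,
    task: str,
    n_shuffles: int,
    seed: int,
) -> np.ndarray:
    """Mean drop in test score when one feature column is shuffled.

    importance[j] = mean over shuffles of (baseline − score with column j
    permuted across subjects); the baseline is computed once on unshuffled
    data.  Seed-deterministic.
    """
    x = test_features.values
    observed = np.asarray(observed)
    if x.shape[0] != len(observed):
        raise ValueError("feature rows do not match observed labels")
    n_expected = getattr(model, "n_features_in_", x.shape[1])
    if n_expected != x.shape[1]:
        raise ValueError("feature layout does not match the fitted model")
    def _score(predictions) -> float:
        # constant predictions make the correlation score undefined; treat
        # such models as scoring 0 so their importances are exactly 0
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                value = score(predictions, observed, task)
        except ValueError:
            return 0.0
        return value if np.isfinite(value) else 0.0

    baseline = _score(model.predict(x))
    rng = np.random.default_rng(seed)
    n, p = x.shape
    importances = np.zeros(p)
    for j in range(p):
        drop = 0.0
        for _ in range(n_shuffles):
            perm = rng.permutation(n)
            shuffled = x.copy()
            shuffled[:, j] = x[perm, j]
            drop += baseline - _score(model.predict(shuffled))
        importances[j] = drop / n_shuffles
    return importances


def aggregate_importance(
    per_model_importances: list[np.ndarray],
    feature_index: list[tuple[str, int]],
    n_shuffles: int,
    roi_rule: str = "any",
) -> ImportanceMap:
    """Elementwise mean of per-model importance vectors."""
    if not per_model_importances:
        raise ValueError("need at least one importance vector")
    stacked = np.vstack(per_model_importances)
    if stacked.shape[1] != len(feature_index):
        raise ValueError("inconsistent feature layouts")
    return ImportanceMap(
        mean_importance=stacked.mean(axis=0),
        feature_index=list(feature_index),
        n_shuffles=n_shuffles,
        n_models=stacked.shape[0],
        roi_rule=roi_rule,
    )


def jaccard(set_a, set_b) -> float:
    """|A∩B| / |A∪B|; two empty sets give 0 (with a warning)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        logger.warning("Jaccard of two empty sets defined as 0")
        return 0.0
    return len(a & b) / len(union)


def consistency_map(predictive_sets: list[set]) -> set:
    """ROIs predictive in strictly more than half of the clips."""
    if not predictive_sets:
        raise ValueError("need at least one clip's predictive set")
    counts: dict = {}
    for s in predictive_sets:
        for roi in s:
            counts[roi] = counts.get(roi, 0) + 1
    half = len(predictive_sets) / 2.0
    return {roi for roi, c in counts.items() if c > half}


def harmonise_signs(
    model: SharedResponseModel, features: FeatureMatrix | None = None
) -> tuple[SharedResponseModel, FeatureMatrix | None]:
    """Flip PCs (and matching feature columns) whose largest-magnitude
    loading is negative; idempotent."""
    timecourses, loadings, flipped = apply_sign_convention(
        model.pc_timecourses, model.train_loadings
    )
    new_model = replace(
        model,
        pc_timecourses=timecourses,
        train_loadings=loadings,
        sign_flipped=model.sign_flipped ^ flipped,
    )
    new_features = None
    if features is not None:
        values = features.values.copy()
        for k in range(model.n_pcs):
            if not flipped[k]:
                continue
            for j, (roi, pc) in enumerate(features.feature_index):
                if roi == model.roi_id and pc == k + 1:
                    values[:, j] = -values[:, j]
        new_features = FeatureMatrix(
            values, list(features.feature_index), list(features.subject_ids),
            mean_=features.mean_, sd_=features.sd_,
        )
    return new_model, new_features


def cross_predict(
    result_a: PredictionResult, result_b: PredictionResult
) -> np.ndarray:
    """Apply clip A's per-fold models to clip B's matching test features.

    Both results must come from identical fold schemes (same subjects per
    fold).  B's test subjects are projected through B's OWN training-fold
    models — sign conventions were applied at fit time — then scored by A's
    fitted estimator.  Returns per-fold scores in record order.
    """
    if len(result_a.records) != len(result_b.records):
        raise ValueError("fold counts differ between clips")
    scores = []
    for rec_a, rec_b in zip(result_a.records, result_b.records):
        if (rec_a.repeat, rec_a.fold) != (rec_b.repeat, rec_b.fold):
            raise ValueError("fold schemes are not aligned")
        if rec_a.test_subjects != rec_b.test_subjects:
            raise ValueError(
                f"fold {rec_a.fold} (repeat {rec_a.repeat}): test subjects differ"
            )
        if rec_a.estimator is None or rec_b.test_features is None:
            raise ValueError("results must be run with keep_models=True")
        predictions = rec_a.estimator.predict(rec_b.test_features.values)
        scores.append(score(predictions, rec_b.observed, result_a.task))
    return np.asarray(scores)


def cross_predict_matrix(results: dict[str, PredictionResult]) -> pd.DataFrame:
    """Clip × clip mean cross-prediction scores (rows: model source A,
    columns: data target B); diagonal equals within-clip performance."""
    clip_ids = list(results)
    out = pd.DataFrame(np.nan, index=clip_ids, columns=clip_ids)
    for a in clip_ids:
        for b in clip_ids:
            out.loc[a, b] = float(np.mean(cross_predict(results[a], results[b])))
    return out
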