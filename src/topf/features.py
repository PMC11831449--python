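"""Loading-based feature matrices for training and held-out subjects.

Training subjects contribute their PCA loadings directly; held-out subjects
are projected as the Pearson correlation between their time series and the
component time courses learned on the training sample.  All normalisation
statistics come from the training sample only, so test features never feed
back into the models (leakage freedom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from topf.synchrony import SharedResponseModel, fit_shared_response
from topf.synthdata import ClipDataset

logger = logging.getLogger(__name__)

__all__ = ["FeatureMatrix", "extract_train_features", "project_test_features"]


@dataclass
class FeatureMatrix:
    """subjects × (roi, pc) feature values with training normalisation stats."""

    values: np.ndarray
    feature_index: list[tuple[str, int]]  # (roi_id, pc_rank starting at 1)
    subject_ids: list[str]
    mean_: np.ndarray = field(default=None)
    sd_: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.feature_index)):
            raise ValueError("values shape inconsistent with index")

    @property
    def n_features(self) -> int:
        return len(self.feature_index)

    @property
    def column_names(self) -> list[str]:
        return [f"{roi}:PC{pc}" for roi, pc in self.feature_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids,
                            columns=self.column_names)

    def columns_for_roi(self, roi_id: str) -> list[int]:
        return [j for j, (roi, _) in enumerate(self.feature_index) if roi == roi_id]


def extract_train_features(
    train: ClipDataset, n_pcs: int
) -> tuple[FeatureMatrix, dict[str, SharedResponseModel]]:
    """Fit one shared-response model per ROI and assemble loading features.

    Features are z-scored per column with the training mean/sd, which are
    stored on the returned matrix.  ROIs containing a constant series are
    dropped with a warning and absent from the feature index.
    """
    if n_pcs not in (1, 2):
        raise ValueError("n_pcs must be 1 or 2")
    if train.n_subjects < 10:
        raise ValueError("need at least 10 training subjects")
    degenerate = train.degenerate_rois()
    models: dict[str, SharedResponseModel] = {}
    columns, index = [], []
    for r in range(train.n_rois):
        roi = train.roi_ids[r]
        if degenerate[r]:
            logger.warning("dropping degenerate ROI %s from feature space", roi)
            continue
        model = fit_shared_response(train.data[:, r, :], n_pcs=n_pcs, roi_id=roi)
        models[roi] = model
        for k in range(model.n_pcs):
            columns.append(model.train_loadings[:, k])
            index.append((roi, k + 1))
    raw = np.column_stack(columns) if columns else np.empty((train.n_subjects, 0))
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    fm = FeatureMatrix(
        values=(raw - mean) / sd_safe,
        feature_index=index,
        subject_ids=list(train.subject_ids),
        mean_=mean,
        sd_=sd_safe,
    )
    return fm, models


def _pearson_with_columns(series: np.ndarray, components: np.ndarray) -> np.ndarray:
    """Pearson r of one time series against each column of ``components``."""
    x = series - series.mean()
    nx = np.linalg.norm(x)
    c = components - components.mean(axis=0, keepdims=True)
    nc = np.linalg.norm(c, axis=0)
    return (x @ c) / (nx * nc)


def project_test_features(
    test: ClipDataset,
    models: dict[str, SharedResponseModel],
    train_features: FeatureMatrix,
    norm: str = "train",
) -> FeatureMatrix:
    """Correlation-projected features for held-out subjects.

    feature(s, roi, pc) = Pearson r between subject s's series and the ROI's
    training component time course, normalised with the training mean/sd
    (``norm='train'``, default) or within the test sample (``norm='test'``).
    Constant test series yield missing cells imputed with 0 — the training
    mean after normalisation.
    """
    if norm not in ("train", "test"):
        raise ValueError("norm must be 'train' or 'test'")
    n_trs = next(iter(models.values())).pc_timecourses.shape[0]
    if test.n_trs != n_trs:
        raise ValueError(
            f"test TR count {test.n_trs} does not match model TR count {n_trs}"
        )
    roi_pos = {roi: r for r, roi in enumerate(test.roi_ids)}
    raw = np.full((test.n_subjects, len(train_features.feature_index)), np.nan)
    col = 0
    for roi, model in models.items():
        if roi not in roi_pos:
            raise KeyError(f"ROI {roi!r} absent from test dataset")
        block = test.data[:, roi_pos[roi], :]
        for s in range(test.n_subjects):
            series = block[s]
            if series.std() == 0:
                continue  # leave NaN; imputed below
            raw[s, col:col + model.n_pcs] = _pearson_with_columns(
                series, model.pc_timecourses
            )
        col += model.n_pcs
    if norm == "train":
        values = (raw - train_features.mean_) / train_features.sd_
        values = np.where(np.isnan(values), 0.0, values)
    else:
        mean = np.nanmean(raw, axis=0)
        sd = np.nanstd(raw, axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        values = (raw - mean) / sd
        values = np.where(np.isnan(values), 0.0, values)
    return FeatureMatrix(
        values=values,
        feature_index=list(train_features.feature_index),
        subject_ids=list(test.subject_ids),
        mean_=train_features.mean_,
        sd_=train_features.sd_,
    )
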