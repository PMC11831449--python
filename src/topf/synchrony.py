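"""Shared-response estimation and inter-subject synchrony.

For each ROI a PCA is applied to the z-scored time series with subjects as
variables and TRs as observations; the fraction of variance explained by the
first component is the synchrony statistic.  The PCA is computed via an SVD
of the TRs × subjects z-scored matrix, so the explained-variance ratios are
exactly the eigenvalues of the subject correlation matrix divided by the
number of subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from topf.synthdata import ClipDataset

__all__ = [
    "DegenerateSeriesError",
    "SharedResponseModel",
    "SynchronyMap",
    "zscore_rows",
    "fit_shared_response",
    "synchrony_map",
    "spatial_similarity",
    "loading_similarity",
    "network_summary",
    "mean_isc",
]


class DegenerateSeriesError(ValueError):
    """A constant series makes z-scoring (and hence the PCA) undefined."""


@dataclass
class SharedResponseModel:
    """Per-ROI principal-component time courses and training loadings.

    ``pc_timecourses`` has unit-norm columns (TRs × n_pcs);
    ``train_loadings[s, k]`` equals sqrt(eigenvalue_k) times subject s's
    eigenvector weight, i.e. the Pearson correlation of the subject's
    z-scored series with component k (up to the component's mean removal).
    """

    roi_id: str
    pc_timecourses: np.ndarray
    explained_variance_ratio: np.ndarray
    train_loadings: np.ndarray
    sign_flipped: np.ndarray

    @property
    def n_pcs(self) -> int:
        return self.pc_timecourses.shape[1]

    @property
    def synchrony(self) -> float:
        return float(self.explained_variance_ratio[0])


@dataclass
class SynchronyMap:
    """Per-ROI synchrony values for one clip (NaN marks degenerate ROIs)."""

    clip_id: str
    values: np.ndarray
    roi_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.roi_ids):
            raise ValueError("values / roi_ids length mismatch")
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite < 0) or np.any(finite > 1):
            raise ValueError("synchrony values must lie in [0, 1]")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.roi_ids, name=self.clip_id)


def zscore_rows(series: np.ndarray) -> np.ndarray:
    """Z-score each row over time (population sd); error on constant rows."""
    series = np.asarray(series, dtype=float)
    mean = series.mean(axis=1, keepdims=True)
    sd = series.std(axis=1, keepdims=True)
    bad = np.flatnonzero(sd[:, 0] == 0)
    if bad.size:
        raise DegenerateSeriesError(
            f"constant time series for subject index(es) {bad.tolist()}"
        )
    return (series - mean) / sd


def apply_sign_convention(
    timecourses: np.ndarray, loadings: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flip each PC so that its largest-magnitude loading is positive.

    A component is negated when max(loadings) differs from max(|loadings|);
    the operation is idempotent.
    """
    timecourses = timecourses.copy()
    loadings = loadings.copy()
    flipped = np.zeros(loadings.shape[1], dtype=bool)
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        if col.max() != np.abs(col).max():
            loadings[:, k] = -col
            timecourses[:, k] = -timecourses[:, k]
            flipped[k] = True
    return timecourses, loadings, flipped


def fit_shared_response(
    series: np.ndarray, n_pcs: int = 1, roi_id: str = ""
) -> SharedResponseModel:
    """PCA of z-scored series with subjects as variables, TRs as observations.

    ``explained_variance_ratio[k]`` equals eigenvalue k of the n × n subject
    correlation matrix divided by n; ratio[0] is the synchrony value.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be subjects × TRs")
    n_subj, n_trs = series.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if n_trs < n_pcs + 2:
        raise ValueError("need at least n_pcs + 2 TRs")
    z = zscore_rows(series)

    x = z.T  # TRs × subjects; columns have mean 0, population sd 1
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = s**2 / n_trs  # eigenvalues of the subject correlation matrix
    k = min(n_pcs, len(eigvals))
    ratios = np.clip(eigvals[:k] / n_subj, 0.0, 1.0)  # guard float overshoot
    timecourses = u[:, :k]
    loadings = vt[:k].T * np.sqrt(eigvals[:k])[None, :]
    timecourses, loadings, flipped = apply_sign_convention(timecourses, loadings)
    return SharedResponseModel(
        roi_id=roi_id,
        pc_timecourses=timecourses,
        explained_variance_ratio=ratios,
        train_loadings=loadings,
        sign_flipped=flipped,
    )


def synchrony_map(dataset: ClipDataset) -> SynchronyMap:
    """Per-ROI synchrony; degenerate ROIs are reported as NaN."""
    values = np.full(dataset.n_rois, np.nan)
    degenerate = dataset.degenerate_rois()
    for r in range(dataset.n_rois):
        if degenerate[r]:
            continue
        model = fit_shared_response(dataset.data[:, r, :], n_pcs=1,
                                    roi_id=dataset.roi_ids[r])
        values[r] = model.synchrony
    return SynchronyMap(clip_id=dataset.clip_id, values=values,
                        roi_ids=list(dataset.roi_ids))


def spatial_similarity(maps: list[SynchronyMap]) -> pd.DataFrame:
    """Clip × clip Pearson correlation of synchrony maps over ROIs.

    Missing (degenerate) ROIs are dropped pairwise; fewer than 3 shared
    non-missing ROIs for any pair is an error.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    roi_sets = {tuple(m.roi_ids) for m in maps}
    if len(roi_sets) != 1:
        raise ValueError("maps must share an identical ROI set")
    clip_ids = [m.clip_id for m in maps]
    values = np.vstack([m.values for m in maps])
    n = len(maps)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            ok = np.isfinite(values[i]) & np.isfinite(values[j])
            if ok.sum() < 3:
                raise ValueError(
                    f"fewer than 3 shared non-missing ROIs for pair "
                    f"({clip_ids[i]}, {clip_ids[j]})"
                )
            r = np.corrcoef(values[i, ok], values[j, ok])[0, 1]
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=clip_ids, columns=clip_ids)


def loading_similarity(clips: list[ClipDataset], roi: str) -> pd.DataFrame:
    """Clip × clip Pearson correlation of PC1 loadings for one ROI."""
    if len(clips) < 2:
        raise ValueError("need at least 2 clips")
    orders = {tuple(c.subject_ids) for c in clips}
    if len(orders) != 1:
        raise ValueError("clips must share an identical subject order")
    loadings = []
    for clip in clips:
        try:
            r = clip.roi_ids.index(roi)
        except ValueError:
            raise KeyError(f"ROI {roi!r} not present in clip {clip.clip_id}")
        model = fit_shared_response(clip.data[:, r, :], n_pcs=1, roi_id=roi)
        loadings.append(model.train_loadings[:, 0])
    clip_ids = [c.clip_id for c in clips]
    corr = np.corrcoef(np.vstack(loadings))
    return pd.DataFrame(corr, index=clip_ids, columns=clip_ids)


def network_summary(values: np.ndarray, roi_network: list[str]) -> pd.DataFrame:
    """Per-network mean, quartiles, min and max of a per-ROI statistic."""
    values = np.asarray(values, dtype=float)
    if len(values) != len(roi_network):
        raise ValueError("values / labels length mismatch")
    if any(label is None or label == "" for label in roi_network):
        raise ValueError("every ROI needs a network label")
    frame = pd.DataFrame({"value": values, "network": roi_network})
    grouped = frame.groupby("network")["value"]
    out = grouped.agg(
        mean="mean",
        q25=lambda v: v.quantile(0.25),
        median="median",
        q75=lambda v: v.quantile(0.75),
        min="min",
        max="max",
    )
    return out


def mean_isc(series: np.ndarray) -> float:
    """Subject-averaged inter-subject correlation (mean off-diagonal of the
    subject correlation matrix) — the classical synchrony statistic used as a
    reference for the PC1-based one."""
    z = zscore_rows(np.asarray(series, dtype=float))
    n = z.shape[0]
    corr = (z @ z.T) / z.shape[1]
    off = corr[~np.eye(n, dtype=bool)]
    return float(off.mean())
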