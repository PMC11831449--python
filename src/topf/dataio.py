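"""On-disk formats, trimming, and run configuration.

Time series are stored as one tab-delimited file per subject per clip
(rows = TRs with an explicit 0-based ``tr_index`` column, columns = ROI ids);
cohort and ROI metadata as CSV.  All writers round-trip through their
readers to equal values.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from topf.synthdata import ClipDataset, CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "FormatError",
    "write_clip",
    "load_clip",
    "write_cohort",
    "load_cohort",
    "write_roi_metadata",
    "load_roi_metadata",
    "write_annotations",
    "load_annotations",
    "trim_clip",
]


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected layout."""


ESTIMATORS = ("ridge", "svm_linear", "svm_rbf", "rf")


@dataclass
class RunConfig:
    """Resolved configuration of one prediction run."""

    phenotype: str = "sex_label"
    task: str = "classification"  # or "regression"
    n_pcs: int = 2
    estimator: str = "ridge"
    k_outer: int = 10
    k_inner: int = 5
    n_repeats: int = 10
    n_permutations: int = 1000
    n_importance_shuffles: int = 1000
    seed: int = 0
    rf_n_trees: int = 500
    keep_models: bool = True
    test_feature_norm: str = "train"  # or "test": z-score within test sample
    grids: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_pcs not in (1, 2):
            raise ValueError("n_pcs must be 1 or 2")
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"estimator must be one of {ESTIMATORS}")
        for name in ("k_outer", "k_inner", "n_repeats", "n_permutations",
                     "n_importance_shuffles", "rf_n_trees"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.test_feature_norm not in ("train", "test"):
            raise ValueError("test_feature_norm must be 'train' or 'test'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# clip time series
# ---------------------------------------------------------------------------

def _clip_filename(clip_id: str, subject_id: str) -> str:
    return f"{clip_id}_{subject_id}.tsv"


def write_clip(dataset: ClipDataset, out_dir: str | Path) -> list[Path]:
    """Write one TSV per subject: tr_index column plus one column per ROI."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, subject in enumerate(dataset.subject_ids):
        frame = pd.DataFrame(dataset.data[i].T, columns=dataset.roi_ids)
        frame.insert(0, "tr_index", np.arange(dataset.n_trs))
        path = out_dir / _clip_filename(dataset.clip_id, subject)
        frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
        paths.append(path)
    return paths


def load_clip(
    clip_dir: str | Path,
    clip_id: str,
    subject_ids: list[str],
    roi_network: list[str] | None = None,
    tr_seconds: float = 1.0,
) -> ClipDataset:
    """Assemble per-subject TSVs into a ClipDataset in the declared order.

    All files must share the TR count and the ROI header; degenerate
    (constant) series are permitted and flagged on the returned dataset.
    """
    clip_dir = Path(clip_dir)
    blocks, roi_ids, n_trs = [], None, None
    for subject in subject_ids:
        path = clip_dir / _clip_filename(clip_id, subject)
        if not path.exists():
            raise FileNotFoundError(
                f"missing time-series file for subject {subject!r}: {path}"
            )
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
        if "tr_index" not in frame.columns:
            raise FormatError(f"{path} lacks a tr_index column")
        cols = [c for c in frame.columns if c != "tr_index"]
        if roi_ids is None:
            roi_ids, n_trs = cols, len(frame)
        elif cols != roi_ids:
            raise FormatError(
                f"ROI header mismatch for subject {subject!r}: "
                f"expected {roi_ids[:3]}…, got {cols[:3]}…"
            )
        elif len(frame) != n_trs:
            raise FormatError(f"TR count mismatch for subject {subject!r}")
        blocks.append(frame[roi_ids].to_numpy().T)
    data = np.stack(blocks)
    if roi_network is None:
        roi_network = ["unknown"] * len(roi_ids)
    dataset = ClipDataset(
        clip_id=clip_id,
        data=data,
        subject_ids=list(subject_ids),
        roi_ids=list(roi_ids),
        roi_network=list(roi_network),
        tr_seconds=tr_seconds,
    )
    n_degenerate = int(dataset.degenerate_rois().sum())
    if n_degenerate:
        logger.warning(
            "clip %s: %d ROI(s) contain constant series and are flagged degenerate",
            clip_id, n_degenerate,
        )
    return dataset


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.table.to_csv(path, index=False, float_format="%.17g")


def load_cohort(path: str | Path) -> CohortTable:
    return CohortTable(pd.read_csv(path))


def write_roi_metadata(dataset: ClipDataset, path: str | Path) -> None:
    pd.DataFrame(
        {"roi_id": dataset.roi_ids, "network": dataset.roi_network}
    ).to_csv(path, index=False)


def load_roi_metadata(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if not {"roi_id", "network"} <= set(frame.columns):
        raise FormatError("ROI metadata needs roi_id and network columns")
    return frame


def write_annotations(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for clip_id, frame in tables.items():
        frame.to_csv(out_dir / f"annotations_{clip_id}.csv", index=False,
                     float_format="%.17g")


def load_annotations(out_dir: str | Path) -> dict[str, pd.DataFrame]:
    out_dir = Path(out_dir)
    tables = {}
    for path in sorted(out_dir.glob("annotations_*.csv")):
        clip_id = path.stem.replace("annotations_", "")
        frame = pd.read_csv(path, float_precision="round_trip")
        required = {"tr_index", "motion_energy", "brightness", "loudness", "face"}
        if not required <= set(frame.columns):
            raise FormatError(f"{path} missing annotation columns")
        tables[clip_id] = frame
    return tables


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

def trim_clip(dataset: ClipDataset, n_discard_initial: int, target_trs: int) -> ClipDataset:
    """Drop the first ``n_discard_initial`` TRs, then truncate to
    ``target_trs`` by removing extra TRs at the end.  The output length is
    ``min(target_trs, original − n_discard_initial)``."""
    if n_discard_initial < 0 or target_trs < 1:
        raise ValueError("counts must be non-negative / positive")
    if n_discard_initial >= dataset.n_trs:
        raise ValueError(
            f"cannot discard {n_discard_initial} of {dataset.n_trs} TRs"
        )
    kept = dataset.data[:, :, n_discard_initial:]
    kept = kept[:, :, :target_trs]
    return ClipDataset(
        clip_id=dataset.clip_id,
        data=kept.copy(),
        subject_ids=list(dataset.subject_ids),
        roi_ids=list(dataset.roi_ids),
        roi_network=list(dataset.roi_network),
        tr_seconds=dataset.tr_seconds,
    )
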