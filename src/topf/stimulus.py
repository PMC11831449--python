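"""Stimulus-level analyses: synchrony-performance regressions with BIC model
selection, film-type contrasts, low/middle-level movie-feature summaries,
semantic-label frequencies with non-negative factorisation, and validation
correlations."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import NMF

from topf.prediction import corrected_resampled_ttest

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionFit",
    "TopicModel",
    "fit_synchrony_performance",
    "classify_effect",
    "film_type_contrast",
    "summarise_clip_features",
    "correlate_with_performance",
    "semantic_frequency",
    "filter_and_factorise",
    "validation_correlation",
]

EFFECT_CLASSES = (
    "negative-linear",
    "positive-linear",
    "negative-quadratic",
    "positive-quadratic",
    "none",
)


@dataclass
class RegressionFit:
    """Linear and quadratic fits of performance on synchrony for one ROI."""

    roi_id: str
    linear: dict  # beta0, beta1, resid_var, bic, p
    quadratic: dict  # beta0, beta1, beta2, resid_var, bic, p
    selected_order: int
    effect_class: str
    n_points: int


@dataclass
class TopicModel:
    """Non-negative factorisation of the label × clip frequency matrix."""

    label_weights: pd.DataFrame  # labels × topics
    clip_loadings: pd.DataFrame  # topics × clips
    reconstruction_error: float
    excluded_labels: list[str]

    def reconstruct(self) -> np.ndarray:
        return self.label_weights.to_numpy() @ self.clip_loadings.to_numpy()


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot z-score a constant vector")
    return (v - v.mean()) / sd


def _gaussian_bic(rss: float, n: int, n_params: int) -> float:
    # Gaussian-likelihood BIC up to an additive constant shared by both
    # candidate models: n*ln(RSS/n) + p*ln(n).  RSS is floored so that
    # numerically perfect fits compare by parameter count alone.
    rss = max(rss, n * 1e-12)
    return n * np.log(rss / n) + n_params * np.log(n)


def _ols_fit(x_design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    model = sm.OLS(y, x_design).fit()
    rss = float(model.ssr)
    return model.params, rss, float(model.f_pvalue)


def fit_synchrony_performance(
    x, y, exclude: set | None = None, clip_ids: list[str] | None = None,
    roi_id: str = "", alpha: float = 0.05,
) -> RegressionFit:
    """Fit y = b0 + b1 x and y = b0 + b1 x + b2 x² (x, y z-scored) and select
    the order with the lower Gaussian BIC; classify the effect by the sign of
    the selected model's highest-order coefficient when its overall F-test is
    significant at ``alpha``, otherwise 'none'.

    ``exclude`` drops clips (by id, requires ``clip_ids``) before fitting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if exclude:
        if clip_ids is None:
            raise ValueError("exclusions require clip_ids")
        keep = np.array([c not in exclude for c in clip_ids])
        x, y = x[keep], y[keep]
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 clips after exclusion")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("x and y must be non-constant")
    xz, yz = _zscore(x), _zscore(y)

    design_lin = np.column_stack([np.ones(n), xz])
    beta_lin, rss_lin, p_lin = _ols_fit(design_lin, yz)
    bic_lin = _gaussian_bic(rss_lin, n, 2)

    design_quad = np.column_stack([np.ones(n), xz, xz**2])
    beta_quad, rss_quad, p_quad = _ols_fit(design_quad, yz)
    bic_quad = _gaussian_bic(rss_quad, n, 3)

    linear = {
        "beta0": beta_lin[0], "beta1": beta_lin[1],
        "resid_var": rss_lin / (n - 2), "bic": bic_lin, "p": p_lin,
    }
    quadratic = {
        "beta0": beta_quad[0], "beta1": beta_quad[1], "beta2": beta_quad[2],
        "resid_var": rss_quad / max(n - 3, 1), "bic": bic_quad, "p": p_quad,
    }
    selected = 1 if bic_lin <= bic_quad else 2
    fit = RegressionFit(
        roi_id=roi_id,
        linear=linear,
        quadratic=quadratic,
        selected_order=selected,
        effect_class="",
        n_points=n,
    )
    fit.effect_class = classify_effect(fit, alpha=alpha)
    return fit


def classify_effect(fit: RegressionFit, alpha: float = 0.05) -> str:
    """Map (selected order, highest-order coefficient sign, significance) to
    an effect class; non-significant selected models give 'none'."""
    if fit.selected_order == 1:
        coeff, p = fit.linear["beta1"], fit.linear["p"]
        kind = "linear"
    else:
        coeff, p = fit.quadratic["beta2"], fit.quadratic["p"]
        kind = "quadratic"
    if not np.isfinite(p) or p >= alpha:
        return "none"
    return ("positive-" if coeff > 0 else "negative-") + kind


def film_type_contrast(
    per_clip_scores: dict[str, np.ndarray],
    groups: dict[str, str],
    n_train: int,
    n_test: int,
):
    """Compare per-fold performance between two film groups.

    Per-fold scores of each clip (all clips must share the fold scheme and
    hence score count) are averaged over clips within each group per fold,
    then the two per-fold group means are compared by the corrected
    resampled paired t-test.  Returns (group_means, t, p).
    """
    names = sorted(set(groups.values()))
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    lengths = {len(v) for v in per_clip_scores.values()}
    if len(lengths) != 1:
        raise ValueError("clips have mismatching fold counts")
    by_group = {name: [] for name in names}
    for clip, scores in per_clip_scores.items():
        if clip not in groups:
            raise KeyError(f"clip {clip!r} has no group assignment")
        by_group[groups[clip]].append(np.asarray(scores, dtype=float))
    if any(not v for v in by_group.values()):
        raise ValueError("both groups must be non-empty")
    means = {name: np.vstack(v).mean(axis=0) for name, v in by_group.items()}
    t, p = corrected_resampled_ttest(
        means[names[0]], means[names[1]], n_train=n_train, n_test=n_test
    )
    group_means = {name: float(v.mean()) for name, v in means.items()}
    return group_means, t, p


def summarise_clip_features(
    table: pd.DataFrame, word_count: int, delay_trs: int = 4
) -> pd.Series:
    """Per-clip movie-feature row from a per-TR annotation table.

    The annotation axis is shifted by ``delay_trs`` to account for the
    haemodynamic delay (rows without a matching BOLD TR inside the clip are
    dropped from the end), then means / sample standard deviations are taken
    over the retained TRs.  #Faces counts TRs with a face present.
    """
    required = {"motion_energy", "brightness", "loudness", "face"}
    if not required <= set(table.columns):
        raise ValueError(f"annotation table missing columns {required - set(table.columns)}")
    if delay_trs < 0:
        raise ValueError("delay_trs must be >= 0")
    if len(table) < delay_trs + 2:
        raise ValueError("annotation table too short for the requested delay")
    kept = table.iloc[: len(table) - delay_trs] if delay_trs else table
    out = {}
    for col, prefix in (("motion_energy", "ME"), ("brightness", "Brt"),
                        ("loudness", "RMS")):
        out[f"{prefix}_mean"] = float(kept[col].mean())
        out[f"{prefix}_std"] = float(kept[col].std(ddof=1))
    out["n_face_trs"] = int((kept["face"] > 0).sum())
    out["n_words"] = int(word_count)
    return pd.Series(out)


def correlate_with_performance(
    table: pd.DataFrame, performance: pd.Series
) -> pd.DataFrame:
    """Pearson r and two-sided p of each per-clip feature against the
    per-clip performance scores; constant columns give NaN with a warning."""
    if len(table) < 4:
        raise ValueError("need at least 4 clips")
    perf = performance.loc[table.index].to_numpy(dtype=float)
    rows = {}
    for col in table.columns:
        v = table[col].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            logger.warning("feature %s is constant across clips; skipped", col)
            rows[col] = (np.nan, np.nan)
            continue
        res = stats.pearsonr(v, perf)
        rows[col] = (float(res.statistic), float(res.pvalue))
    return pd.DataFrame(rows, index=["r", "p"]).T


def semantic_frequency(presence: np.ndarray, n_trs: int) -> np.ndarray:
    """Per-label appearance frequency: TRs showing the label / total TRs."""
    if n_trs <= 0:
        raise ValueError("n_trs must be positive")
    presence = np.asarray(presence)
    counts = (presence > 0).sum(axis=-1)
    return counts / n_trs


def filter_and_factorise(
    freq_matrix: pd.DataFrame, n_topics: int, seed: int, n_restarts: int = 10,
    max_iter: int = 2000, tol: float = 1e-10,
) -> TopicModel:
    """Drop zero-variance label rows, then non-negative factorisation.

    Runs one deterministic NNDSVD-based initialisation plus ``n_restarts``
    random restarts (seeded) and keeps the solution with the lowest
    reconstruction error.
    """
    values = freq_matrix.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("frequency matrix must be non-negative")
    variable = values.std(axis=1) > 0
    excluded = [label for label, keep in zip(freq_matrix.index, variable) if not keep]
    kept = freq_matrix.loc[variable]
    if kept.shape[0] < n_topics or kept.shape[1] < n_topics:
        raise ValueError("too few non-constant labels or clips for n_topics")
    x = kept.to_numpy(dtype=float)

    best = None
    inits = [("nndsvda", seed)] + [("random", seed + i) for i in range(n_restarts)]
    for init, state in inits:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nmf = NMF(n_components=n_topics, init=init, random_state=state,
                      max_iter=max_iter, tol=tol)
            w = nmf.fit_transform(x)
        err = np.linalg.norm(x - w @ nmf.components_)
        if best is None or err < best[0]:
            best = (err, w, nmf.components_)
    err, w, h = best
    topics = [f"topic-{t}" for t in range(n_topics)]
    return TopicModel(
        label_weights=pd.DataFrame(w, index=kept.index, columns=topics),
        clip_loadings=pd.DataFrame(h, index=topics, columns=kept.columns),
        reconstruction_error=float(err),
        excluded_labels=excluded,
    )


def validation_correlation(
    per_subject_values: pd.DataFrame, performance: pd.Series
):
    """Correlate a subject-level scalar (e.g. mean FD, blink rate) with
    per-clip performance: subject values are averaged within each clip, then
    Pearson r / p against the performance scores.

    ``per_subject_values`` is subjects × clips.  Returns (r, p); a constant
    clip-mean vector gives (nan, nan) with a warning.
    """
    if per_subject_values.shape[1] < 4:
        raise ValueError("need at least 4 clips")
    clip_means = per_subject_values.mean(axis=0)
    perf = performance.loc[clip_means.index].to_numpy(dtype=float)
    v = clip_means.to_numpy(dtype=float)
    if np.ptp(v) == 0 or np.ptp(perf) == 0:
        logger.warning("constant vector in validation correlation")
        return np.nan, np.nan
    res = stats.pearsonr(v, perf)
    return float(res.statistic), float(res.pvalue)
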