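"""Synthetic cohorts, clip datasets, and stimulus annotations with planted truth.

Every generator is seed-deterministic: identical arguments (including the
seed) give bit-identical outputs.  Generated objects carry a ``truth``
attribute holding the planted parameters (latent time courses, subject
loadings, topic factors) so that downstream estimators can be validated
against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import brentq

__all__ = [
    "CohortTable",
    "GenerativeSpec",
    "ClipDataset",
    "generate_cohort",
    "generate_clip",
    "generate_clip_family",
    "generate_annotations",
    "solve_shared_amplitude",
    "population_synchrony",
]

_SMOOTH_WINDOW = 5  # moving-average width (TRs) of the latent time course


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Subject table: ids, family ids, one binary and ≥0 continuous phenotypes."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject_id", "family_id", "sex_label"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        if self.table["subject_id"].duplicated().any():
            raise ValueError("subject_ids must be unique")
        if self.table["family_id"].nunique() < 2:
            raise ValueError("cohort must contain at least 2 families")
        numeric = self.table.drop(columns=["subject_id", "family_id"])
        if not np.isfinite(numeric.to_numpy(dtype=float)).all():
            raise ValueError("phenotype columns must be finite")

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].tolist()

    @property
    def family_ids(self) -> list[str]:
        return self.table["family_id"].tolist()

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def phenotype(self, name: str) -> np.ndarray:
        if name not in self.table.columns:
            raise KeyError(f"unknown phenotype {name!r}")
        return self.table[name].to_numpy()

    def subset(self, subject_ids: list[str]) -> "CohortTable":
        sub = self.table.set_index("subject_id").loc[list(subject_ids)].reset_index()
        return CohortTable(sub)


@dataclass(frozen=True)
class GenerativeSpec:
    """Parameters of one synthetic clip.

    ``shared_fraction`` is the target population fraction of across-subject
    variance carried by the shared component in each ROI (scalar or per-ROI
    array); ``effect_size`` is the standardised loading-phenotype association
    in the ``predictive_rois`` — a Pearson correlation for a continuous
    phenotype, a Cohen's d group difference for a binary one.
    """

    n_subjects: int
    n_rois: int
    n_trs: int
    shared_fraction: float | np.ndarray = 0.3
    predictive_rois: tuple[int, ...] = ()
    effect_size: float = 0.0
    noise_sd: float = 1.0
    loading_sd: float = 0.3
    cross_clip_loading_corr: float = 1.0
    phenotype: str = "sex_label"
    seed: int = 0

    def __post_init__(self) -> None:
        frac = np.broadcast_to(np.asarray(self.shared_fraction, dtype=float),
                               (self.n_rois,))
        if np.any(frac < 0) or np.any(frac >= 1):
            raise ValueError("shared_fraction must be elementwise in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not -1.0 <= self.cross_clip_loading_corr <= 1.0:
            raise ValueError("cross_clip_loading_corr must be in [-1, 1]")
        bad = [r for r in self.predictive_rois if not 0 <= r < self.n_rois]
        if bad:
            raise ValueError(f"predictive_rois out of range: {bad}")

    @property
    def shared_fraction_per_roi(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.shared_fraction, dtype=float), (self.n_rois,)
        ).copy()


@dataclass
class ClipDataset:
    """subjects × ROIs × TRs time-series tensor for one stimulus."""

    clip_id: str
    data: np.ndarray
    subject_ids: list[str]
    roi_ids: list[str]
    roi_network: list[str]
    tr_seconds: float = 1.0
    truth: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be subjects × ROIs × TRs")
        n_subj, n_roi, _ = self.data.shape
        if len(self.subject_ids) != n_subj:
            raise ValueError("subject_ids length mismatch")
        if len(self.roi_ids) != n_roi or len(self.roi_network) != n_roi:
            raise ValueError("ROI metadata length mismatch")
        if np.isnan(self.data).any():
            raise ValueError("data contains NaN")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def n_trs(self) -> int:
        return self.data.shape[2]

    def degenerate_series(self) -> np.ndarray:
        """Boolean subjects × ROIs mask of constant (non z-scorable) series."""
        return np.ptp(self.data, axis=2) == 0

    def degenerate_rois(self) -> np.ndarray:
        """ROIs containing at least one constant per-subject series."""
        return self.degenerate_series().any(axis=0)

    def subset_subjects(self, subject_ids: list[str]) -> "ClipDataset":
        index = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in index]
        if missing:
            raise KeyError(f"subjects not in dataset: {missing}")
        rows = [index[s] for s in subject_ids]
        return ClipDataset(
            clip_id=self.clip_id,
            data=self.data[rows].copy(),
            subject_ids=list(subject_ids),
            roi_ids=list(self.roi_ids),
            roi_network=list(self.roi_network),
            tr_seconds=self.tr_seconds,
        )

    def take_trs(self, n_trs: int) -> "ClipDataset":
        if n_trs > self.n_trs:
            raise ValueError("cannot take more TRs than available")
        return ClipDataset(
            clip_id=self.clip_id,
            data=self.data[:, :, :n_trs].copy(),
            subject_ids=list(self.subject_ids),
            roi_ids=list(self.roi_ids),
            roi_network=list(self.roi_network),
            tr_seconds=self.tr_seconds,
        )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    n_subjects: int,
    n_families: int,
    seed: int,
    continuous: tuple[str, ...] = ("score",),
) -> CohortTable:
    """Generate a cohort with balanced families and phenotypes.

    Family sizes differ by at most one; the binary label is balanced to
    within one subject and assigned independently of family; continuous
    phenotypes are standard-normal draws independent of family.
    """
    if n_families > n_subjects:
        raise ValueError("n_families may not exceed n_subjects")
    if n_families < 2:
        raise ValueError("need at least 2 families")
    rng = np.random.default_rng(seed)

    base, extra = divmod(n_subjects, n_families)
    sizes = np.full(n_families, base)
    sizes[:extra] += 1
    rng.shuffle(sizes)
    family_ids = np.repeat(
        [f"fam-{i:04d}" for i in range(n_families)], sizes
    )

    sex = np.zeros(n_subjects, dtype=int)
    sex[: n_subjects // 2 + n_subjects % 2] = 1
    rng.shuffle(sex)

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n_subjects)],
            "family_id": family_ids,
            "sex_label": sex,
        }
    )
    for name in continuous:
        table[name] = rng.standard_normal(n_subjects)
    return CohortTable(table)


# ---------------------------------------------------------------------------
# amplitude calibration
# ---------------------------------------------------------------------------

def _rho_squared_expectation(c: float, loading_sd: float, nodes, weights) -> float:
    # E_w[ c w^2 / (c w^2 + 1) ] under w ~ N(1, loading_sd^2), by
    # Gauss-Hermite quadrature (probabilists' convention).
    w = 1.0 + loading_sd * nodes
    vals = c * w**2 / (c * w**2 + 1.0)
    return float(np.sum(weights * vals) / np.sqrt(2 * np.pi))


def solve_shared_amplitude(
    shared_fraction: float, noise_sd: float, loading_sd: float
) -> float:
    """Amplitude ``a`` such that the population synchrony equals the target.

    A subject's series is ``a·w·g(t) + e(t)`` with ``Var(g)=1``,
    ``Var(e)=noise_sd²`` and ``w ~ N(1, loading_sd²)``.  The correlation of
    subject ``s`` with the latent course is ``ρ_s = a·w_s/√(a²w_s²+σ²)`` and
    the population subject-correlation matrix is ``diag(1-ρ²) + ρρᵀ``, whose
    top eigenvalue over n tends to ``E[ρ²]``.  We therefore solve

        E_w[ a²w² / (a²w² + noise_sd²) ] = shared_fraction

    for ``a`` (the expectation is taken by quadrature; a plain moment-ratio
    solution ``a²E[w²]/(a²E[w²]+σ²)`` ignores the Jensen gap across subjects).
    """
    if shared_fraction == 0.0:
        return 0.0
    if noise_sd == 0.0:
        return 1.0  # noise-free data are rank one whatever the amplitude
    nodes, weights = hermegauss(80)
    target = shared_fraction

    def gap(log_c: float) -> float:
        return _rho_squared_expectation(np.exp(log_c), loading_sd, nodes, weights) - target

    log_c = brentq(gap, -30.0, 30.0)
    return float(noise_sd * np.sqrt(np.exp(log_c)))


def population_synchrony(
    amplitude: float, loadings: np.ndarray, noise_sd: float
) -> float:
    """Analytic synchrony of a planted clip: top eigenvalue / n of the
    population subject-correlation matrix built from the actual loadings."""
    w = np.asarray(loadings, dtype=float)
    if noise_sd == 0.0:
        return 1.0 if amplitude != 0 else np.nan
    rho = amplitude * w / np.sqrt(amplitude**2 * w**2 + noise_sd**2)
    corr = np.outer(rho, rho)
    np.fill_diagonal(corr, 1.0)
    top = np.linalg.eigvalsh(corr)[-1]
    return float(top / len(w))


# ---------------------------------------------------------------------------
# clip generation
# ---------------------------------------------------------------------------

def _latent_timecourse(rng: np.random.Generator, n_trs: int) -> np.ndarray:
    """Band-limited unit-variance latent course: moving-average(5) noise."""
    raw = rng.standard_normal(n_trs + _SMOOTH_WINDOW - 1)
    g = np.convolve(raw, np.ones(_SMOOTH_WINDOW) / _SMOOTH_WINDOW, mode="valid")
    g -= g.mean()
    sd = g.std()
    if sd == 0:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("degenerate latent course")
    return g / sd


def _standardised_phenotype(cohort: CohortTable, name: str) -> tuple[np.ndarray, bool]:
    y = cohort.phenotype(name).astype(float)
    binary = set(np.unique(y)) <= {0.0, 1.0}
    z = y - y.mean()
    sd = z.std()
    if sd == 0:
        raise ValueError(f"phenotype {name!r} is constant")
    return z / sd, binary


def _loading_mix(
    base_noise: np.ndarray,
    y_std: np.ndarray,
    binary: bool,
    effect_size: float,
    predictive: np.ndarray,
) -> np.ndarray:
    """Unit-variance standardised loading components u (subjects × ROIs).

    Predictive ROIs mix the standardised phenotype into u.  For a continuous
    phenotype ``u = r·y + √(1-r²)·ε`` so corr(u, y) = effect_size; for a
    binary one ``u = (d/2·y± + ε)/√(1+d²/4)`` so the group-standardised mean
    difference (Cohen's d) equals effect_size — both leave Var(u) = 1, hence
    the synchrony calibration is unaffected by the planted effect.
    """
    u = base_noise.copy()
    if predictive.any() and effect_size != 0.0:
        if binary:
            half_d = effect_size / 2.0
            mixed = (half_d * y_std[:, None] + base_noise[:, predictive]) / np.sqrt(
                1.0 + half_d**2
            )
        else:
            r = effect_size
            if not -1.0 < r < 1.0:
                raise ValueError(
                    "effect_size must be in (-1, 1) for a continuous phenotype"
                )
            mixed = r * y_std[:, None] + np.sqrt(1.0 - r**2) * base_noise[:, predictive]
        u[:, predictive] = mixed
    return u


def _generate_clip(
    cohort: CohortTable,
    spec: GenerativeSpec,
    clip_id: str,
    shared_noise: np.ndarray | None,
    seed: int,
) -> ClipDataset:
    if spec.n_subjects != cohort.n_subjects:
        raise ValueError("spec n_subjects inconsistent with cohort")
    rng = np.random.default_rng(seed)
    n_subj, n_roi, n_tr = spec.n_subjects, spec.n_rois, spec.n_trs

    fresh = rng.standard_normal((n_subj, n_roi))
    if shared_noise is None:
        base_noise = fresh
    else:
        # pairwise corr between two clips mixing a common draw with weight b
        # is b^2, so b = sqrt(rho); works for any number of clips when rho>=0
        rho = spec.cross_clip_loading_corr
        if rho < 0:
            raise ValueError(
                "negative cross_clip_loading_corr is not representable with a "
                "single shared draw across >= 2 clips"
            )
        b = np.sqrt(rho)
        base_noise = b * shared_noise + np.sqrt(1.0 - rho) * fresh

    y_std, binary = _standardised_phenotype(cohort, spec.phenotype)
    predictive = np.zeros(n_roi, dtype=bool)
    predictive[list(spec.predictive_rois)] = True
    u = _loading_mix(base_noise, y_std, binary, spec.effect_size, predictive)
    loadings = 1.0 + spec.loading_sd * u  # mean-1 subject loadings w

    fractions = spec.shared_fraction_per_roi
    amplitudes = np.array(
        [solve_shared_amplitude(f, spec.noise_sd, spec.loading_sd) for f in fractions]
    )
    latents = np.vstack([_latent_timecourse(rng, n_tr) for _ in range(n_roi)])
    noise = (
        rng.standard_normal((n_subj, n_roi, n_tr)) * spec.noise_sd
        if spec.noise_sd > 0
        else np.zeros((n_subj, n_roi, n_tr))
    )
    data = amplitudes[None, :, None] * loadings[:, :, None] * latents[None, :, :] + noise

    roi_ids = [f"roi-{i:04d}" for i in range(n_roi)]
    networks = [f"net-{i % 7}" for i in range(n_roi)]
    return ClipDataset(
        clip_id=clip_id,
        data=data,
        subject_ids=cohort.subject_ids,
        roi_ids=roi_ids,
        roi_network=networks,
        tr_seconds=1.0,
        truth={
            "loadings": loadings,
            "amplitudes": amplitudes,
            "latents": latents,
            "shared_fraction": fractions,
            "predictive_rois": np.flatnonzero(predictive),
            "noise_sd": spec.noise_sd,
        },
    )


def generate_clip(cohort: CohortTable, spec: GenerativeSpec) -> ClipDataset:
    """Generate one clip with a planted shared response per ROI.

    Per ROI r and subject s the series is ``a_r·w_{s,r}·g_r(t) + e(t)`` with
    the amplitude ``a_r`` calibrated so the population synchrony equals
    ``spec.shared_fraction[r]`` (see :func:`solve_shared_amplitude`).
    """
    return _generate_clip(cohort, spec, clip_id=f"clip-{spec.seed:04d}",
                          shared_noise=None, seed=spec.seed)


def generate_clip_family(
    cohort: CohortTable, specs: list[GenerativeSpec], n_clips: int
) -> list[ClipDataset]:
    """Generate clips whose loading noise is correlated across clips.

    Each spec's ``cross_clip_loading_corr`` sets the correlation of its
    standardised loading noise with a cohort-level shared draw; with corr=1
    and equal specs the planted loadings are identical across clips.
    """
    if n_clips != len(specs):
        raise ValueError("n_clips must equal len(specs)")
    if any(s.n_subjects != cohort.n_subjects for s in specs):
        raise ValueError("all specs must reference the cohort size")
    shapes = {(s.n_rois,) for s in specs}
    if len(shapes) != 1:
        raise ValueError("all specs must share n_rois")
    master = np.random.default_rng(specs[0].seed)
    shared_noise = master.standard_normal((cohort.n_subjects, specs[0].n_rois))
    clips = []
    for k, spec in enumerate(specs):
        clips.append(
            _generate_clip(
                cohort,
                spec,
                clip_id=f"clip-{k:04d}",
                shared_noise=shared_noise,
                seed=spec.seed + 1000 * (k + 1),
            )
        )
    return clips


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def generate_annotations(
    n_clips: int,
    n_trs: int,
    n_labels: int,
    n_topics: int,
    seed: int,
    n_constant_labels: int = 0,
    noise_scale: float = 0.0,
):
    """Generate per-TR stimulus tables plus a low-rank semantic matrix.

    Returns ``(tables, freq_matrix, truth)`` where ``tables`` maps clip id to
    a per-TR DataFrame (tr_index, motion_energy, brightness, loudness, face),
    ``freq_matrix`` is a labels × clips DataFrame equal to ``W·H`` plus
    non-negative noise, and ``truth`` holds the planted factors and the
    indices of labels made constant across clips.
    """
    if n_topics >= min(n_labels, n_clips):
        raise ValueError("n_topics must be < min(n_labels, n_clips)")
    if n_constant_labels > n_labels:
        raise ValueError("n_constant_labels exceeds n_labels")
    rng = np.random.default_rng(seed)

    tables = {}
    for k in range(n_clips):
        tables[f"clip-{k:04d}"] = pd.DataFrame(
            {
                "tr_index": np.arange(n_trs),
                "motion_energy": np.abs(_latent_timecourse(rng, n_trs)) + 0.1,
                "brightness": 0.5 + 0.2 * _latent_timecourse(rng, n_trs),
                "loudness": np.abs(_latent_timecourse(rng, n_trs)),
                "face": (rng.random(n_trs) < 0.4).astype(int),
            }
        )

    # sparse label weights make the planted factorisation identifiable
    w = rng.gamma(2.0, 0.5, size=(n_labels, n_topics))
    w *= rng.random((n_labels, n_topics)) < 0.4
    empty = w.sum(axis=1) == 0
    w[empty, rng.integers(0, n_topics, size=int(empty.sum()))] = rng.gamma(
        2.0, 0.5, size=int(empty.sum())
    )
    h = rng.gamma(2.0, 0.5, size=(n_topics, n_clips))
    freq = w @ h
    if noise_scale > 0:
        freq = freq + rng.gamma(1.0, noise_scale, size=freq.shape)
    constant_labels = np.array([], dtype=int)
    if n_constant_labels:
        constant_labels = rng.choice(n_labels, size=n_constant_labels, replace=False)
        freq[constant_labels, :] = rng.random(n_constant_labels)[:, None]
    scale = freq.max()
    freq = freq / scale  # frequencies live in [0, 1]
    labels = [f"label-{i:04d}" for i in range(n_labels)]
    freq_df = pd.DataFrame(
        freq, index=labels, columns=[f"clip-{k:04d}" for k in range(n_clips)]
    )
    truth = {
        "W": w / scale,
        "H": h,
        "constant_labels": np.sort(constant_labels),
    }
    return tables, freq_df, truth
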