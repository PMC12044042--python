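"""Per-subject, per-region encoding models and their statistical evaluation.

An encoding model is a SIMPLS regression from HRF-convolved stimulus
features to the BOLD responses of one region's voxels.  Generalization is
estimated by fivefold cross-validation with a seeded random partition of
time points; per-voxel Pearson correlations between concatenated held-out
predictions and observations are Fisher-transformed (atanh) for group
inference.  Group-level tools implement one-sample t maps with
Benjamini-Hochberg FDR control, the voxel-wise vs region-average model
comparison, and the repeated-measures ANOVA with planned contrasts across
the four amygdala subregions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import AMY_SUBREGIONS, FeatureTimeSeries, ParcellatedBOLD
from .pls import PLSModel, pls_predict, simpls_fit

logger = logging.getLogger(__name__)

DEFAULT_N_COMPONENTS = 20
DEFAULT_K_FOLDS = 5


@dataclass
class EncodingModel:
    """A fitted feature -> region-voxel mapping for one subject."""

    subject_id: str
    region: str
    pls: PLSModel
    voxel_ids: np.ndarray
    n_components: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.pls.n_features

    @property
    def n_voxels(self) -> int:
        return self.pls.n_outcomes


@dataclass
class PerformanceMap:
    """Per-voxel cross-validated performance for one subject and region."""

    subject_id: str
    region: str
    voxel_ids: np.ndarray
    voxel_regions: np.ndarray
    r: np.ndarray
    z: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "voxel_id": self.voxel_ids,
                "region": self.voxel_regions,
                "r": self.r,
                "z": self.z,
            }
        )


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilizing Fisher transform, clipped away from |r| = 1."""
    r = np.clip(np.asarray(r, dtype=float), -1.0 + 1e-12, 1.0 - 1e-12)
    return np.arctanh(r)


def _as_matrix(features: FeatureTimeSeries | np.ndarray) -> np.ndarray:
    if isinstance(features, FeatureTimeSeries):
        return features.data
    return np.asarray(features, dtype=float)


def fit_encoding_model(
    features_conv: FeatureTimeSeries | np.ndarray,
    bold: ParcellatedBOLD,
    region: str,
    n_components: int = DEFAULT_N_COMPONENTS,
    subject_id: str = "sub-00",
) -> EncodingModel:
    """Fit a SIMPLS encoding model restricted to one region's voxels.

    The convolved feature series forms the predictor block and the region's
    BOLD time courses the outcome block.  ``region='AMY'`` pools all four
    amygdala subregions.
    """
    X = _as_matrix(features_conv)
    if X.shape[0] != bold.n_timepoints:
        raise ValueError("features and BOLD must have equal row counts")
    idx = bold.parcellation.region_indices(region)
    if idx.size == 0:
        raise ValueError(f"region {region!r} has no voxels")
    Y = bold.data[:, idx]
    pls = simpls_fit(X, Y, n_components=n_components)
    return EncodingModel(
        subject_id=subject_id,
        region=region,
        pls=pls,
        voxel_ids=bold.parcellation.voxel_ids[idx],
        n_components=pls.n_components,
    )


def _pearson_by_column(pred: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r; zero-variance observed columns give r = 0."""
    p = pred - pred.mean(axis=0)
    o = obs - obs.mean(axis=0)
    sp = np.sqrt((p**2).sum(axis=0))
    so = np.sqrt((o**2).sum(axis=0))
    denom = sp * so
    r = np.zeros(pred.shape[1])
    ok = denom > 0
    n_bad = int((so == 0).sum())
    if n_bad:
        logger.warning("%d voxel(s) with zero variance; their r set to 0", n_bad)
    r[ok] = (p[:, ok] * o[:, ok]).sum(axis=0) / denom[ok]
    return r


def make_folds(T: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded random partition of ``range(T)`` into k near-equal folds."""
    if T < k:
        raise ValueError("need at least k time points")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(T)
    return [np.sort(f) for f in np.array_split(perm, k)]


def cross_validate(
    features_conv: FeatureTimeSeries | np.ndarray,
    bold: ParcellatedBOLD,
    region: str,
    k: int = DEFAULT_K_FOLDS,
    n_components: int = DEFAULT_N_COMPONENTS,
    seed: int = 0,
    subject_id: str = "sub-00",
) -> PerformanceMap:
    """K-fold cross-validated per-voxel performance of the encoding model.

    Time points are partitioned at random (seeded); for each fold the model
    is refit on the remaining folds and held-out rows predicted.  Per-voxel
    Pearson r is computed between the concatenated held-out predictions and
    observations, then Fisher-transformed.
    """
    X = _as_matrix(features_conv)
    idx = bold.parcellation.region_indices(region)
    Y = bold.data[:, idx]
    T = X.shape[0]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("features and BOLD must have equal row counts")
    preds = np.empty_like(Y)
    for fold in make_folds(T, k, seed):
        train = np.setdiff1d(np.arange(T), fold)
        model = simpls_fit(X[train], Y[train], n_components=n_components)
        preds[fold] = pls_predict(model, X[fold])
    r = _pearson_by_column(preds, Y)
    return PerformanceMap(
        subject_id=subject_id,
        region=region,
        voxel_ids=bold.parcellation.voxel_ids[idx],
        voxel_regions=bold.parcellation.labels[idx],
        r=r,
        z=fisher_z(r),
    )


def average_response_model(
    features_conv: FeatureTimeSeries | np.ndarray,
    bold: ParcellatedBOLD,
    region: str,
    k: int = DEFAULT_K_FOLDS,
    n_components: int = DEFAULT_N_COMPONENTS,
    seed: int = 0,
    subject_id: str = "sub-00",
) -> PerformanceMap:
    """Cross-validated performance of a model for the region-mean time series.

    Identical to :func:`cross_validate` except the outcome block is the
    single region-average voxel, quantifying how much of the encoding
    model's performance is attributable to the mean response alone.
    """
    X = _as_matrix(features_conv)
    y = bold.region_data(region).mean(axis=1, keepdims=True)
    T = X.shape[0]
    preds = np.empty_like(y)
    for fold in make_folds(T, k, seed):
        train = np.setdiff1d(np.arange(T), fold)
        model = simpls_fit(X[train], y[train], n_components=n_components)
        preds[fold] = pls_predict(model, X[fold])
    r = _pearson_by_column(preds, y)
    return PerformanceMap(
        subject_id=subject_id,
        region=region,
        voxel_ids=np.array([-1]),
        voxel_regions=np.array([region]),
        r=r,
        z=fisher_z(r),
    )


def group_voxel_inference(
    z_maps: "list[PerformanceMap] | np.ndarray",
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-voxel one-sample t tests with Benjamini-Hochberg FDR control.

    Accepts a list of :class:`PerformanceMap` sharing a common voxel space,
    or a subjects x voxels array of Fisher-z values (NaN marks a voxel
    missing for that subject; such voxels are analyzed case-complete and
    the reduced counts are logged).

    Returns a DataFrame with columns t, p, q_sig (BH-significant at the
    given q) and n (subjects contributing per voxel).
    """
    if isinstance(z_maps, (list, tuple)):
        Z = np.vstack([m.z for m in z_maps])
    else:
        Z = np.asarray(z_maps, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError("need a subjects x voxels array with >= 2 subjects")
    n = np.sum(~np.isnan(Z), axis=0)
    incomplete = int((n < Z.shape[0]).sum())
    if incomplete:
        logger.warning(
            "%d voxel(s) missing in some subjects; case-complete analysis", incomplete
        )
    mean = np.nanmean(Z, axis=0)
    sd = np.nanstd(Z, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = np.full_like(t, np.nan)
    ok = (n >= 2) & np.isfinite(t)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=n[ok] - 1)
    sig = np.zeros(t.size, dtype=bool)
    if ok.any():
        sig[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return pd.DataFrame({"t": t, "p": p, "q_sig": sig, "n": n})


@dataclass
class ContrastResult:
    name: str
    weights: np.ndarray
    estimate: float
    t: float
    p: float
    d: float


@dataclass
class SubregionAnova:
    F: float
    p: float
    df_num: float
    df_den: float
    contrasts: list[ContrastResult]


#: Planned contrast weights over (LB, CM, SF, AStr), scaled to unit sum of
#: absolute values so estimates are comparable across contrasts.
PLANNED_CONTRASTS = {
    "LB_vs_rest": np.array([3.0, -1.0, -1.0, -1.0]) / 6.0,
    "CM_vs_SF_AStr": np.array([0.0, 2.0, -1.0, -1.0]) / 4.0,
    "SF_vs_AStr": np.array([0.0, 0.0, 1.0, -1.0]) / 2.0,
}


def subregion_contrast_suite(region_mean_z) -> SubregionAnova:
    """One-way repeated-measures ANOVA plus planned contrasts over subregions.

    ``region_mean_z`` is a subjects x 4 table ordered (LB, CM, SF, AStr):
    the mean Fisher-z performance per amygdala subregion per subject.  The
    ANOVA blocks on subject; each planned contrast is a one-sample t test
    on within-subject contrast scores.
    """
    if isinstance(region_mean_z, pd.DataFrame):
        data = region_mean_z[list(AMY_SUBREGIONS)].to_numpy(dtype=float)
    else:
        data = np.asarray(region_mean_z, dtype=float)
    if data.ndim != 2 or data.shape[1] != 4:
        raise ValueError("expected a subjects x 4 table ordered (LB, CM, SF, AStr)")
    if data.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if np.isnan(data).any():
        raise ValueError("missing cells are not allowed")

    n_s, n_c = data.shape
    grand = data.mean()
    ss_cond = n_s * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = n_c * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_num = n_c - 1
    df_den = (n_s - 1) * (n_c - 1)
    if ss_cond <= 1e-300:
        F, p = 0.0, 1.0
    else:
        ms_err = ss_err / df_den
        if ms_err <= 0:
            F, p = np.inf, 0.0
        else:
            F = (ss_cond / df_num) / ms_err
            p = float(stats.f.sf(F, df_num, df_den))

    contrasts = []
    tol = 1e-12 * max(1.0, float(np.abs(data).max()))
    for name, w in PLANNED_CONTRASTS.items():
        scores = data @ w
        est = float(scores.mean())
        sd = float(scores.std(ddof=1))
        if abs(est) < tol:
            est = 0.0
        if sd <= tol:
            tval, pval, d = 0.0, 1.0, 0.0
        else:
            tval = est / (sd / np.sqrt(n_s))
            pval = float(2.0 * stats.t.sf(abs(tval), df=n_s - 1))
            d = est / sd
        contrasts.append(
            ContrastResult(name=name, weights=w, estimate=est, t=tval, p=pval, d=d)
        )
    return SubregionAnova(
        F=float(F), p=float(p), df_num=df_num, df_den=df_den, contrasts=contrasts
    )
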