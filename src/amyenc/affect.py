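"""Validation of encoding models against affective image ratings.

Predicted model responses to static images are regressed, per subject, on
eight standardized predictors: valence, arousal, their interaction (coded
so that positive-and-arousing images score highest), the three channel
medians, and the high and low spectral band powers.  Inference is the
two-stage summary-statistics approach: ordinary least squares per subject,
then one-sample group t tests on each coefficient with Cohen's d.  A
piecewise variant regresses responses on valence separately within
negative (z < 0), neutral (|z| < 1) and positive (z > 1) image segments —
the segments overlap by definition, which is intentional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import EncodingModel
from .pls import pls_predict

logger = logging.getLogger(__name__)

#: Fixed order of the eight predictors of interest.
DESIGN_COLUMNS = [
    "valence_z",
    "arousal_z",
    "interaction",
    "median_r",
    "median_g",
    "median_b",
    "power_high",
    "power_low",
]

VALENCE_SEGMENTS = ("negative", "neutral", "positive")


def predict_image_response(
    model: EncodingModel, image_features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted voxel activations and region average for image feature rows.

    ``image_features`` is a single length-F vector or an n x F matrix.
    Returns ``(voxel_activations, region_average)`` with one row / element
    per image.
    """
    feats = np.asarray(image_features, dtype=float)
    single = feats.ndim == 1
    vox = pls_predict(model.pls, feats)
    avg = vox.mean(axis=1)
    if single:
        return vox[0], float(avg[0])
    return vox, avg


def _zscore(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=1)
    if sd < 1e-12:
        logger.warning("predictor %s has zero variance; left as zeros", name)
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def build_affect_design(
    ratings: pd.DataFrame, image_features: pd.DataFrame
) -> pd.DataFrame:
    """Assemble the standardized 8-predictor design matrix.

    ``ratings`` must carry columns image_id, valence, arousal;
    ``image_features`` the five low-level covariates keyed by image_id.
    Images missing a rating are dropped with a log message.  The
    valence-arousal interaction is formed from the standardized ratings and
    then itself standardized.  All eight columns have mean 0 and SD 1
    (zero-variance columns are left at 0).
    """
    merged = ratings.merge(image_features, on="image_id", how="inner")
    n_drop = max(len(ratings), len(image_features)) - len(merged)
    if n_drop > 0:
        logger.warning("dropped %d image(s) without matched ratings/features", n_drop)
    missing = merged[["valence", "arousal"]].isna().any(axis=1)
    if missing.any():
        logger.warning("dropped %d image(s) with missing ratings", int(missing.sum()))
        merged = merged.loc[~missing]
    out = pd.DataFrame({"image_id": merged["image_id"].to_numpy()})
    vz = _zscore(merged["valence"].to_numpy(), "valence")
    az = _zscore(merged["arousal"].to_numpy(), "arousal")
    out["valence_z"] = vz
    out["arousal_z"] = az
    out["interaction"] = _zscore(vz * az, "interaction")
    for col_in, col_out in [
        ("median_r", "median_r"),
        ("median_g", "median_g"),
        ("median_b", "median_b"),
        ("power_high", "power_high"),
        ("power_low", "power_low"),
    ]:
        out[col_out] = _zscore(merged[col_in].to_numpy(), col_out)
    return out[["image_id"] + DESIGN_COLUMNS]


@dataclass
class SubjectBetas:
    """Per-subject OLS coefficients on the eight affect predictors."""

    subject_id: str
    region: str
    betas: pd.Series  # indexed by DESIGN_COLUMNS
    intercept: float


def subject_affect_regression(
    responses: np.ndarray,
    design: pd.DataFrame,
    subject_id: str = "sub-00",
    region: str = "AMY",
) -> SubjectBetas:
    """OLS of one subject's per-image responses on the 8-predictor design."""
    y = np.asarray(responses, dtype=float)
    Xd = design[DESIGN_COLUMNS].to_numpy(dtype=float)
    if y.shape[0] != Xd.shape[0]:
        raise ValueError("responses and design must have the same length")
    if y.shape[0] <= 9:
        raise ValueError("need more images than predictors (> 9)")
    X = np.column_stack([np.ones(len(y)), Xd])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify which predictors are linearly dependent on the others
        bad = []
        for j, name in enumerate(DESIGN_COLUMNS):
            others = np.delete(X, j + 1, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(name)
        raise ValueError(f"design is rank-deficient; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return SubjectBetas(
        subject_id=subject_id,
        region=region,
        betas=pd.Series(coef[1:], index=DESIGN_COLUMNS),
        intercept=float(coef[0]),
    )


def betas_table(betas: list[SubjectBetas]) -> pd.DataFrame:
    """Stack per-subject betas into a subjects x predictors table."""
    return pd.DataFrame(
        [b.betas for b in betas], index=[b.subject_id for b in betas]
    )


def _one_sample_suite(B: pd.DataFrame) -> pd.DataFrame:
    n = len(B)
    mean = B.mean(axis=0)
    sd = B.std(axis=0, ddof=1)
    t = np.zeros(B.shape[1])
    p = np.ones(B.shape[1])
    d = np.zeros(B.shape[1])
    nonzero = sd.to_numpy() > 0
    t[nonzero] = mean.to_numpy()[nonzero] / (sd.to_numpy()[nonzero] / np.sqrt(n))
    p[nonzero] = 2.0 * stats.t.sf(np.abs(t[nonzero]), df=n - 1)
    d[nonzero] = mean.to_numpy()[nonzero] / sd.to_numpy()[nonzero]
    return pd.DataFrame(
        {"mean": mean, "t": t, "p": p, "d": d, "n": n}, index=B.columns
    )


def group_affect_test(betas: "list[SubjectBetas] | pd.DataFrame") -> pd.DataFrame:
    """Group one-sample t test (and Cohen's d) per predictor across subjects.

    The subject is the random unit: each predictor's per-subject betas are
    tested against zero; d = mean / SD of the subject betas.
    """
    B = betas_table(betas) if isinstance(betas, list) else betas
    if len(B) < 3:
        raise ValueError("need at least 3 subjects")
    return _one_sample_suite(B)


def valence_segment_mask(valence_z: np.ndarray, segment: str) -> np.ndarray:
    """Boolean mask for a valence segment (segments overlap by definition)."""
    vz = np.asarray(valence_z, dtype=float)
    if segment == "negative":
        return vz < 0
    if segment == "neutral":
        return np.abs(vz) < 1
    if segment == "positive":
        return vz > 1
    raise ValueError(f"unknown segment {segment!r}; expected one of {VALENCE_SEGMENTS}")


def piecewise_valence_regression(
    responses: np.ndarray,
    valence_z: np.ndarray,
    segment: str,
) -> dict:
    """Simple valence regression within one segment, with a group t test.

    ``responses`` is a subjects x images matrix of predicted responses;
    a per-subject slope of response on valence is fit within the segment
    subset and tested against zero across subjects.
    """
    R = np.atleast_2d(np.asarray(responses, dtype=float))
    vz = np.asarray(valence_z, dtype=float)
    mask = valence_segment_mask(vz, segment)
    if mask.sum() == 0:
        raise ValueError(f"segment {segment!r} contains no images")
    if mask.sum() < 10:
        logger.warning("segment %s has only %d images", segment, int(mask.sum()))
    x = vz[mask]
    xc = x - x.mean()
    ssx = (xc**2).sum()
    if ssx == 0:
        raise ValueError("valence has no variance within the segment")
    slopes = (R[:, mask] - R[:, mask].mean(axis=1, keepdims=True)) @ xc / ssx
    n = slopes.size
    sd = slopes.std(ddof=1) if n > 1 else 0.0
    if sd > 0:
        t = slopes.mean() / (sd / np.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
        d = slopes.mean() / sd
    else:
        t, p, d = 0.0, 1.0, 0.0
    return {
        "segment": segment,
        "slopes": slopes,
        "mean_beta": float(slopes.mean()),
        "t": float(t),
        "p": p,
        "d": float(d),
        "n_images": int(mask.sum()),
        "n_subjects": n,
    }


def compare_region_betas(
    betas_a: "list[SubjectBetas] | pd.DataFrame",
    betas_b: "list[SubjectBetas] | pd.DataFrame",
) -> pd.DataFrame:
    """Paired t tests per predictor on A - B subject-beta differences."""
    A = betas_table(betas_a) if isinstance(betas_a, list) else betas_a
    B = betas_table(betas_b) if isinstance(betas_b, list) else betas_b
    if list(A.index) != list(B.index):
        raise ValueError("both regions must carry the same subjects in order")
    return _one_sample_suite(A - B)
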