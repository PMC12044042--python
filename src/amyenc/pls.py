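"""Partial least squares regression (SIMPLS) and PLS discriminant analysis.

SIMPLS (de Jong, 1993) extracts successive score directions that maximize
covariance between predictor and outcome blocks, deflating the F x V
cross-product matrix ``S = X0' Y0`` directly rather than the data blocks.
Both blocks are mean-centered (not variance-scaled) before fitting, which
matches the convention of the MATLAB ``plsregress`` reference this family
of analyses is usually run with; unit-variance scaling is available as an
option.

PLS-DA applies the same regression to a one-hot indicator coding of class
labels and classifies by the argmax of the predicted indicators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).eps


@dataclass
class PLSModel:
    """A fitted SIMPLS regression from an F-column X block to a V-column Y block.

    ``coefficients`` is F x V on the centered scale, so predictions are
    ``(X_new - x_mean) @ coefficients + y_mean``.  ``x_scores`` columns are
    mutually orthogonal by construction.
    """

    x_mean: np.ndarray
    y_mean: np.ndarray
    coefficients: np.ndarray
    n_components: int
    x_scores: np.ndarray
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    x_scale: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_outcomes(self) -> int:
        return self.coefficients.shape[1]

    def save(self, path, **metadata) -> None:
        """Serialize to an ``.npz`` archive with optional string metadata."""
        meta = {f"meta_{k}": np.asarray(str(v)) for k, v in metadata.items()}
        np.savez(
            path,
            x_mean=self.x_mean,
            y_mean=self.y_mean,
            coefficients=self.coefficients,
            n_components=np.asarray(self.n_components),
            x_scores=self.x_scores,
            x_weights=self.x_weights,
            x_loadings=self.x_loadings,
            y_loadings=self.y_loadings,
            **meta,
        )

    @classmethod
    def load(cls, path) -> "PLSModel":
        with np.load(path) as z:
            return cls(
                x_mean=z["x_mean"],
                y_mean=z["y_mean"],
                coefficients=z["coefficients"],
                n_components=int(z["n_components"]),
                x_scores=z["x_scores"],
                x_weights=z["x_weights"],
                x_loadings=z["x_loadings"],
                y_loadings=z["y_loadings"],
            )


def simpls_fit(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    scale: bool = False,
) -> PLSModel:
    """Fit a SIMPLS regression of ``Y`` (T x V) on ``X`` (T x F).

    Components are extracted from the dominant singular direction of the
    deflated cross-product matrix.  A requested component count beyond
    ``min(T - 1, F)`` or beyond the effective rank of ``X`` is clamped with
    a warning rather than raised, since real voxel blocks can be rank
    deficient.

    Parameters
    ----------
    X, Y
        Predictor and outcome blocks with equal row counts and no missing
        values.  A 1-D ``Y`` is treated as a single column.
    n_components
        Number of latent dimensions to retain (>= 1).
    scale
        If True, scale the columns of ``X`` to unit variance after
        centering.  The default mirrors centering-only fitting.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 2-D")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    if X.shape[0] < 2:
        raise ValueError("at least two observations are required")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("X and Y must not contain missing or infinite values")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")

    T, F = X.shape
    V = Y.shape[1]
    max_k = min(T - 1, F)
    if n_components > max_k:
        warnings.warn(
            f"n_components={n_components} exceeds min(T-1, F)={max_k}; clamping",
            stacklevel=2,
        )
        n_components = max_k

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    X0 = X - x_mean
    Y0 = Y - y_mean
    x_scale = None
    if scale:
        x_scale = X0.std(axis=0, ddof=1)
        x_scale[x_scale < _EPS] = 1.0
        X0 = X0 / x_scale

    S = X0.T @ Y0
    R = np.zeros((F, n_components))  # x weights
    Tm = np.zeros((T, n_components))  # x scores
    P = np.zeros((F, n_components))  # x loadings
    Q = np.zeros((V, n_components))  # y loadings
    Vb = np.zeros((F, n_components))  # orthonormal basis for deflation

    k_eff = 0
    first_normt = None
    s_norm0 = np.linalg.norm(S)
    for k in range(n_components):
        if np.linalg.norm(S) <= 1e-12 * max(s_norm0, _EPS):
            warnings.warn(
                f"cross-product deflated to zero after {k} components; "
                f"clamping n_components from {n_components}",
                stacklevel=2,
            )
            break
        # dominant left singular vector of the deflated cross-product,
        # taken from the symmetric eigenproblem of S S' for robustness
        if V == 1:
            r = S[:, 0].copy()
        else:
            _, U = np.linalg.eigh(S @ S.T)
            r = U[:, -1]
        t = X0 @ r
        t = t - t.mean()
        if k > 0:
            # re-orthogonalize against earlier scores for numerical stability
            # (also makes rank exhaustion detectable as a vanishing score)
            proj = Tm[:, :k].T @ t
            t = t - Tm[:, :k] @ proj
            r = r - R[:, :k] @ proj
        normt = np.linalg.norm(t)
        if first_normt is None:
            first_normt = normt
        if normt <= max(1e-10 * first_normt, _EPS):
            warnings.warn(
                f"predictor block rank exhausted after {k} components; "
                f"clamping n_components from {n_components}",
                stacklevel=2,
            )
            break
        t /= normt
        r /= normt
        p = X0.T @ t
        q = Y0.T @ t
        v = p.copy()
        if k > 0:
            v -= Vb[:, :k] @ (Vb[:, :k].T @ p)
        nv = np.linalg.norm(v)
        if nv <= _EPS:
            warnings.warn(
                f"deflation basis degenerate after {k} components; clamping",
                stacklevel=2,
            )
            break
        v /= nv
        S = S - v[:, None] @ (v[None, :] @ S)
        R[:, k], Tm[:, k], P[:, k], Q[:, k], Vb[:, k] = r, t, p, q, v
        k_eff = k + 1

    if k_eff == 0:
        raise ValueError("X block has no variance; cannot fit")
    R, Tm, P, Q = R[:, :k_eff], Tm[:, :k_eff], P[:, :k_eff], Q[:, :k_eff]
    B = R @ Q.T
    if scale:
        B = B / x_scale[:, None]
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        coefficients=B,
        n_components=k_eff,
        x_scores=Tm,
        x_weights=R,
        x_loadings=P,
        y_loadings=Q,
        x_scale=x_scale,
    )


def pls_predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict outcomes for new predictor rows.

    Accepts a single row (1-D) or a matrix; returns a matrix with one row
    per input row and one column per outcome.
    """
    X_new = np.asarray(X_new, dtype=float)
    single = X_new.ndim == 1
    if single:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.n_features}"
        )
    return (X_new - model.x_mean) @ model.coefficients + model.y_mean


@dataclass
class PLSDAModel:
    """PLS discriminant analysis: SIMPLS on one-hot class indicators."""

    pls: PLSModel
    class_labels: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.class_labels.size


def plsda_fit(X: np.ndarray, labels, n_components: int = 7) -> PLSDAModel:
    """Fit a PLS-DA classifier.

    The indicator block has one column per class, ordered by the sorted
    unique labels; prediction is the argmax over predicted indicators with
    ties broken toward the earlier class in that order.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("PLS-DA requires at least two distinct classes")
    Y = (labels[:, None] == classes[None, :]).astype(float)
    pls = simpls_fit(X, Y, n_components=n_components)
    return PLSDAModel(pls=pls, class_labels=classes)


def plsda_decision_values(model: PLSDAModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted indicator scores, one column per class."""
    return pls_predict(model.pls, X_new)


def plsda_predict(model: PLSDAModel, X_new: np.ndarray):
    """Predicted class labels (argmax of indicator scores, first class wins ties)."""
    scores = plsda_decision_values(model, X_new)
    return model.class_labels[np.argmax(scores, axis=1)]
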