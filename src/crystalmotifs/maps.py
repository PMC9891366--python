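"""Principal Covariates Regression (PCovR) maps of motif energetics.

PCovR interpolates between PCA of a feature matrix (alpha = 1) and a
latent space ordered by the variance explained by a regression's
predictions (alpha = 0).  It is implemented here through the augmented
matrix Z = [sqrt(alpha) X, sqrt(1 - alpha) y_hat], whose Gram matrix is
the standard sample-space PCovR kernel

    K = alpha X X^T + (1 - alpha) y_hat y_hat^T,

so the PCA of Z yields the PCovR scores while keeping the out-of-sample
projection exactly linear in x (y_hat itself is a linear ridge
prediction).  Features are column-standardized on the training motifs and
the X and y_hat blocks are normalized to unit Frobenius norm so that
alpha mixes comparable magnitudes.

The maps arrange functional-group motifs by structural similarity and
correlation with their attributed lattice-energy contributions; Euclidean
distance over all retained covariates defines motif similarity for
co-former inspiration searches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .attribution import RegressionModel, fit_energy_model

__all__ = [
    "PCovRModel",
    "MapPoint",
    "fit_pcovr",
    "project",
    "correlate_axes",
    "similar_motifs",
]


@dataclass
class PCovRModel:
    alpha: float
    n_components: int
    x_mean: np.ndarray
    x_std: np.ndarray
    x_norm: float  # Frobenius norm of the standardized training block
    y_mean: float
    y_norm: float
    regression: RegressionModel  # supervised block (on scaled features)
    components: np.ndarray  # ((d+1), k) right singular vectors of Z
    eigenvalues: np.ndarray  # k singular values squared
    training_scores: np.ndarray  # (n, k)

    def _augment(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xs = (X - self.x_mean) / self.x_std / self.x_norm
        yhat = self.regression.predict(Xs)
        yh = (yhat - self.y_mean) / self.y_norm
        return np.hstack(
            [np.sqrt(self.alpha) * Xs, np.sqrt(1.0 - self.alpha) * yh[:, None]]
        )


@dataclass
class MapPoint:
    ref: str
    coordinates: np.ndarray  # PCov_1..k
    color: float  # attributed motif contribution epsilon (kJ/mol atom)
    in_sample: bool = True


def fit_pcovr(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.5,
    n_components: int = 4,
    lambda_grid: Sequence[float] | None = None,
) -> PCovRModel:
    """Fit a PCovR latent space on motif descriptors X and contributions y.

    The supervised block uses ridge *predictions* of y (not raw y), with
    the regularization chosen by cross-validation on the scaled features.
    Component signs are fixed so each component's largest-magnitude
    feature loading is positive, making the map deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if X.shape[0] != len(y):
        raise ValueError("X rows and y length differ")
    x_mean = X.mean(axis=0)
    x_std = X.std(axis=0)
    x_std = np.where(x_std > 1e-14, x_std, 1.0)
    Xs = (X - x_mean) / x_std
    x_norm = float(np.linalg.norm(Xs))
    if x_norm <= 1e-14:
        raise ValueError("features have no variance")
    Xs = Xs / x_norm

    grid = lambda_grid if lambda_grid is not None else None
    reg = (
        fit_energy_model(Xs, y, feature_space="latent")
        if grid is None
        else fit_energy_model(Xs, y, lambda_grid=grid, feature_space="latent")
    )
    yhat = reg.predict(Xs)
    y_mean = float(yhat.mean())
    y_norm = float(np.linalg.norm(yhat - y_mean))
    if y_norm <= 1e-14:
        y_norm = 1.0  # degenerate: constant prediction contributes nothing

    Z = np.hstack(
        [
            np.sqrt(alpha) * Xs,
            np.sqrt(1.0 - alpha) * ((yhat - y_mean) / y_norm)[:, None],
        ]
    )
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size and S[0] > 0 else 0
    if n_components > rank:
        raise ValueError(
            f"requested {n_components} components but rank is {rank}"
        )
    V = Vt[:n_components].T  # ((d+1), k)
    scores = Z @ V
    # sign convention: largest-|loading| entry of each component positive
    for k in range(n_components):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
            scores[:, k] = -scores[:, k]
    return PCovRModel(
        alpha=float(alpha),
        n_components=int(n_components),
        x_mean=x_mean, x_std=x_std, x_norm=x_norm,
        y_mean=y_mean, y_norm=y_norm,
        regression=reg,
        components=V,
        eigenvalues=S[:n_components] ** 2,
        training_scores=scores,
    )


def project(model: PCovRModel, X_new: np.ndarray) -> np.ndarray:
    """Project new motif descriptors into the fitted latent space.

    Linear and idempotent on the training data; the training mean maps to
    the origin.
    """
    Z = model._augment(X_new)
    if Z.shape[1] != model.components.shape[0]:
        raise ValueError("feature dimension mismatch with fitted model")
    return Z @ model.components


def correlate_axes(
    scores: np.ndarray, properties: np.ndarray
) -> np.ndarray:
    """Pearson correlation of each latent axis with each property column.

    Returns a (k, p) array; a zero-variance property yields NaN in its
    column (undefined correlation, reported as such).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    properties = np.asarray(properties, dtype=float)
    if properties.ndim == 1:
        properties = properties[:, None]
    if len(scores) != len(properties):
        raise ValueError("scores and properties are misaligned")
    if len(scores) < 3:
        raise ValueError("need at least 3 points for a correlation")
    s = scores - scores.mean(axis=0)
    p = properties - properties.mean(axis=0)
    s_sd = np.sqrt((s**2).sum(axis=0))
    p_sd = np.sqrt((p**2).sum(axis=0))
    out = np.full((scores.shape[1], properties.shape[1]), np.nan)
    for i in range(scores.shape[1]):
        for j in range(properties.shape[1]):
            if s_sd[i] > 0 and p_sd[j] > 0:
                out[i, j] = float(s[:, i] @ p[:, j] / (s_sd[i] * p_sd[j]))
    return out


def similar_motifs(
    scores: np.ndarray,
    query_indices: Sequence[int],
    k: int,
    candidate_indices: Sequence[int] | None = None,
) -> list[dict]:
    """k nearest and k farthest candidates per query, by full-space distance.

    Distance uses ALL retained covariates, so points that look extremal in
    a 2-D slice of the map need not be extremal here.  Queries are excluded
    from their own candidate list.
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    cand = (
        np.asarray(candidate_indices, dtype=int)
        if candidate_indices is not None
        else np.arange(n)
    )
    out = []
    for q in query_indices:
        if not 0 <= q < n:
            raise IndexError(f"unknown query id {q}")
        mask = cand != q
        pool = cand[mask]
        if k > len(pool):
            raise ValueError(f"k={k} exceeds {len(pool)} candidates")
        d = np.linalg.norm(scores[pool] - scores[q], axis=1)
        order = np.argsort(d, kind="stable")
        out.append(
            {
                "query": int(q),
                "nearest": [(int(pool[i]), float(d[i])) for i in order[:k]],
                "farthest": [
                    (int(pool[i]), float(d[i])) for i in order[::-1][:k]
                ],
            }
        )
    return out
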