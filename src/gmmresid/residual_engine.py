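"""Bartlett factor scores, individual case residuals, and communalities.

Individual case residuals (ICRs) measure how far each person's observed
trajectory lies from what a particular local growth model predicts for them.
They are built in three steps:

1. *Bartlett factor scores* give each individual conditionally unbiased
   estimates of their latent level and shape,
   ``eta_hat_i = eta_mean + (L' Th^-1 L)^-1 L' Th^-1 (y_i - mu)``.
2. *Per-factor residuals* regress each observed occasion y_t on the score of
   each factor j (simple least squares within the individuals the model was
   fitted to) and take ``eps_itj = y_it - yhat_itj``.  For individuals outside
   that set the residual is evaluated against the same fitted line, so it
   measures the distance of an outsider to an existing local model.
3. *Communalities* are the squared Pearson correlation between y_t and the
   score of factor j within the model's individuals; they later serve as the
   normaliser of the closeness measure, down-weighting occasion/factor pairs
   the local model barely explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .growth_model import FittedGrowthModel, LongitudinalData, NumericalError

__all__ = [
    "ResidualBundle",
    "DegenerateClassError",
    "bartlett_scores",
    "per_factor_residuals",
    "communalities",
    "residual_bundle",
]


class DegenerateClassError(RuntimeError):
    """A class is too small or too degenerate to support residual geometry."""


@dataclass
class ResidualBundle:
    """Scores, ICRs and communalities of all N individuals under one model.

    ``scores`` is N x J, ``icr`` is N x T x J and ``communality`` is T x J.
    ``members`` are the row indices of the individuals the model (and its
    regressions/communalities) was computed from; residuals are nevertheless
    evaluated for every row, so out-of-class closeness can be formed.
    """

    scores: np.ndarray
    icr: np.ndarray
    communality: np.ndarray
    class_id: int = 0
    members: np.ndarray | None = None

    def closeness_numerator(self) -> np.ndarray:
        """A_i = sum_{t,j} eps_itj^2 / com_tj for every individual."""
        if np.any(self.communality <= 0):
            raise DegenerateClassError(
                "zero communality: a measured variable is uncorrelated with its score"
            )
        return np.einsum("itj,tj->i", self.icr**2, 1.0 / self.communality)

    def to_long_frame(self, ids=None):
        """Long-format (id, occasion, factor, residual) export for diagnostics."""
        import pandas as pd

        n, T, J = self.icr.shape
        idx = np.arange(1, n + 1) if ids is None else np.asarray(ids)
        rows = {
            "id": np.repeat(idx, T * J),
            "occasion": np.tile(np.repeat(np.arange(1, T + 1), J), n),
            "factor": np.tile(np.arange(1, J + 1), n * T),
            "residual": self.icr.reshape(-1),
        }
        return pd.DataFrame(rows)


def _bartlett(y: np.ndarray, lam: np.ndarray, theta_diag: np.ndarray,
              mu: np.ndarray, eta_mean: np.ndarray) -> np.ndarray:
    """Bartlett estimator on raw arrays (J follows from lam's columns)."""
    wt = 1.0 / np.asarray(theta_diag, dtype=float)
    ltl = (lam.T * wt) @ lam
    if np.linalg.matrix_rank(ltl) < lam.shape[1]:
        raise NumericalError("loading matrix is rank deficient under Theta weighting")
    M = np.linalg.solve(ltl, (lam.T * wt))  # J x T
    return np.asarray(eta_mean) + (np.asarray(y) - np.asarray(mu)) @ M.T


def bartlett_scores(model: FittedGrowthModel, data: LongitudinalData) -> np.ndarray:
    """N x J matrix of Bartlett factor scores under ``model``.

    Conditionally unbiased: E[eta_hat | eta] = eta, because the weighting
    matrix satisfies M Lambda = I.
    """
    return _bartlett(
        data.y,
        model.loading_matrix,
        model.params.theta_full(model.spec),
        model.implied_mu,
        model.params.eta_mean,
    )


def _member_index(n: int, members) -> np.ndarray:
    if members is None:
        return np.arange(n)
    members = np.asarray(members)
    if members.dtype == bool:
        members = np.flatnonzero(members)
    if members.size < 3:
        raise DegenerateClassError(f"need >= 3 individuals, got {members.size}")
    return members


def per_factor_residuals(
    model: FittedGrowthModel,
    scores: np.ndarray,
    data: LongitudinalData,
    members=None,
    mode: str = "per_factor",
) -> np.ndarray:
    """N x T x J array of individual case residuals.

    mode="per_factor" (default): eps_itj is the residual of the simple
    least-squares regression of y_t on the factor-j score, the regression
    being fitted on ``members`` (all rows when None) and evaluated for all
    rows.  mode="model": the full-model residual y_i - Lambda eta_hat_i is
    reused for every factor j.
    """
    y = data.y
    n, T = y.shape
    J = scores.shape[1]
    idx = _member_index(n, members)
    if mode == "model":
        resid = y - scores @ model.loading_matrix.T
        return np.repeat(resid[:, :, None], J, axis=2)
    if mode != "per_factor":
        raise ValueError(f"unknown ICR mode {mode!r}")

    ym = y[idx]
    eps = np.empty((n, T, J))
    for j in range(J):
        x = scores[:, j]
        xm = x[idx]
        vx = xm.var()
        if vx <= 1e-12:
            raise DegenerateClassError(f"factor {j} scores are constant within the class")
        xc = xm - xm.mean()
        b = (ym - ym.mean(axis=0)).T @ xc / (xc @ xc)  # slope per occasion
        a = ym.mean(axis=0) - b * xm.mean()
        eps[:, :, j] = y - (a[None, :] + np.outer(x, b))
    return eps


def communalities(
    scores: np.ndarray,
    data: LongitudinalData,
    members=None,
    mode: str = "per_pair",
) -> np.ndarray:
    """T x J matrix of squared correlations com(eta_j, y_t).

    Computed over ``members`` (all rows when None).  mode="per_pair" keeps
    one value per (occasion, factor) pair; mode="occasion_mean" replaces each
    factor's column by its mean over occasions.
    """
    idx = _member_index(data.n, members)
    y = data.y[idx]
    s = scores[idx]
    yc = y - y.mean(axis=0)
    sc = s - s.mean(axis=0)
    vy = np.einsum("it,it->t", yc, yc)
    vs = np.einsum("ij,ij->j", sc, sc)
    if np.any(vy <= 1e-12) or np.any(vs <= 1e-12):
        raise DegenerateClassError("zero variance in an observed variable or factor score")
    cov = yc.T @ sc  # T x J
    com = cov**2 / np.outer(vy, vs)
    com = np.clip(com, 0.0, 1.0)
    if mode == "occasion_mean":
        com = np.tile(com.mean(axis=0, keepdims=True), (com.shape[0], 1))
    elif mode != "per_pair":
        raise ValueError(f"unknown communality mode {mode!r}")
    return com


def residual_bundle(
    model: FittedGrowthModel,
    data: LongitudinalData,
    members=None,
    class_id: int = 0,
    icr_mode: str = "per_factor",
    com_mode: str = "per_pair",
) -> ResidualBundle:
    """Scores, ICRs and communalities of every individual under one model."""
    scores = bartlett_scores(model, data)
    icr = per_factor_residuals(model, scores, data, members=members, mode=icr_mode)
    com = communalities(scores, data, members=members, mode=com_mode)
    return ResidualBundle(
        scores=scores, icr=icr, communality=com, class_id=class_id,
        members=None if members is None else np.asarray(members),
    )
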