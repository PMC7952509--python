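"""Latent growth curve models fitted by normal-theory maximum likelihood.

A latent growth curve model (LGM) describes T repeated measures y_1..y_T per
individual through two latent growth factors, a level (intercept) eta_0 and a
shape (slope) eta_1.  The model-implied moments of y are

    mu    = Lambda @ eta_mean
    Sigma = Lambda @ Psi @ Lambda' + Theta

with Lambda the T x 2 loading matrix, Psi the 2 x 2 covariance matrix of the
growth factors, and Theta a diagonal matrix of occasion residual variances.
Two loading conventions are supported: the *linear* intercept-slope model,
whose slope loadings are 0, 1, ..., T-1, and the *latent basis* (level and
shape) model, whose first slope loading is fixed at 0, last at 1, with the
T-2 intermediate loadings freely estimated.

Estimation minimises the standard normal-theory discrepancy between sample
and implied moments (see :func:`ml_discrepancy`) with a quasi-Newton
optimiser and analytic gradients.  Variances are optimised on the log scale
and Psi through its Cholesky factor, so fitted solutions are admissible by
construction.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "LoadingKind",
    "ResidualStructure",
    "GrowthModelSpec",
    "GrowthParams",
    "LongitudinalData",
    "FittedGrowthModel",
    "SpecificationError",
    "ParameterError",
    "NumericalError",
    "build_loading_matrix",
    "implied_moments",
    "ml_discrepancy",
    "fit_growth_model",
    "fit_growth_model_moments",
]

log = logging.getLogger("gmmresid")

# Log-variance box constraints keep exp() finite and Sigma positive definite.
_LOG_VAR_MIN = -13.8  # variance floor ~1e-6
_LOG_VAR_MAX = 6.0
_MAX_ITER = 500
_FTOL = 1e-10
_GTOL = 1e-6


class SpecificationError(ValueError):
    """Model specification is internally inconsistent."""


class ParameterError(ValueError):
    """Parameter values violate their admissibility constraints."""


class NumericalError(RuntimeError):
    """A matrix operation required by the fit function is not defined."""


class LoadingKind(str, enum.Enum):
    LINEAR = "linear"
    LATENT_BASIS = "latent_basis"


class ResidualStructure(str, enum.Enum):
    HOMOSCEDASTIC = "homoscedastic"
    OCCASION_SPECIFIC = "occasion_specific"


@dataclass(frozen=True)
class GrowthModelSpec:
    """Structural choices of a two-factor growth model.

    Parameters
    ----------
    n_occasions
        Number of repeated measures T; T >= 3 is required so that a
        latent-basis model with free interior loadings is identified.
    loading_kind
        ``linear`` or ``latent_basis`` slope-loading convention.
    residual_structure
        ``occasion_specific`` (default) estimates one residual variance per
        occasion; ``homoscedastic`` constrains them equal.
    """

    n_occasions: int
    loading_kind: LoadingKind = LoadingKind.LINEAR
    residual_structure: ResidualStructure = ResidualStructure.OCCASION_SPECIFIC

    def __post_init__(self) -> None:
        if self.n_occasions < 3:
            raise SpecificationError(
                f"a two-factor growth model needs T >= 3 occasions, got {self.n_occasions}"
            )
        object.__setattr__(self, "loading_kind", LoadingKind(self.loading_kind))
        object.__setattr__(
            self, "residual_structure", ResidualStructure(self.residual_structure)
        )

    @property
    def n_factors(self) -> int:
        return 2

    @property
    def n_free_loadings(self) -> int:
        if self.loading_kind is LoadingKind.LATENT_BASIS:
            return self.n_occasions - 2
        return 0

    @property
    def n_theta(self) -> int:
        if self.residual_structure is ResidualStructure.OCCASION_SPECIFIC:
            return self.n_occasions
        return 1

    @property
    def n_free_params(self) -> int:
        # 2 factor means + 3 Psi elements + residual variances + free loadings
        return 2 + 3 + self.n_theta + self.n_free_loadings


@dataclass
class GrowthParams:
    """Parameter values of a two-factor growth model.

    ``eta_mean`` holds (eta_0, eta_1); ``psi`` the 2x2 factor covariance
    matrix; ``theta_diag`` the T occasion residual variances; and
    ``free_loadings`` the T-2 interior slope loadings of a latent-basis
    model (empty for linear loadings).
    """

    eta_mean: np.ndarray
    psi: np.ndarray
    theta_diag: np.ndarray
    free_loadings: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.eta_mean = np.asarray(self.eta_mean, dtype=float).reshape(2)
        self.psi = np.asarray(self.psi, dtype=float).reshape(2, 2)
        self.theta_diag = np.atleast_1d(np.asarray(self.theta_diag, dtype=float))
        self.free_loadings = np.atleast_1d(
            np.asarray(self.free_loadings, dtype=float)
        ) if np.size(self.free_loadings) else np.empty(0)

    def validate(self, spec: GrowthModelSpec) -> None:
        if self.theta_diag.shape[0] not in (1, spec.n_occasions):
            raise ParameterError("theta_diag length must be 1 or T")
        if np.any(self.theta_diag <= 0):
            raise ParameterError("residual variances must be positive")
        if not np.allclose(self.psi, self.psi.T, atol=1e-10):
            raise ParameterError("psi must be symmetric")
        if np.min(np.linalg.eigvalsh(self.psi)) < -1e-10:
            raise ParameterError("psi must be positive semi-definite")
        if self.free_loadings.shape[0] != spec.n_free_loadings:
            raise SpecificationError(
                f"expected {spec.n_free_loadings} free loadings, got {self.free_loadings.shape[0]}"
            )

    def theta_full(self, spec: GrowthModelSpec) -> np.ndarray:
        """Length-T residual-variance vector (broadcast if homoscedastic)."""
        if self.theta_diag.shape[0] == spec.n_occasions:
            return self.theta_diag
        return np.full(spec.n_occasions, float(self.theta_diag[0]))


@dataclass
class LongitudinalData:
    """Complete-case wide-format repeated measures: one row per individual."""

    y: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("y must be an N x T matrix")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y must be complete (no missing or non-finite values)")
        if self.ids is None:
            self.ids = np.arange(1, self.y.shape[0] + 1)
        else:
            self.ids = np.asarray(self.ids)
            if self.ids.shape[0] != self.y.shape[0]:
                raise ValueError("ids length must match the number of rows of y")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    @classmethod
    def from_csv(cls, path: str | Path) -> "LongitudinalData":
        """Read ``id,y1,...,yT`` wide CSV."""
        df = pd.read_csv(path)
        ycols = [c for c in df.columns if c.lower() != "id"]
        ids = df["id"].to_numpy() if "id" in df.columns else None
        return cls(y=df[ycols].to_numpy(dtype=float), ids=ids)

    def to_csv(self, path: str | Path) -> None:
        cols = {f"y{t + 1}": self.y[:, t] for t in range(self.n_occasions)}
        pd.DataFrame({"id": self.ids, **cols}).to_csv(path, index=False)


@dataclass
class FittedGrowthModel:
    """A converged (or flagged non-converged) growth model fit."""

    spec: GrowthModelSpec
    params: GrowthParams
    loglik: float
    converged: bool
    n_obs: int
    implied_mu: np.ndarray
    implied_sigma: np.ndarray
    discrepancy: float = np.nan
    n_iter: int = 0

    @property
    def loading_matrix(self) -> np.ndarray:
        return build_loading_matrix(self.spec, self.params.free_loadings)

    def to_report(self) -> dict:
        return {
            "loading_kind": self.spec.loading_kind.value,
            "residual_structure": self.spec.residual_structure.value,
            "n_occasions": self.spec.n_occasions,
            "n_obs": self.n_obs,
            "converged": bool(self.converged),
            "loglik": float(self.loglik),
            "discrepancy": float(self.discrepancy),
            "eta_mean": self.params.eta_mean.tolist(),
            "psi": self.params.psi.tolist(),
            "theta_diag": self.params.theta_full(self.spec).tolist(),
            "free_loadings": self.params.free_loadings.tolist(),
        }

    def params_frame(self) -> pd.DataFrame:
        """Flat key-value table of the estimated parameters."""
        rows = [
            ("eta0_mean", self.params.eta_mean[0]),
            ("eta1_mean", self.params.eta_mean[1]),
            ("psi_00", self.params.psi[0, 0]),
            ("psi_11", self.params.psi[1, 1]),
            ("psi_01", self.params.psi[0, 1]),
        ]
        for t, v in enumerate(self.params.theta_full(self.spec), start=1):
            rows.append((f"theta_{t}", v))
        for t, v in enumerate(self.params.free_loadings, start=2):
            rows.append((f"loading_t{t}", v))
        rows += [("loglik", self.loglik), ("converged", float(self.converged))]
        return pd.DataFrame(rows, columns=["parameter", "value"])

    def write_report(self, json_path: str | Path | None = None,
                     csv_path: str | Path | None = None) -> None:
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.to_report(), indent=2))
        if csv_path is not None:
            self.params_frame().to_csv(csv_path, index=False)


# ---------------------------------------------------------------------------
# Implied moments and the ML fit function
# ---------------------------------------------------------------------------

def build_loading_matrix(
    spec: GrowthModelSpec, free_loadings: np.ndarray | None = None
) -> np.ndarray:
    """Return the T x 2 loading matrix Lambda.

    The first column is all ones (the level factor).  The second column is
    0, 1, ..., T-1 for linear loadings, or [0, b_2, ..., b_{T-1}, 1] for the
    latent-basis convention, where the b's are the supplied free loadings.
    """
    T = spec.n_occasions
    free = np.empty(0) if free_loadings is None else np.atleast_1d(
        np.asarray(free_loadings, dtype=float)
    )
    if free.shape[0] != spec.n_free_loadings:
        raise SpecificationError(
            f"{spec.loading_kind.value} loadings with T={T} require "
            f"{spec.n_free_loadings} free values, got {free.shape[0]}"
        )
    lam = np.ones((T, 2))
    if spec.loading_kind is LoadingKind.LINEAR:
        lam[:, 1] = np.arange(T, dtype=float)
    else:
        lam[0, 1] = 0.0
        lam[-1, 1] = 1.0
        lam[1:-1, 1] = free
    return lam


def implied_moments(
    params: GrowthParams, spec: GrowthModelSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance matrix of y."""
    params.validate(spec)
    lam = build_loading_matrix(spec, params.free_loadings)
    mu = lam @ params.eta_mean
    sigma = lam @ params.psi @ lam.T + np.diag(params.theta_full(spec))
    return mu, 0.5 * (sigma + sigma.T)


def ml_discrepancy(
    sample_mean: np.ndarray,
    sample_cov: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
) -> float:
    """Normal-theory ML discrepancy between sample and implied moments.

    F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - T + (ybar-mu)' Sigma^-1 (ybar-mu)

    F >= 0 with equality iff S = Sigma and ybar = mu.
    """
    S = np.asarray(sample_cov, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    T = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise NumericalError("sample covariance matrix is singular or not PD")
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_m <= 0:
        raise NumericalError("implied covariance matrix is singular or not PD")
    try:
        P = np.linalg.inv(sigma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise NumericalError("implied covariance matrix is not invertible") from exc
    d = np.asarray(sample_mean, dtype=float) - np.asarray(mu, dtype=float)
    return float(logdet_m - logdet_s + np.trace(S @ P) + d @ P @ d - T)


# ---------------------------------------------------------------------------
# Parameter vector packing and analytic gradient
# ---------------------------------------------------------------------------
# Layout: [eta0, eta1, log L00, L10, log L11, log theta (n_theta), free loadings]
# with Psi = L L' and variances on the log scale.

def _pack(params: GrowthParams, spec: GrowthModelSpec) -> np.ndarray:
    psi = params.psi + 1e-10 * np.eye(2)
    try:
        L = np.linalg.cholesky(psi)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(params.psi)
        psi = (V * np.maximum(w, 1e-6)) @ V.T
        L = np.linalg.cholesky(psi)
    theta = params.theta_diag
    if spec.residual_structure is ResidualStructure.OCCASION_SPECIFIC:
        theta = params.theta_full(spec)
    else:
        theta = np.atleast_1d(np.mean(theta))
    return np.concatenate([
        params.eta_mean,
        [np.log(max(L[0, 0], 1e-6)), L[1, 0], np.log(max(L[1, 1], 1e-6))],
        np.log(np.maximum(theta, 1e-6)),
        params.free_loadings,
    ])


def _unpack(x: np.ndarray, spec: GrowthModelSpec) -> GrowthParams:
    nt = spec.n_theta
    eta = x[:2]
    L = np.array([[np.exp(x[2]), 0.0], [x[3], np.exp(x[4])]])
    theta = np.exp(x[5:5 + nt])
    free = x[5 + nt:]
    return GrowthParams(eta_mean=eta, psi=L @ L.T, theta_diag=theta,
                        free_loadings=free)


def _fg(x: np.ndarray, S: np.ndarray, ybar: np.ndarray, logdet_s: float,
        spec: GrowthModelSpec) -> tuple[float, np.ndarray]:
    """Discrepancy F and its analytic gradient w.r.t. the packed vector."""
    T = spec.n_occasions
    nt = spec.n_theta
    eta = x[:2]
    L = np.array([[np.exp(x[2]), 0.0], [x[3], np.exp(x[4])]])
    psi = L @ L.T
    theta = np.exp(x[5:5 + nt])
    theta_full = theta if nt == T else np.full(T, theta[0])
    free = x[5 + nt:]
    lam = build_loading_matrix(spec, free)

    sigma = lam @ psi @ lam.T + np.diag(theta_full)
    P = np.linalg.inv(sigma)
    sign, logdet_m = np.linalg.slogdet(sigma)
    mu = lam @ eta
    d = ybar - mu
    Pd = P @ d
    F = logdet_m - logdet_s + np.trace(S @ P) + d @ Pd - T

    W = P - P @ (S + np.outer(d, d)) @ P
    g_mu = -2.0 * Pd

    grad = np.empty_like(x)
    grad[:2] = lam.T @ g_mu
    G = lam.T @ W @ lam
    GL2 = 2.0 * G @ L
    grad[2] = GL2[0, 0] * L[0, 0]
    grad[3] = GL2[1, 0]
    grad[4] = GL2[1, 1] * L[1, 1]
    wdiag = np.diag(W)
    if nt == T:
        grad[5:5 + nt] = wdiag * theta_full
    else:
        grad[5] = np.sum(wdiag) * theta[0]
    if free.shape[0]:
        M = W @ lam @ psi
        grad[5 + nt:] = 2.0 * M[1:-1, 1] + g_mu[1:-1] * eta[1]
    return float(F), grad


def _moment_start(sample_mean: np.ndarray, sample_cov: np.ndarray,
                  spec: GrowthModelSpec) -> GrowthParams:
    """Deterministic OLS-flavoured starting values from sample moments.

    With a fixed loading matrix the per-person OLS growth coefficients are
    H y_i with H = (Lambda'Lambda)^-1 Lambda', so their mean and covariance
    are H ybar and H S H'; residual variances start at the unexplained
    diagonal of S.
    """
    T = spec.n_occasions
    if spec.loading_kind is LoadingKind.LINEAR:
        free = np.empty(0)
    else:
        free = np.linspace(0.0, 1.0, T)[1:-1]
    lam = build_loading_matrix(spec, free)
    H = np.linalg.solve(lam.T @ lam, lam.T)
    eta0 = H @ sample_mean
    psi_raw = H @ sample_cov @ H.T
    resid = np.diag(sample_cov - lam @ psi_raw @ lam.T)
    theta0 = np.maximum(resid, 0.05 * np.diag(sample_cov))
    # shrink Psi for the part of H S H' that is OLS estimation noise
    psi0 = psi_raw - H @ np.diag(theta0) @ H.T
    w, V = np.linalg.eigh(0.5 * (psi0 + psi0.T))
    psi0 = (V * np.maximum(w, 1e-3)) @ V.T
    if spec.residual_structure is ResidualStructure.HOMOSCEDASTIC:
        theta0 = np.atleast_1d(np.mean(theta0))
    return GrowthParams(eta_mean=eta0, psi=psi0, theta_diag=theta0,
                        free_loadings=free)


def fit_growth_model_moments(
    sample_mean: np.ndarray,
    sample_cov: np.ndarray,
    n_obs: int,
    spec: GrowthModelSpec,
    start: GrowthParams | None = None,
) -> FittedGrowthModel:
    """Fit a growth model to first- and second-order sample moments by ML."""
    S = np.asarray(sample_cov, dtype=float)
    ybar = np.asarray(sample_mean, dtype=float)
    T = spec.n_occasions
    if S.shape != (T, T) or ybar.shape != (T,):
        raise SpecificationError("sample moments do not match the number of occasions")
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise NumericalError("sample covariance matrix is singular or not PD")

    x0 = _pack(start if start is not None else _moment_start(ybar, S, spec), spec)
    nt = spec.n_theta
    bounds: list[tuple[float | None, float | None]] = [(None, None)] * 2
    bounds += [(_LOG_VAR_MIN, _LOG_VAR_MAX), (-50.0, 50.0), (_LOG_VAR_MIN, _LOG_VAR_MAX)]
    bounds += [(_LOG_VAR_MIN, _LOG_VAR_MAX)] * nt
    bounds += [(-10.0, 10.0)] * spec.n_free_loadings

    res = optimize.minimize(
        _fg, x0, args=(S, ybar, logdet_s, spec), jac=True,
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": _MAX_ITER, "ftol": _FTOL, "gtol": _GTOL},
    )
    params = _unpack(res.x, spec)
    mu, sigma = implied_moments(params, spec)
    F = float(res.fun)
    converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-4
    if not converged:
        log.warning("growth model fit did not converge: %s", res.message)
    loglik = -0.5 * n_obs * (F + logdet_s + T + T * np.log(2.0 * np.pi))
    return FittedGrowthModel(
        spec=spec, params=params, loglik=float(loglik), converged=converged,
        n_obs=int(n_obs), implied_mu=mu, implied_sigma=sigma,
        discrepancy=F, n_iter=int(res.nit),
    )


def fit_growth_model(
    data: LongitudinalData,
    spec: GrowthModelSpec,
    start: GrowthParams | None = None,
) -> FittedGrowthModel:
    """Fit a growth model to raw wide-format data by maximum likelihood.

    The fit operates on the sample mean and the ML (divisor N) covariance
    matrix, which are sufficient statistics under the normal model.
    """
    if data.n_occasions != spec.n_occasions:
        raise SpecificationError("data and spec disagree on the number of occasions")
    if data.n <= spec.n_free_params:
        raise SpecificationError(
            f"N={data.n} individuals cannot identify {spec.n_free_params} free parameters"
        )
    ybar = data.y.mean(axis=0)
    S = np.cov(data.y, rowvar=False, ddof=0)
    return fit_growth_model_moments(ybar, S, data.n, spec, start=start)
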