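"""Synthetic K-class longitudinal data matching the Monte Carlo study design.

Each dataset is a finite mixture of linear latent growth trajectories over
T = 4 occasions.  Within class k an individual draws growth factors
eta_i ~ MVN(mean_k, Psi) and occasion noise e_i ~ MVN(0, diag(theta)), and
observes y_i = Lambda eta_i + e_i with slope loadings (0, 1, 2, 3).  The
study's fixed population values are Psi = diag(0.25, 0.04) with zero
intercept-slope covariance and heteroscedastic residual variances
(0.15, 0.20, 0.20, 0.35).  Classes are equally sized (mixing ratio N/K) and
their mean vectors sit equally spaced along a line with adjacent-class
Mahalanobis distance MD = 1 in the Psi metric — a deliberately severe,
poorly separated condition.

Two trajectory conditions are provided: Model 1 places the whole MD budget
on the intercept (different intercepts, same slope); Model 2 splits MD^2
equally between intercept and slope (different intercepts, different
slopes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .growth_model import GrowthModelSpec, LongitudinalData, build_loading_matrix

__all__ = [
    "MODEL_CONDITIONS",
    "SimulationDesign",
    "SimulatedDataset",
    "class_mean_grid",
    "simulate",
]

MODEL_CONDITIONS = {
    1: "diff_intercept_same_slope",
    2: "diff_intercept_diff_slope",
}

_DEFAULT_PSI = (0.25, 0.04)
_DEFAULT_THETA = (0.15, 0.20, 0.20, 0.35)


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of the simulation design grid.

    ``model`` is the trajectory condition (1 = different-intercept-same-
    slope, 2 = different-intercept-different-slope); ``md`` the adjacent-
    class Mahalanobis distance in the Psi metric; ``md_intercept_weight``
    the fraction of MD^2 placed on the intercept under Model 2 (Model 1
    always puts everything on the intercept).  ``base_mean`` positions the
    reference class; the method is invariant to this translation.
    """

    k: int
    n: int
    model: int = 1
    t: int = 4
    psi_diag: tuple[float, float] = _DEFAULT_PSI
    theta_diag: tuple[float, ...] = _DEFAULT_THETA
    md: float = 1.0
    base_mean: tuple[float, float] = (1.0, 0.3)
    md_intercept_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.model not in MODEL_CONDITIONS:
            raise ValueError(f"model must be 1 or 2, got {self.model}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.n % self.k:
            raise ValueError(f"N={self.n} is not divisible into {self.k} equal classes")
        if self.md < 0:
            raise ValueError("md must be >= 0")
        if len(self.theta_diag) != self.t:
            raise ValueError("theta_diag must have one variance per occasion")
        if min(self.psi_diag) <= 0:
            raise ValueError("psi must be positive definite")
        if not 0.0 <= self.md_intercept_weight <= 1.0:
            raise ValueError("md_intercept_weight must lie in [0, 1]")

    @property
    def trajectory_condition(self) -> str:
        return MODEL_CONDITIONS[self.model]

    @property
    def psi(self) -> np.ndarray:
        return np.diag(self.psi_diag)

    def spec(self) -> GrowthModelSpec:
        return GrowthModelSpec(n_occasions=self.t)


@dataclass
class SimulatedDataset:
    data: LongitudinalData
    true_labels: np.ndarray
    class_means: np.ndarray
    seed: int | None = None


def class_mean_grid(design: SimulationDesign) -> np.ndarray:
    """K x 2 matrix of per-class (intercept, slope) means.

    Class means are collinear and equally spaced so that every adjacent pair
    is separated by Mahalanobis distance ``design.md`` under Psi:
    MD^2 = dmu' Psi^-1 dmu.  Model 1 takes dmu = (md * s_eta0, 0); Model 2
    splits MD^2 as (w, 1-w) across intercept and slope, giving
    dmu = (sqrt(w md^2 psi_00), sqrt((1-w) md^2 psi_11)).
    """
    p0, p1 = design.psi_diag
    md2 = design.md**2
    if design.model == 1:
        delta = np.array([np.sqrt(md2 * p0), 0.0])
    else:
        w = design.md_intercept_weight
        delta = np.array([np.sqrt(w * md2 * p0), np.sqrt((1.0 - w) * md2 * p1)])
    base = np.asarray(design.base_mean, dtype=float)
    return base[None, :] + np.arange(design.k)[:, None] * delta[None, :]


def simulate(design: SimulationDesign, seed: int | np.random.Generator | None = None
             ) -> SimulatedDataset:
    """Draw one dataset from the design; bit-reproducible from ``seed``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = class_mean_grid(design)
    per_class = design.n // design.k
    lam = build_loading_matrix(design.spec())  # linear slope loadings 0..T-1

    labels = np.repeat(np.arange(1, design.k + 1), per_class)
    eta = rng.multivariate_normal(np.zeros(2), design.psi, size=design.n)
    eta += means[labels - 1]
    noise = rng.normal(0.0, np.sqrt(np.asarray(design.theta_diag)),
                       size=(design.n, design.t))
    y = eta @ lam.T + noise
    return SimulatedDataset(
        data=LongitudinalData(y=y),
        true_labels=labels,
        class_means=means,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )
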