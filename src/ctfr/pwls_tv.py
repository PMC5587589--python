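"""Penalized weighted least-squares with total-variation regularization.

One image update of the steepest-descent scheme is

    mu_{n+1} = mu_n - tau_n * H - beta * grad TV(mu_n),

where ``H = Gᵀ(Σ⁻¹(G mu_n - y))`` is the gradient of the weighted
data-fidelity term ``½ (G mu - y)ᵀ Σ⁻¹ (G mu - y)`` and ``tau_n`` the
exact line-search minimizer of that quadratic along ``-H``:

    tau_n = HᵀH / (GH)ᵀ Σ⁻¹ (GH).

The smoothed (differentiable) total variation is

    TV(mu) = Σ_{s,t} sqrt((mu_{s,t}-mu_{s-1,t})² + (mu_{s,t}-mu_{s,t-1})² + alpha),

summed over pixels whose upper and left neighbours exist; ``alpha``
keeps the square root differentiable at flat regions.  The weight
``beta`` multiplies the TV gradient directly — there is no separate TV
line search.  No non-negativity constraint is applied here; clamping
happens in the feature-refinement step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import AttenuationImage, ScanGeometry, Sinogram
from .projector import back_project, forward_project
from .simulate import StatisticalWeights

__all__ = [
    "TvConfig",
    "IterationState",
    "tv_value",
    "tv_gradient",
    "wls_gradient",
    "step_size",
    "tv_coefficient",
    "pwls_tv_update",
    "pwls_tv_step",
]

DENOM_FLOOR = 1e-30  # line-search denominator below this flags convergence


@dataclass(frozen=True)
class TvConfig:
    """TV smoothing constant and descent weight.

    ``alpha`` (default 1e-8) keeps the TV functional differentiable;
    ``beta`` (default e⁻²) scales the TV gradient step.
    """

    alpha: float = 1e-8
    beta: float = math.exp(-2.0)
    boundary: str = "crop"  # or "neumann": missing differences count as 0
    tv_step_mode: str = "relative"  # or "absolute"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.boundary not in ("crop", "neumann"):
            raise ValueError("boundary must be 'crop' or 'neumann'")
        if self.tv_step_mode not in ("relative", "absolute"):
            raise ValueError("tv_step_mode must be 'relative' or 'absolute'")


@dataclass
class IterationState:
    """Bookkeeping for one PWLS-TV update."""

    iterate: AttenuationImage
    wls_gradient: np.ndarray
    step_size: float
    iteration_index: int
    wls_cost: float
    tv_cost: float
    converged: bool


def _as_array(image) -> np.ndarray:
    if isinstance(image, AttenuationImage):
        return image.values
    return np.asarray(image, dtype=np.float64)


def _diffs(mu: np.ndarray, boundary: str):
    """Vertical/horizontal backward differences of the summed TV terms."""
    if boundary == "crop":
        dv = mu[1:, 1:] - mu[:-1, 1:]
        dh = mu[1:, 1:] - mu[1:, :-1]
    else:  # neumann: replicate edges, boundary differences vanish
        dv = np.zeros_like(mu)
        dh = np.zeros_like(mu)
        dv[1:, :] = mu[1:, :] - mu[:-1, :]
        dh[:, 1:] = mu[:, 1:] - mu[:, :-1]
    return dv, dh


def tv_value(image, alpha: float, boundary: str = "crop") -> float:
    """Smoothed total variation of a 2-D image.

    ``alpha`` may be 0 for exact (non-smooth) TV in oracle computations.
    """
    mu = _as_array(image)
    if mu.ndim != 2 or mu.shape[0] < 2 or mu.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    dv, dh = _diffs(mu, boundary)
    return float(np.sum(np.sqrt(dv * dv + dh * dh + alpha)))


def tv_gradient(image, alpha: float, boundary: str = "crop") -> np.ndarray:
    """Exact analytic gradient of :func:`tv_value` w.r.t. every pixel.

    Each pixel appears in up to three square-root terms (its own, the
    one below, the one to the right).  Where a term's root vanishes
    (possible only at ``alpha = 0`` on locally flat patches) the
    subgradient 0 is used.
    """
    mu = _as_array(image)
    if mu.ndim != 2 or mu.shape[0] < 2 or mu.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    dv, dh = _diffs(mu, boundary)
    r = np.sqrt(dv * dv + dh * dh + alpha)
    inv = np.where(r > 0.0, 1.0 / np.where(r > 0.0, r, 1.0), 0.0)
    grad = np.zeros_like(mu)
    if boundary == "crop":
        grad[1:, 1:] += (dv + dh) * inv
        grad[:-1, 1:] -= dv * inv
        grad[1:, :-1] -= dh * inv
    else:
        grad += (dv + dh) * inv
        grad[:-1, :] -= (dv * inv)[1:, :]
        grad[:, :-1] -= (dh * inv)[:, 1:]
    return grad


def wls_gradient(mu: AttenuationImage, y: Sinogram,
                 weights: StatisticalWeights,
                 geometry: ScanGeometry) -> AttenuationImage:
    """Gradient ``H = Gᵀ(Σ⁻¹(G mu - y))`` of the weighted data term."""
    residual = forward_project(mu, geometry).values - y.values
    scaled = Sinogram(geometry=geometry,
                      values=residual / weights.variances)
    return back_project(scaled, geometry, mu.grid)


def step_size(H: AttenuationImage, geometry: ScanGeometry,
              weights: StatisticalWeights) -> tuple[float, bool]:
    """Exact line-search step ``tau = HᵀH / (GH)ᵀΣ⁻¹(GH)``.

    Returns ``(tau, converged)``; a vanishing gradient or denominator
    yields ``(0.0, True)``.
    """
    h = H.values
    num = float(np.sum(h * h))
    if num == 0.0:
        return 0.0, True
    gh = forward_project(H, geometry).values
    den = float(np.sum(gh * gh / weights.variances))
    if den < DENOM_FLOOR:
        return 0.0, True
    return num / den, False


def tv_coefficient(config: TvConfig, tau: float, h_values: np.ndarray,
                   tv_grad: np.ndarray) -> float:
    """Coefficient multiplying the TV gradient in the image update.

    ``tv_step_mode="absolute"`` uses ``beta`` verbatim, so the TV move is
    ``beta * grad TV`` regardless of the image scale.  The default
    ``"relative"`` mode scales the unit TV direction by ``beta`` times
    the length of the data-fidelity step,

        mu - tau*H - beta * ||tau*H|| * grad TV / ||grad TV||,

    the steepest-descent-TV convention: ``beta`` then measures the TV
    move as a fraction of the data move and is dimensionless, which is
    what makes a single value like e⁻² meaningful for attenuation images
    of any magnitude.
    """
    if config.tv_step_mode == "absolute":
        return config.beta
    grad_norm = float(np.linalg.norm(tv_grad))
    if grad_norm == 0.0:
        return 0.0
    data_norm = abs(tau) * float(np.linalg.norm(h_values))
    return config.beta * data_norm / grad_norm


def pwls_tv_step(mu: AttenuationImage, y: Sinogram,
                 weights: StatisticalWeights, geometry: ScanGeometry,
                 config: TvConfig,
                 iteration_index: int = 0) -> tuple[AttenuationImage,
                                                    IterationState]:
    """One PWLS-TV image update, returning the new iterate and its state."""
    residual = forward_project(mu, geometry).values - y.values
    wls_cost = 0.5 * float(np.sum(residual * residual / weights.variances))
    H = back_project(
        Sinogram(geometry=geometry, values=residual / weights.variances),
        geometry, mu.grid)
    tau, converged = step_size(H, geometry, weights)
    tv_grad = tv_gradient(mu.values, config.alpha, config.boundary)
    new_values = mu.values - tau * H.values \
        - tv_coefficient(config, tau, H.values, tv_grad) * tv_grad
    new_image = AttenuationImage(grid=mu.grid, values=new_values)
    state = IterationState(
        iterate=new_image,
        wls_gradient=H.values,
        step_size=tau,
        iteration_index=iteration_index,
        wls_cost=wls_cost,
        tv_cost=tv_value(mu.values, config.alpha, config.boundary),
        converged=converged,
    )
    return new_image, state


def pwls_tv_update(mu: AttenuationImage, y: Sinogram,
                   weights: StatisticalWeights, geometry: ScanGeometry,
                   config: TvConfig) -> AttenuationImage:
    """One PWLS-TV image update ``mu - tau*H - beta*grad TV(mu)``."""
    new_image, _ = pwls_tv_step(mu, y, weights, geometry, config)
    return new_image
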