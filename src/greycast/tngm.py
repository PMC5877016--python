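"""The nonlinear grey multivariate model NGM(1,N) and its transformed
derived form TNGM(1,N).

NGM(1,N) generalizes GM(1,N) by raising each accumulated driver to an
exponent γᵢ:

    x₁⁰(k) + a·z₁¹(k) = Σᵢ bᵢ·(xᵢ¹(k))^γᵢ.

Expanding the background value z(k) = x₁¹(k−1) + 0.5·x₁⁰(k) and solving for
x₁⁰(k) gives the *derived* (transformed) model

    x₁⁰(k) = Σᵢ βᵢ·(xᵢ¹(k))^γᵢ − α·x₁¹(k−1),
    βᵢ = bᵢ/(1 + 0.5a),  α = a/(1 + 0.5a),

an explicit recursion in the levels.  (α, β) are a pure view of (a, b): they
are recomputed on access, never estimated or stored independently, so the two
parameterizations cannot drift apart.  With γᵢ ≡ 1 every operation here
degenerates exactly to its GM(1,N) counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateModelError
from .gm1n import fitted_in_sample, time_response
from .series import PreparedDataset

__all__ = ["TNGMParams", "derive_transformed", "tngm_fitted", "tngm_time_response"]


def derive_transformed(a: float, b) -> tuple[float, np.ndarray]:
    """Map difference-equation coefficients (a, b) to the derived-model
    coefficients (α, β): α = a/(1+0.5a), βᵢ = bᵢ/(1+0.5a)."""
    denom = 1.0 + 0.5 * a
    if denom == 0:
        raise DegenerateModelError("a = -2 makes the derived-model transform singular")
    b = np.atleast_1d(np.asarray(b, float))
    return a / denom, b / denom


@dataclass(frozen=True)
class TNGMParams:
    """Parameters of NGM/TNGM(1,N): a, driving coefficients b₂..b_N and
    exponents γ₂..γ_N.  ``alpha``/``beta`` expose the derived-model view."""

    a: float
    b: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "b", np.atleast_1d(np.asarray(self.b, float)))
        object.__setattr__(self, "gamma", np.atleast_1d(np.asarray(self.gamma, float)))
        if self.b.shape != self.gamma.shape:
            raise ValueError("b and gamma must have the same length")
        if not (np.isfinite(self.a) and np.isfinite(self.b).all() and np.isfinite(self.gamma).all()):
            raise DegenerateModelError("non-finite TNGM parameters")
        if 1.0 + 0.5 * self.a == 0:
            raise DegenerateModelError("a = -2 makes the derived model singular")

    @property
    def alpha(self) -> float:
        return derive_transformed(self.a, self.b)[0]

    @property
    def beta(self) -> np.ndarray:
        return derive_transformed(self.a, self.b)[1]

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([[self.a], self.b, self.gamma])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "TNGMParams":
        vec = np.asarray(vec, float)
        m = (len(vec) - 1) // 2
        return cls(a=float(vec[0]), b=vec[1 : 1 + m], gamma=vec[1 + m :])


def tngm_fitted(params: TNGMParams, data: PreparedDataset) -> np.ndarray:
    """In-sample difference-equation fit of NGM/TNGM(1,N):
    fitted(k) = −a·z(k) + Σᵢ bᵢ·(xᵢ¹(k))^γᵢ, with fitted(1) pinned to the
    actual value.  Identical to the derived-model recursion evaluated with
    actual accumulated values."""
    return fitted_in_sample(params, data, gammas=params.gamma)


def tngm_derived_fitted(params: TNGMParams, data: PreparedDataset) -> np.ndarray:
    """The same fit computed through the (α, β) derived form
    x₁⁰(k) = Σ βᵢ (xᵢ¹(k))^γᵢ − α·x₁¹(k−1); exposed for the algebraic
    consistency check between the two parameterizations."""
    from .gm1n import driver_powers

    alpha, beta = derive_transformed(params.a, params.b)
    body = driver_powers(data.X1, params.gamma)[1:] @ beta - alpha * data.y1.values[:-1]
    return np.concatenate([[data.y0[0]], body])


def tngm_time_response(
    params: TNGMParams,
    driver_accumulated_paths: np.ndarray,
    x1_initial: float,
    horizon: int | None = None,
) -> np.ndarray:
    """Grey-constant approximate time response of NGM(1,N) (accumulated
    scale); apply inverse accumulation for level forecasts."""
    return time_response(
        params,
        driver_accumulated_paths,
        x1_initial,
        horizon=horizon,
        gammas=params.gamma,
    )
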