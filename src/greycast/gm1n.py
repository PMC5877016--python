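"""The linear multivariate grey model GM(1,N).

The model couples one system-behaviour series x₁⁰ to N−1 accumulated driving
series through the grey difference equation

    x₁⁰(k) + a·z₁¹(k) = Σᵢ bᵢ·xᵢ¹(k),   k = 2..n,

where z₁¹ is the background (nearest-neighbour mean) series of the
accumulated system series, −a is the development coefficient and the bᵢ are
driving coefficients.  The equation is linear in (a, b), so the parameters
come from ordinary least squares on the stacked design.  Two distinct
"fitted value" notions exist and both are exposed:

- the in-sample *difference-equation fit* −a·z(k) + Σ bᵢ xᵢ¹(k), which uses
  the actual background values and is the default for in-sample evaluation;
- the *time-response recursion*, the grey-constant approximation to the
  whitening ODE solution, used for genuine out-of-sample forecasting where
  actual system values are unavailable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateModelError, PositivityError, RankDeficiencyError
from .series import PreparedDataset

__all__ = [
    "GM1NParams",
    "DesignSystem",
    "FitResult",
    "build_design",
    "ols_estimate",
    "fitted_in_sample",
    "time_response",
    "fit_gm1n",
    "extrapolate_driver",
]

logger = logging.getLogger(__name__)

#: Condition number above which a warning is logged.
COND_WARN = 1e8


@dataclass(frozen=True)
class GM1NParams:
    """Development coefficient ``a`` and driving coefficients ``b``
    (b₂..b_N; the exponents γᵢ are implicitly all 1)."""

    a: float
    b: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "b", np.atleast_1d(np.asarray(self.b, float)))
        if not np.isfinite(self.a) or not np.isfinite(self.b).all():
            raise DegenerateModelError("non-finite GM(1,N) parameters")

    @property
    def gamma(self) -> np.ndarray:
        return np.ones_like(self.b)

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([[self.a], self.b])


@dataclass(frozen=True)
class DesignSystem:
    """Stacked least-squares system: rows of B are
    [−z(k), x₂¹(k)^γ₂, …, x_N¹(k)^γ_N] and Y holds x₁⁰(k), k = 2..n."""

    B: np.ndarray
    Y: np.ndarray

    def __post_init__(self):
        if self.B.shape[0] != self.Y.shape[0]:
            raise ValueError("B and Y row counts differ")


def driver_powers(X1: np.ndarray, gammas: Sequence[float]) -> np.ndarray:
    """Element-wise xᵢ¹(k)^γᵢ with real-power domain checking.

    Zero base is allowed only for γ > 0 (0^γ = 0); negative base, or zero
    base with γ ≤ 0, is a :class:`PositivityError` unless γ is an integer.
    """
    X1 = np.atleast_2d(np.asarray(X1, float))
    g = np.asarray(gammas, float)
    if g.shape != (X1.shape[1],):
        raise ValueError(f"expected {X1.shape[1]} exponents, got {g.shape}")
    for i, gi in enumerate(g):
        col = X1[:, i]
        if float(gi).is_integer():
            if gi < 0 and (col == 0).any():
                raise PositivityError(f"driver {i}: 0 raised to negative power {gi}")
            continue
        if (col < 0).any() or ((col == 0).any() and gi <= 0):
            raise PositivityError(
                f"driver {i}: non-positive accumulated value with fractional "
                f"exponent {gi}"
            )
    return X1**g


def build_design(
    data: PreparedDataset, gammas: Sequence[float] | None = None
) -> DesignSystem:
    """Assemble the least-squares system for GM(1,N) (γ all 1) or its
    nonlinear extension (driver columns raised element-wise to γᵢ)."""
    if gammas is None:
        gammas = np.ones(data.N - 1)
    B = np.column_stack([-data.z.values, driver_powers(data.X1, gammas)[1:]])
    return DesignSystem(B=B, Y=data.y0[1:].copy())


def ols_estimate(design: DesignSystem) -> np.ndarray:
    """Least-squares parameter vector [a, b₂, …, b_N] for the stacked system.

    Three rank cases: square & invertible → exact solve; overdetermined →
    unique least-squares solution (rank-deficiency is an error); under-
    determined → the minimum-norm least-squares solution (pseudoinverse).
    """
    B, Y = design.B, design.Y
    m, p = B.shape
    if m == 0:
        raise ValueError("empty design")
    s = np.linalg.svd(B, compute_uv=False)
    cond = float(s[0] / s[-1]) if s[-1] > 0 else np.inf
    if m >= p:
        rank = int(np.sum(s > s[0] * max(m, p) * np.finfo(float).eps))
        if rank < p:
            raise RankDeficiencyError(
                f"design matrix is numerically singular (condition {cond:.3g})",
                condition=cond,
            )
    if cond > COND_WARN:
        logger.warning("ill-conditioned design: condition number %.3g", cond)
    # gelsd returns the least-squares solution, minimum-norm when underdetermined
    sol, *_ = np.linalg.lstsq(B, Y, rcond=None)
    return sol


def fitted_in_sample(
    params,
    data: PreparedDataset,
    gammas: Sequence[float] | None = None,
) -> np.ndarray:
    """Difference-equation in-sample fit.

    fitted(k) = −a·z(k) + Σᵢ bᵢ·(xᵢ¹(k))^γᵢ for k = 2..n with the actual
    background values; fitted(1) is pinned to the actual initialized value,
    so its error is zero by construction.
    """
    gam = np.asarray(
        gammas if gammas is not None else getattr(params, "gamma", np.ones_like(params.b)),
        float,
    )
    body = -params.a * data.z.values + driver_powers(data.X1, gam)[1:] @ params.b
    return np.concatenate([[data.y0[0]], body])


def time_response(
    params,
    driver_accumulated_paths: np.ndarray,
    x1_initial: float,
    horizon: int | None = None,
    gammas: Sequence[float] | None = None,
) -> np.ndarray:
    """Grey-constant approximate time response (accumulated scale).

    x̂¹(k+1) = [x¹(1) − (1/a)·S(k+1)]·e^(−a·k) + (1/a)·S(k+1),
    S(k+1) = Σᵢ bᵢ·(xᵢ¹(k+1))^γᵢ,

    evaluated for k = 0..horizon.  ``driver_accumulated_paths`` supplies the
    accumulated driver values xᵢ¹(k+1) row-wise (shape (horizon+1, N−1));
    row 0 corresponds to the initial epoch.  Returns the accumulated
    forecast; apply :func:`greycast.series.inverse_accumulate` for levels.
    """
    if params.a == 0:
        raise DegenerateModelError("a = 0: the closed-form time response is invalid")
    X = np.atleast_2d(np.asarray(driver_accumulated_paths, float))
    if X.ndim == 2 and X.shape[1] != len(params.b):
        raise ValueError(f"expected {len(params.b)} driver columns, got {X.shape[1]}")
    if horizon is None:
        horizon = X.shape[0] - 1
    if X.shape[0] < horizon + 1:
        raise ValueError(
            f"driver paths cover {X.shape[0]} epochs, need horizon+1 = {horizon + 1}"
        )
    gam = np.asarray(
        gammas if gammas is not None else getattr(params, "gamma", np.ones_like(params.b)),
        float,
    )
    S = driver_powers(X[: horizon + 1], gam) @ params.b
    k = np.arange(horizon + 1)
    c = S / params.a
    return (x1_initial - c) * np.exp(-params.a * k) + c


@dataclass
class FitResult:
    """A fitted grey model with its in-sample evaluation.

    ``fitted`` follows the difference-equation convention (position 1 pinned
    to the actual value); ``errors_pct`` are signed percentage errors;
    ``mape`` excludes the zero-error base epoch, ``mape_include_base``
    averages over all n epochs.  ``diagnostics`` carries solver information
    for iterative fits (None for OLS).
    """

    model: str
    params: object
    epochs: np.ndarray
    actual: np.ndarray
    fitted: np.ndarray
    errors_pct: np.ndarray
    mape: float
    mape_include_base: float
    diagnostics: object | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Fitted table in the conventional report layout."""
        return pd.DataFrame(
            {
                "Year": self.epochs,
                "Actual Value": self.actual,
                "Model Value": self.fitted,
                "Error": self.errors_pct,
            }
        )

    def to_dict(self) -> dict:
        p = self.params
        d = {
            "model": self.model,
            "params": {
                "a": float(p.a),
                "b": [float(x) for x in p.b],
                "gamma": [float(x) for x in np.asarray(p.gamma)],
            },
            "epochs": [int(e) for e in self.epochs],
            "actual": [float(x) for x in self.actual],
            "fitted": [float(x) for x in self.fitted],
            "errors_pct": [float(x) for x in self.errors_pct],
            "mape": {
                "exclude_base": float(self.mape),
                "include_base": float(self.mape_include_base),
            },
            "meta": self.meta,
        }
        if self.diagnostics is not None:
            d["diagnostics"] = self.diagnostics.summary()
        return d

    def to_json(self, path: str | Path | None = None, **kw) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.15g")


def fit_gm1n(data: PreparedDataset) -> FitResult:
    """Fit GM(1,N) by least squares and evaluate the in-sample fit."""
    from .evaluation import mape as _mape
    from .evaluation import percentage_errors

    sol = ols_estimate(build_design(data))
    params = GM1NParams(a=float(sol[0]), b=sol[1:])
    fitted = fitted_in_sample(params, data)
    errors = percentage_errors(data.y0, fitted, epochs=data.epochs)
    return FitResult(
        model="gm1n",
        params=params,
        epochs=data.epochs,
        actual=data.y0,
        fitted=fitted,
        errors_pct=errors,
        mape=_mape(errors, "exclude_base"),
        mape_include_base=_mape(errors, "include_base"),
        meta={
            "system": data.system.name,
            "drivers": list(data.driver_names),
            "normalization": data.system.mode,
        },
    )


def extrapolate_driver(values: np.ndarray, horizon: int) -> np.ndarray:
    """Optional helper: extend a positive driver series ``horizon`` steps by a
    univariate exponential-trend (GM(1,1)-style) fit.

    Nothing in the fitting pipeline calls this implicitly — future driver
    values for forecasting must normally be supplied by the caller.
    """
    x0 = np.asarray(values, float)
    if (x0 <= 0).any():
        raise PositivityError("exponential driver extrapolation needs positive values")
    x1 = np.cumsum(x0)
    z = 0.5 * (x1[1:] + x1[:-1])
    B = np.column_stack([-z, np.ones(len(z))])
    (a, u), *_ = np.linalg.lstsq(B, x0[1:], rcond=None)
    if a == 0:
        raise DegenerateModelError("degenerate univariate trend (a = 0)")
    k = np.arange(len(x0), len(x0) + horizon)
    acc = (x0[0] - u / a) * np.exp(-a * k) + u / a
    acc_prev = (x0[0] - u / a) * np.exp(-a * (k - 1)) + u / a
    return np.concatenate([x0, acc - acc_prev])
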