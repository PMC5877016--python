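"""Synthetic data from the TNGM(1,N) generating process.

The generator runs the derived-model recursion forward with known
parameters: given accumulated drivers xᵢ¹(k),

    x₁⁰(k) = [Σᵢ bᵢ·(xᵢ¹(k))^γᵢ − a·x₁¹(k−1)] / (1 + 0.5a) + ε(k),

with x₁⁰(1) = 1 and ε ~ N(0, noise_sd²).  Drivers are either explicit paths
or geometric-growth series starting at 1 — the shape of a steadily growing
economic driver.  The defaults mirror the conditions of the packaged
China dataset's wastewater model: 20 annual observations, one driver growing
12%/year, (a, b₂, γ₂) near the empirical estimates, no noise.  At zero noise
the NLS estimators must recover the true parameters; with noise the recovery
bias shrinks with noise_sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import SimulationError
from .series import RawSeries
from .tngm import TNGMParams

__all__ = ["SimulationSpec", "simulate"]

#: Fewest observations the generator will produce (enough for a grey fit
#: with a couple of spare degrees of freedom).
MIN_N = 6


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of a synthetic run.

    ``driver_growth`` gives one geometric growth rate per driver (ignored
    for drivers supplied via ``driver_paths``, which are level series in
    columns).  The seed fully determines the output.
    """

    n: int = 20
    a: float = -0.0426
    b: tuple[float, ...] = (1.0168,)
    gamma: tuple[float, ...] = (-0.099,)
    driver_growth: tuple[float, ...] = (0.12,)
    driver_paths: np.ndarray | None = None
    noise_sd: float = 0.0
    seed: int = 0
    epoch_start: int = 1996

    def __post_init__(self):
        if self.n < MIN_N:
            raise ValueError(f"n must be >= {MIN_N}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.b) != len(self.gamma):
            raise ValueError("b and gamma must have the same length")

    @property
    def true_params(self) -> TNGMParams:
        return TNGMParams(a=self.a, b=np.array(self.b), gamma=np.array(self.gamma))


def simulate(spec: SimulationSpec) -> tuple[RawSeries, list[RawSeries], TNGMParams]:
    """Generate (system series, driver series, true parameters).

    Raises :class:`SimulationError` if the recursion produces a non-positive
    system value (fractional exponents downstream require positivity).
    """
    rng = np.random.default_rng(spec.seed)
    m = len(spec.b)
    epochs = spec.epoch_start + np.arange(spec.n)

    if spec.driver_paths is not None:
        X0 = np.atleast_2d(np.asarray(spec.driver_paths, float))
        if X0.shape != (spec.n, m):
            raise ValueError(f"driver_paths must have shape ({spec.n}, {m})")
    else:
        if len(spec.driver_growth) != m:
            raise ValueError("need one growth rate per driver")
        k = np.arange(spec.n)
        X0 = np.column_stack([(1.0 + g) ** k for g in spec.driver_growth])
    if (X0 <= 0).any():
        raise SimulationError("driver paths must be positive")
    X1 = np.cumsum(X0, axis=0)

    a, b, gamma = spec.a, np.array(spec.b), np.array(spec.gamma)
    denom = 1.0 + 0.5 * a
    if denom == 0:
        raise SimulationError("a = -2 makes the generating recursion singular")
    drive = (X1**gamma) @ b

    y0 = np.empty(spec.n)
    y0[0] = 1.0
    acc = 1.0
    noise = rng.normal(0.0, spec.noise_sd, spec.n) if spec.noise_sd > 0 else np.zeros(spec.n)
    for k in range(1, spec.n):
        val = (drive[k] - a * acc) / denom + noise[k]
        if val <= 0:
            raise SimulationError(
                f"system value {val:.4g} at step {k + 1} is non-positive; "
                "choose parameters/noise that keep the series positive"
            )
        y0[k] = val
        acc += val

    system = RawSeries(name="system", epochs=epochs, values=y0, unit="ratio")
    drivers = [
        RawSeries(name=f"driver{i + 2}", epochs=epochs, values=X0[:, i], unit="ratio")
        for i in range(m)
    ]
    return system, drivers, spec.true_params
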