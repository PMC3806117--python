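"""Canonical chaotic test series with known largest Lyapunov exponents.

These serve as validation oracles for the divergence-curve LLE estimator:
the logistic map at r = 4 has an analytic exponent of ln 2 per iteration,
computable directly from the derivative sum, and the Lorenz system's
exponent is well tabulated (~0.906 nats per time unit for the classic
parameters).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChaoticSeriesSpec",
    "chaotic_series",
    "logistic_series",
    "lorenz_series",
    "logistic_lyapunov_oracle",
]


@dataclass(frozen=True)
class ChaoticSeriesSpec:
    """Parameters for one canonical chaotic series."""

    system: str  # "logistic" | "lorenz"
    length: int
    r: float = 4.0  # logistic growth rate
    x0: float = 0.2  # logistic initial condition
    sigma: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0
    dt: float = 0.01
    initial_state: tuple[float, float, float] = (1.0, 1.0, 1.0)
    transient: int = 1000

    def __post_init__(self) -> None:
        if self.system not in ("logistic", "lorenz"):
            raise ValueError(f"unknown system {self.system!r}")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.system == "logistic" and not (0 < self.r <= 4):
            raise ValueError("logistic growth rate r must be in (0, 4]")


def logistic_series(
    length: int, r: float = 4.0, x0: float = 0.2, transient: int = 1000
) -> np.ndarray:
    """Iterate x_{n+1} = r x_n (1 - x_n), discarding ``transient`` steps."""
    if not (0.0 < x0 < 1.0):
        raise ValueError("logistic initial condition must lie in (0, 1)")
    if not (0 < r <= 4):
        raise ValueError("logistic growth rate r must be in (0, 4]")
    n_total = length + transient
    x = np.empty(n_total)
    x[0] = x0
    for i in range(1, n_total):
        x[i] = r * x[i - 1] * (1.0 - x[i - 1])
    return x[transient:]


def logistic_lyapunov_oracle(
    length: int = 100_000, r: float = 4.0, x0: float = 0.2, transient: int = 1000
) -> float:
    """Analytic Lyapunov exponent of the logistic map via the derivative sum.

    lambda = (1/n) sum ln |r (1 - 2 x_i)|, which converges to ln 2 at r = 4.
    """
    x = logistic_series(length, r=r, x0=x0, transient=transient)
    return float(np.mean(np.log(np.abs(r * (1.0 - 2.0 * x)))))


def _lorenz_deriv(state: np.ndarray, sigma: float, rho: float, beta: float) -> np.ndarray:
    x, y, z = state
    return np.array([sigma * (y - x), x * (rho - z) - y, x * y - beta * z])


def lorenz_series(
    length: int,
    sigma: float = 10.0,
    rho: float = 28.0,
    beta: float = 8.0 / 3.0,
    dt: float = 0.01,
    initial_state: tuple[float, float, float] = (1.0, 1.0, 1.0),
    transient: int = 1000,
) -> np.ndarray:
    """First coordinate of the Lorenz system, fixed-step RK4 integration."""
    state = np.asarray(initial_state, dtype=float)
    n_total = length + transient
    out = np.empty(n_total)
    for i in range(n_total):
        out[i] = state[0]
        k1 = _lorenz_deriv(state, sigma, rho, beta)
        k2 = _lorenz_deriv(state + 0.5 * dt * k1, sigma, rho, beta)
        k3 = _lorenz_deriv(state + 0.5 * dt * k2, sigma, rho, beta)
        k4 = _lorenz_deriv(state + dt * k3, sigma, rho, beta)
        state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return out[transient:]


def chaotic_series(spec: ChaoticSeriesSpec) -> np.ndarray:
    """Generate the series described by ``spec``."""
    if spec.system == "logistic":
        return logistic_series(spec.length, r=spec.r, x0=spec.x0, transient=spec.transient)
    return lorenz_series(
        spec.length,
        sigma=spec.sigma,
        rho=spec.rho,
        beta=spec.beta,
        dt=spec.dt,
        initial_state=spec.initial_state,
        transient=spec.transient,
    )
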