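"""Ornstein-Uhlenbeck model of per-CpG methylation dynamics.

The methylation fraction M(t) at a CpG is modeled as mean-reverting
diffusion dM = theta * (mu - M) dt + sigma dW: mu is the equilibrium
methylation level, theta the restoring ("regulatory") force, and sigma
the stochastic noise level in methylation-fraction units (0.04 = 4%).
High theta pins M near mu, as in normal tissue; a carcinogenic event is
modeled as a drop in theta, which inflates the stationary variance
sigma^2 / (2 theta) and hence cell-to-cell methylation heterogeneity.

Trajectories are integrated with the Euler-Maruyama scheme and clipped
into [0, 1] after each step (methylation is a fraction; the model is
otherwise unbounded). All closed-form checks therefore apply only in
regimes where the truncation is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError

__all__ = ["OUParams", "OUTrace", "simulate_ou", "stationary_moments", "estimate_ou_params"]


@dataclass(frozen=True)
class OUParams:
    """Parameters of one OU simulation run.

    theta : restoring force, 1/time, > 0
    mu    : equilibrium methylation in [0, 1]
    sigma : diffusion coefficient per sqrt(time), >= 0
    dt    : Euler-Maruyama step
    n_steps : number of steps (trace has n_steps + 1 points)
    m0    : initial methylation in [0, 1]
    seed  : RNG seed; one fresh generator per simulation call
    """

    theta: float
    mu: float
    sigma: float = 0.04
    dt: float = 0.01
    n_steps: int = 10_000
    m0: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ConfigError("theta must be > 0")
        if self.sigma < 0:
            raise ConfigError("sigma must be >= 0")
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        if self.n_steps < 1:
            raise ConfigError("n_steps must be >= 1")
        if not (0 <= self.mu <= 1 and 0 <= self.m0 <= 1):
            raise ConfigError("mu and m0 must lie in [0, 1]")


@dataclass(frozen=True)
class OUTrace:
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise DataError("times and values length mismatch")


def simulate_ou(params: OUParams) -> OUTrace:
    """Integrate one OU trajectory by Euler-Maruyama.

    M_{k+1} = M_k + theta (mu - M_k) dt + sigma sqrt(dt) Z_k, clipped to
    [0, 1] after each step. Deterministic given the seed. Raises if
    theta * dt >= 2 (explicit Euler would oscillate divergently).
    """
    if params.theta * params.dt >= 2:
        raise ConfigError(
            f"theta*dt = {params.theta * params.dt:g} >= 2: explicit Euler unstable; "
            "reduce dt"
        )
    rng = np.random.default_rng(params.seed)
    n = params.n_steps
    z = rng.standard_normal(n)
    values = np.empty(n + 1)
    values[0] = params.m0
    a = params.theta * params.dt
    noise = params.sigma * np.sqrt(params.dt)
    m = params.m0
    for k in range(n):
        m = m + a * (params.mu - m) + noise * z[k]
        if m < 0.0:
            m = 0.0
        elif m > 1.0:
            m = 1.0
        values[k + 1] = m
    times = np.arange(n + 1) * params.dt
    return OUTrace(times=times, values=values)


def stationary_moments(params: OUParams) -> tuple[float, float]:
    """Stationary mean and variance (mu, sigma^2 / (2 theta)) of the
    untruncated OU process."""
    if params.theta <= 0:
        raise ConfigError("theta must be > 0")
    return params.mu, params.sigma**2 / (2.0 * params.theta)


def estimate_ou_params(trace: OUTrace, dt: float) -> tuple[float, float, float]:
    """Recover (theta, mu, sigma) from a trace by a discrete AR(1) fit.

    Least-squares fit of M_{k+1} = a M_k + b + eps, then
    theta = (1 - a)/dt, mu = b/(1 - a), sigma = sd(eps)/sqrt(dt).
    Biased when the trace spends time pinned at the [0, 1] boundary.
    """
    v = np.asarray(trace.values, float)
    if len(v) < 101:
        raise DataError("need at least 100 steps for AR(1) estimation")
    if np.ptp(v) == 0:
        raise DataError("constant trace: OU parameters unidentifiable")
    x, y = v[:-1], v[1:]
    A = np.column_stack([x, np.ones_like(x)])
    (a, b), *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - (a * x + b)
    theta_hat = (1.0 - a) / dt
    mu_hat = b / (1.0 - a) if a != 1.0 else float("nan")
    sigma_hat = float(np.std(resid, ddof=2)) / np.sqrt(dt)
    return float(theta_hat), float(mu_hat), sigma_hat
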