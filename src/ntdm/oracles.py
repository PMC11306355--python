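"""Independent numeric integrators used to verify the series solver.

Two solvers that share nothing with the decomposition machinery:

* a classical fixed-step fourth-order Runge–Kutta integrator, the ground
  truth at mu = 1;
* the fractional Adams–Bashforth–Moulton predictor–corrector for Caputo
  systems (product-rectangle predictor, product-trapezoidal corrector, one
  correction per step), the cross-check at mu < 1.

Both return uniform trajectory grids and are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gamma

from .engine import FracODESystem


@dataclass(frozen=True)
class TrajectoryGrid:
    """Uniform-grid trajectory: taus, states (len(taus) x n), solver tag, step."""

    taus: np.ndarray
    states: np.ndarray
    solver: str
    h: float
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.taus) > 0):
            raise ValueError("tau grid must be strictly increasing")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory contains non-finite states")

    def at(self, tau: float) -> np.ndarray:
        """State vector at the grid point closest to tau (must be within h/2)."""
        i = int(np.argmin(np.abs(self.taus - tau)))
        if abs(self.taus[i] - tau) > self.h / 2 + 1e-15:
            raise ValueError(f"tau={tau} is not on the grid (step {self.h})")
        return self.states[i]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.names))
        df.insert(0, "tau", self.taus)
        return df


def rk4_classical(system: FracODESystem, t_end: float, h: float) -> TrajectoryGrid:
    """Fixed-step classical RK4 on the integer-order system."""
    if h <= 0 or t_end < h:
        raise ValueError("need h > 0 and t_end >= h")
    n_steps = int(round(t_end / h))
    taus = np.linspace(0.0, n_steps * h, n_steps + 1)
    states = np.empty((n_steps + 1, system.n))
    states[0] = system.initial
    y = np.asarray(system.initial, dtype=float)
    for i in range(n_steps):
        k1 = system.rhs(y)
        k2 = system.rhs(y + 0.5 * h * k1)
        k3 = system.rhs(y + 0.5 * h * k2)
        k4 = system.rhs(y + h * k3)
        y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise ArithmeticError(f"RK4 blow-up at step {i + 1} (tau={taus[i + 1]:g})")
        states[i + 1] = y
    return TrajectoryGrid(taus, states, "rk4", h, system.names)


def abm_caputo(
    system: FracODESystem, mu: float, t_end: float, h: float
) -> TrajectoryGrid:
    """Fractional Adams–Bashforth–Moulton PECE scheme for Caputo systems.

    Predictor uses the product-rectangle weights
    ``b_j = (n+1-j)^mu - (n-j)^mu``; the corrector uses the standard
    product-trapezoidal weights and one evaluation of the predicted state.
    Reduces to the classical one-step Adams scheme at mu = 1.
    """
    if not (0.0 < mu <= 1.0):
        raise ValueError(f"mu must lie in (0, 1], got {mu}")
    if h <= 0 or t_end < h:
        raise ValueError("need h > 0 and t_end >= h")
    n_steps = int(round(t_end / h))
    taus = np.linspace(0.0, n_steps * h, n_steps + 1)
    y0 = np.asarray(system.initial, dtype=float)
    states = np.empty((n_steps + 1, system.n))
    states[0] = y0
    f_hist = np.empty((n_steps + 1, system.n))
    f_hist[0] = system.rhs(y0)

    g1 = gamma(mu + 1.0)
    g2 = gamma(mu + 2.0)
    # powers (0..n_steps)^mu and ^(mu+1), shared by all steps
    pm = np.arange(n_steps + 2, dtype=float) ** mu
    pm1 = np.arange(n_steps + 2, dtype=float) ** (mu + 1.0)

    for n in range(n_steps):
        j = np.arange(n + 1)
        # predictor weights b_{j,n+1}
        b = pm[n + 1 - j] - pm[n - j]
        y_pred = y0 + (h**mu / g1) * (b @ f_hist[: n + 1])
        # corrector weights a_{j,n+1}
        a = np.empty(n + 1)
        a[0] = pm1[n] - (n - mu) * pm[n + 1]
        if n >= 1:
            jj = j[1:]
            a[1:] = pm1[n - jj + 2] + pm1[n - jj] - 2.0 * pm1[n - jj + 1]
        y = y0 + (h**mu / g2) * (a @ f_hist[: n + 1] + system.rhs(y_pred))
        if not np.all(np.isfinite(y)):
            raise ArithmeticError(f"ABM blow-up at step {n + 1} (tau={taus[n + 1]:g})")
        states[n + 1] = y
        f_hist[n + 1] = system.rhs(y)
    return TrajectoryGrid(taus, states, "abm", h, system.names)


def linear_caputo_ml_series(lam: float, tau: float, mu: float, n_terms: int = 30) -> float:
    """Truncated Mittag–Leffler series solution of D^mu x = lam*x, x(0)=1.

    x(tau) = sum_k (lam * tau^mu)^k / Gamma(1 + k*mu); closed-form oracle
    for the scalar linear test problem.
    """
    return sum((lam * tau**mu) ** k / gamma(1.0 + k * mu) for k in range(n_terms))
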