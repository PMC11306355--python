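"""The five-compartment smoking epidemic model.

States: potential smokers V, occasional smokers G, smokers T, temporary
quitters O, permanent quitters W.  Dynamics (with fractional time
derivative of order mu):

    D^mu V = alpha - epsilon*V*T - vartheta*V
    D^mu G = epsilon*V*T - (eps1 + vartheta)*G
    D^mu T = eps1*G + eps2*T*O - (vartheta + rho)*T
    D^mu O = -eps2*T*O - vartheta*O + rho*(1 - sigma)*T
    D^mu W = sigma*rho*T - vartheta*W

Parameters (all rates per unit time; sigma dimensionless): alpha the
recruitment rate into V, epsilon the effective V–T contact rate, vartheta
the natural death rate, rho the quit rate, sigma the fraction of quitters
who quit permanently, eps1 the occasional-to-regular transition rate, eps2
the relapse contact rate between T and O.

The compartment total N obeys ``D^mu N = alpha - vartheta*N``: the contact
and transfer terms cancel exactly, which the solver-level tests exploit as
a conservation check.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .engine import BilinearTerm, FracODESystem

STATE_NAMES = ("V", "G", "T", "O", "W")


@dataclass(frozen=True)
class ModelParameters:
    """Model rates and initial compartment counts.

    Defaults are the reference parameter set: alpha=1, epsilon=0.14,
    vartheta=0.05, rho=0.8, sigma=0.1, eps1=0.002, eps2=0.0025, with
    initial compartments (V, G, T, O, W) = (40, 10, 20, 10, 5).
    """

    alpha: float = 1.0
    epsilon: float = 0.14
    vartheta: float = 0.05
    rho: float = 0.8
    sigma: float = 0.1
    eps1: float = 0.002
    eps2: float = 0.0025
    V0: float = 40.0
    G0: float = 10.0
    T0: float = 20.0
    O0: float = 10.0
    W0: float = 5.0

    def __post_init__(self) -> None:
        for name in ("alpha", "epsilon", "vartheta", "rho", "eps1", "eps2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"rate {name} must be finite and >= 0, got {v}")
        if not 0.0 <= self.sigma <= 1.0:
            raise ValueError(f"sigma must lie in [0, 1], got {self.sigma}")
        for name in ("V0", "G0", "T0", "O0", "W0"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"initial value {name} must be finite and >= 0, got {v}")

    @property
    def initial(self) -> tuple[float, ...]:
        return (self.V0, self.G0, self.T0, self.O0, self.W0)

    # -- config I/O --------------------------------------------------------

    def to_config(self) -> dict:
        d = asdict(self)
        init = {k[0]: d.pop(k) for k in ("V0", "G0", "T0", "O0", "W0")}
        d["init"] = init
        return d

    @staticmethod
    def from_config(cfg: Mapping) -> "ModelParameters":
        cfg = dict(cfg)
        init = cfg.pop("init", {})
        kwargs = {**cfg, **{f"{k}0": v for k, v in init.items()}}
        valid = set(ModelParameters.__dataclass_fields__)
        unknown = set(kwargs) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return ModelParameters(**kwargs)

    @staticmethod
    def from_json_file(path: str | Path) -> "ModelParameters":
        with open(path) as fh:
            return ModelParameters.from_config(json.load(fh))


def build_system(params: ModelParameters | None = None) -> FracODESystem:
    """Assemble the solver-facing constant + linear + bilinear description."""
    p = params or ModelParameters()
    V, G, T, O, W = range(5)
    linear = np.zeros((5, 5))
    linear[V, V] = -p.vartheta
    linear[G, G] = -(p.eps1 + p.vartheta)
    linear[T, G] = p.eps1
    linear[T, T] = -(p.vartheta + p.rho)
    linear[O, T] = p.rho * (1.0 - p.sigma)
    linear[O, O] = -p.vartheta
    linear[W, T] = p.sigma * p.rho
    linear[W, W] = -p.vartheta
    bilinear = (
        BilinearTerm(V, V, T, -p.epsilon),
        BilinearTerm(G, V, T, +p.epsilon),
        BilinearTerm(T, T, O, +p.eps2),
        BilinearTerm(O, T, O, -p.eps2),
    )
    return FracODESystem(
        names=STATE_NAMES,
        constants=(p.alpha, 0.0, 0.0, 0.0, 0.0),
        linear=tuple(tuple(row) for row in linear),
        bilinear=bilinear,
        initial=p.initial,
    )


def _r0_denominator(p: ModelParameters, T: float) -> float:
    return (p.eps1 + p.vartheta) * (p.vartheta + p.rho) * (p.vartheta + p.epsilon * T)


def reproduction_number(
    params: ModelParameters | None = None, V: float | None = None, T: float | None = None
) -> float:
    """Basic reproduction number of the next-generation construction.

    R0 = eps1*epsilon*vartheta*V / ((eps1+vartheta)(vartheta+rho)(vartheta+epsilon*T)).

    The formula keeps V and T free; they default to the initial compartment
    values, the point at which the headline stability statement evaluates
    them.
    """
    p = params or ModelParameters()
    V = p.V0 if V is None else V
    T = p.T0 if T is None else T
    denom = _r0_denominator(p, T)
    if denom <= 0:
        raise ValueError("reproduction-number denominator must be positive")
    return p.eps1 * p.epsilon * p.vartheta * V / denom


def stability_eigenvalue(
    params: ModelParameters | None = None, V: float | None = None, T: float | None = None
) -> tuple[float, bool]:
    """Dominant eigenvalue lambda of F Q^{-1} and the local-stability verdict.

    lambda coincides with the reproduction number; the smoking-free state is
    locally asymptotically stable when lambda < 1.
    """
    lam = reproduction_number(params, V, T)
    return lam, lam < 1.0


def sensitivity_partials(
    params: ModelParameters | None = None, V: float | None = None, T: float | None = None
) -> dict[str, dict[str, float | str]]:
    """Analytic partial derivatives of R0 w.r.t. eps1, epsilon, rho, vartheta.

    Computed by differentiating the R0 expression directly (via its
    log-derivative for vartheta, which appears in all four factors).  Each
    entry reports the value and its sign at the evaluation point.
    """
    p = params or ModelParameters()
    V = p.V0 if V is None else V
    T = p.T0 if T is None else T
    denom = _r0_denominator(p, T)
    if denom <= 0:
        raise ValueError("reproduction-number denominator must be positive")
    r0 = p.eps1 * p.epsilon * p.vartheta * V / denom
    d_eps1 = (
        p.epsilon * p.vartheta**2 * V
        / ((p.eps1 + p.vartheta) ** 2 * (p.vartheta + p.rho) * (p.vartheta + p.epsilon * T))
    )
    d_epsilon = (
        p.eps1 * p.vartheta**2 * V
        / ((p.eps1 + p.vartheta) * (p.vartheta + p.rho) * (p.vartheta + p.epsilon * T) ** 2)
    )
    d_rho = -r0 / (p.vartheta + p.rho)
    # d(log R0)/d(vartheta) = 1/vartheta - 1/(eps1+vartheta) - 1/(vartheta+rho)
    #                         - 1/(vartheta+epsilon*T)
    d_vartheta = r0 * (
        1.0 / p.vartheta
        - 1.0 / (p.eps1 + p.vartheta)
        - 1.0 / (p.vartheta + p.rho)
        - 1.0 / (p.vartheta + p.epsilon * T)
    )
    out = {}
    for name, val in (
        ("eps1", d_eps1),
        ("epsilon", d_epsilon),
        ("rho", d_rho),
        ("vartheta", d_vartheta),
    ):
        out[name] = {"value": val, "sign": "+" if val > 0 else ("-" if val < 0 else "0")}
    return out


@dataclass
class EquilibriumReport:
    """Stationary points of the model, with plug-back residuals."""

    dfe: tuple[float, ...]
    endemic: tuple[float, ...] | None
    endemic_note: str
    R0: float
    lambda_eig: float
    dfe_locally_stable: bool
    residual_dfe: float
    residual_endemic: float | None
    params: ModelParameters = field(repr=False, default_factory=ModelParameters)

    def to_dict(self) -> dict:
        return {
            "dfe": dict(zip(STATE_NAMES, self.dfe)),
            "endemic": None if self.endemic is None else dict(zip(STATE_NAMES, self.endemic)),
            "endemic_note": self.endemic_note,
            "R0": self.R0,
            "lambda": self.lambda_eig,
            "dfe_locally_stable": self.dfe_locally_stable,
            "residual_dfe": self.residual_dfe,
            "residual_endemic": self.residual_endemic,
            "params": self.params.to_config(),
        }


def endemic_branch(p: ModelParameters, T: float) -> tuple[float, float, float, float]:
    """Forward map of the endemic branch: (V*, G*, O*, W*) as functions of T.

    V* = alpha/(epsilon*T + vartheta); G* = epsilon*alpha*T /
    ((epsilon*T + vartheta)(eps1 + vartheta)); O* = rho(1-sigma)T /
    (eps2*T + vartheta); W* = sigma*rho*T/vartheta.
    """
    V = p.alpha / (p.epsilon * T + p.vartheta)
    G = p.epsilon * p.alpha * T / ((p.epsilon * T + p.vartheta) * (p.eps1 + p.vartheta))
    O = p.rho * (1.0 - p.sigma) * T / (p.eps2 * T + p.vartheta)
    W = p.sigma * p.rho * T / p.vartheta
    return V, G, O, W


def equilibria(params: ModelParameters | None = None) -> EquilibriumReport:
    """Smoking-free and (when it exists) endemic stationary points.

    The smoking-free equilibrium has all smoking classes empty and
    V = alpha/vartheta.  The endemic smoker level T* solves the scalar
    consistency equation eps1*G*(T) + eps2*T*O*(T) - (vartheta+rho)*T = 0
    by bracketed root-finding on T > 0; if no positive root exists the
    endemic entry is reported absent.
    """
    p = params or ModelParameters()
    system = build_system(p)

    dfe = (p.alpha / p.vartheta, 0.0, 0.0, 0.0, 0.0)
    residual_dfe = float(np.max(np.abs(system.rhs(dfe))))

    def t_equation(T: float) -> float:
        _, G, O, _ = endemic_branch(p, T)
        return p.eps1 * G + p.eps2 * T * O - (p.vartheta + p.rho) * T

    endemic = None
    residual_endemic = None
    note = "no positive smoker level solves the stationarity equation"
    lo = 1e-12
    hi = max(p.alpha / max(p.vartheta, 1e-12), 1.0)
    # scan for a sign change of g(T)/T on (0, hi]; g(T) ~ c*T near 0
    grid = np.geomspace(lo, hi, 200)
    vals = np.array([t_equation(t) / t for t in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size:
        i = sign_change[0]
        T_star = brentq(lambda t: t_equation(t) / t, grid[i], grid[i + 1], xtol=1e-12)
        V, G, O, W = endemic_branch(p, T_star)
        endemic = (V, G, T_star, O, W)
        residual_endemic = float(np.max(np.abs(system.rhs(endemic))))
        note = "endemic equilibrium found by bracketed root-finding"

    lam, stable = stability_eigenvalue(p)
    return EquilibriumReport(
        dfe=dfe,
        endemic=endemic,
        endemic_note=note,
        R0=reproduction_number(p),
        lambda_eig=lam,
        dfe_locally_stable=stable,
        residual_dfe=residual_dfe,
        residual_endemic=residual_endemic,
        params=p,
    )
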