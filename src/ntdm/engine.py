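"""The decomposition recursion for fractional ODE systems.

A system ``D^mu x_i = kappa_i + sum_j L[i,j] x_j + sum c x_p x_q`` is solved
as a truncated series ``x_i = sum_{k=0}^K x_{i,k}``: the level-0 component
is the initial value, and each subsequent component is the kernel's
inverse-transform operator applied to the right-hand side assembled from
the previous level.  Bilinear terms enter through their level-k Adomian
polynomial, which for a product ``x_p * x_q`` is the convolution
``sum_{j<=k} x_{p,j} * x_{q,k-j}``.

The constant source ``kappa_i`` is fed into every recursion level by
default (``source_mode="every_level"``); the textbook alternative that
injects it only at level 0 is available as ``source_mode="first_level"``.
See docs/methods.md for why the default is what it is.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .kernels import KernelSpec
from .series import FracSeries

SourceMode = Literal["every_level", "first_level"]


@dataclass(frozen=True)
class BilinearTerm:
    """A contribution ``coefficient * x[factor_p] * x[factor_q]`` to equation ``target``."""

    target: int
    factor_p: int
    factor_q: int
    coefficient: float


@dataclass(frozen=True)
class FracODESystem:
    """Solver-facing description of a constant + linear + bilinear ODE system.

    ``linear[i][j]`` is the coefficient of state j in equation i;
    ``constants[i]`` the constant source of equation i; ``bilinear`` a list
    of products contributing to single equations; ``initial`` the state at
    tau = 0.
    """

    names: tuple[str, ...]
    constants: tuple[float, ...]
    linear: tuple[tuple[float, ...], ...]
    bilinear: tuple[BilinearTerm, ...]
    initial: tuple[float, ...]

    def __post_init__(self) -> None:
        n = self.n
        if len(self.constants) != n or len(self.initial) != n:
            raise ValueError("constants and initial must have one entry per state")
        if len(self.linear) != n or any(len(row) != n for row in self.linear):
            raise ValueError("linear must be an n-by-n matrix")
        arrays = list(self.constants) + list(self.initial) + [c for row in self.linear for c in row]
        for term in self.bilinear:
            for idx in (term.target, term.factor_p, term.factor_q):
                if not 0 <= idx < n:
                    raise ValueError(f"bilinear index {idx} out of range for n={n}")
            arrays.append(term.coefficient)
        if not np.all(np.isfinite(arrays)):
            raise ValueError("all system coefficients must be finite")

    @property
    def n(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown state {name!r}; states are {self.names}") from None

    def rhs(self, x: Sequence[float]) -> np.ndarray:
        """Numeric right-hand side at a state vector (used by the oracles)."""
        x = np.asarray(x, dtype=float)
        out = np.asarray(self.constants, dtype=float) + np.asarray(self.linear, dtype=float) @ x
        for t in self.bilinear:
            out[t.target] += t.coefficient * x[t.factor_p] * x[t.factor_q]
        return out


@dataclass
class NTDMSolution:
    """Truncated series solution: one list of components per state."""

    system: FracODESystem
    spec: KernelSpec
    K: int
    components: list[list[FracSeries]]
    source_mode: SourceMode = "every_level"
    partial_sums: list[FracSeries] = field(init=False)

    def __post_init__(self) -> None:
        sums = []
        for comps in self.components:
            s = FracSeries.zero()
            for c in comps:
                s = s + c
            sums.append(s)
        self.partial_sums = sums

    def evaluate(self, state: int | str, tau: float, upto_k: int | None = None) -> float:
        """Partial sum ``sum_{k<=upto_k} x_{state,k}`` at tau."""
        i = self.system.index(state) if isinstance(state, str) else state
        if not 0 <= i < self.system.n:
            raise KeyError(f"state index {i} out of range")
        if upto_k is None:
            return self.partial_sums[i].evaluate(tau, self.spec.mu)
        if upto_k > self.K:
            raise ValueError(f"upto_k={upto_k} exceeds truncation order K={self.K}")
        total = 0.0
        for k in range(upto_k + 1):
            total += self.components[i][k].evaluate(tau, self.spec.mu)
        return total

    def evaluate_grid(self, taus: Sequence[float]) -> pd.DataFrame:
        """Long-format table of partial-sum values: tau, state, value, kernel, mu, K."""
        rows = []
        for tau in taus:
            for i, name in enumerate(self.system.names):
                rows.append(
                    {
                        "tau": tau,
                        "state": name,
                        "value": self.evaluate(i, tau),
                        "kernel": self.spec.kernel.value,
                        "mu": self.spec.mu,
                        "K": self.K,
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "kernel": self.spec.kernel.value,
            "mu": self.spec.mu,
            "b_mu": self.spec.b_mu,
            "K": self.K,
            "source_mode": self.source_mode,
            "states": {
                name: [comp.to_dict() for comp in comps]
                for name, comps in zip(self.system.names, self.components)
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def adomian_level(
    components: Sequence[Sequence[FracSeries]], p: int, q: int, k: int
) -> FracSeries:
    """Level-k Adomian polynomial of the bilinear product x_p * x_q.

    For a bilinear nonlinearity this is the Cauchy convolution
    ``sum_{j=0}^{k} x_{p,j} * x_{q,k-j}`` of the already-computed components.
    """
    if k >= len(components[p]) or k >= len(components[q]):
        raise ValueError(f"level {k} beyond computed depth")
    out = FracSeries.zero()
    for j in range(k + 1):
        out = out + components[p][j] * components[q][k - j]
    return out


def _level_rhs(
    system: FracODESystem,
    components: list[list[FracSeries]],
    k: int,
    source_mode: SourceMode,
) -> list[FracSeries]:
    """Right-hand side series R_{i,k} feeding the level-(k+1) components."""
    rhs = []
    for i in range(system.n):
        r = FracSeries.zero()
        if source_mode == "every_level" or k == 0:
            r = r + FracSeries.constant(system.constants[i])
        for j in range(system.n):
            coef = system.linear[i][j]
            if coef != 0.0:
                r = r + components[j][k].scale(coef)
        for term in system.bilinear:
            if term.target == i and term.coefficient != 0.0:
                r = r + adomian_level(components, term.factor_p, term.factor_q, k).scale(
                    term.coefficient
                )
        rhs.append(r)
    return rhs


def solve(
    system: FracODESystem,
    spec: KernelSpec,
    K: int = 2,
    source_mode: SourceMode = "every_level",
) -> NTDMSolution:
    """Run the decomposition recursion to truncation order K.

    Deterministic: identical inputs give bit-identical components.  Raises
    ``ArithmeticError`` naming the state and level if a coefficient leaves
    the finite range (only possible for extreme inputs).
    """
    if K < 0:
        raise ValueError(f"truncation order K must be >= 0, got {K}")
    if source_mode not in ("every_level", "first_level"):
        raise ValueError(f"unknown source_mode {source_mode!r}")
    components: list[list[FracSeries]] = [
        [FracSeries.constant(x0)] for x0 in system.initial
    ]
    for k in range(K):
        rhs = _level_rhs(system, components, k, source_mode)
        for i, r in enumerate(rhs):
            try:
                nxt = spec.apply(r)
            except ValueError as exc:
                raise ArithmeticError(
                    f"non-finite coefficient in state {system.names[i]!r} at level {k + 1}"
                ) from exc
            components[i].append(nxt)
    return NTDMSolution(system, spec, K, components, source_mode)


def evaluate_solution(
    sol: NTDMSolution, state: int | str, tau: float, upto_k: int | None = None
) -> float:
    return sol.evaluate(state, tau, upto_k)


def truncation_diagnostic(
    sol: NTDMSolution, tau_grid: Sequence[float], threshold: float = 0.05
) -> pd.DataFrame:
    """Empirical convergence check: last-component share of the partial sum.

    For each state and grid point reports ``|x_{i,K}(tau)| / |S_K(tau)|``
    and whether it is below ``threshold``; the summary column
    ``tau_max_converged`` gives the largest grid tau at which the ratio is
    still below threshold.  Needs at least two components.
    """
    if sol.K < 1:
        raise ValueError("truncation diagnostic needs K >= 1 (at least two components)")
    mu = sol.spec.mu
    rows = []
    for i, name in enumerate(sol.system.names):
        last = sol.components[i][sol.K]
        tau_max = None
        for tau in tau_grid:
            total = sol.evaluate(i, tau)
            last_val = last.evaluate(tau, mu)
            ratio = abs(last_val) / abs(total) if total != 0.0 else np.inf
            ok = ratio < threshold
            if ok:
                tau_max = tau if tau_max is None else max(tau_max, tau)
            rows.append({"state": name, "tau": tau, "ratio": ratio, "converged": ok})
    df = pd.DataFrame(rows)
    tau_max_map = (
        df[df["converged"]].groupby("state")["tau"].max().to_dict()
    )
    df["tau_max_converged"] = df["state"].map(tau_max_map)
    return df
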