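"""Term-wise inverse-transform operators for the three fractional kernels.

The decomposition recursion requires, at each level, the inverse natural
transform of the kernel factor applied to the transform of the current
right-hand side.  Because every right-hand side is a finite sum of
monomials ``c * tau**p``, the transform pair can be eliminated analytically
and each kernel reduces to a term-wise operator:

* Caputo (power-law kernel): the order-mu Riemann–Liouville integral,
  ``c*tau**p -> c * Gamma(p+1)/Gamma(p+mu+1) * tau**(p+mu)``.
* Caputo–Fabrizio (exponential kernel):
  ``c*tau**p -> (1-mu)*c*tau**p + mu*c/(p+1) * tau**(p+1)``.
* Atangana–Baleanu–Caputo (Mittag–Leffler kernel, normalization B(mu)):
  ``c*tau**p -> [(1-mu)*c*tau**p + mu*c*Gamma(p+1)/Gamma(p+mu+1)*tau**(p+mu)] / B(mu)``.

At mu == 1 all three coincide with classical integration.  No quadrature is
ever performed; gamma ratios are evaluated through log-gamma.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from scipy.special import gammaln

from .series import Exponent, FracSeries


class Kernel(str, enum.Enum):
    """Identity of the fractional-derivative kernel."""

    CAPUTO = "caputo"
    CF = "cf"
    ABC = "abc"


def _check_mu(mu: float) -> None:
    if not (0.0 < mu <= 1.0):
        raise ValueError(f"mu must lie in (0, 1], got {mu}")


def _gamma_ratio(p: float, mu: float) -> float:
    # Gamma(p+1) / Gamma(p+mu+1), computed in log space
    return math.exp(gammaln(p + 1.0) - gammaln(p + mu + 1.0))


def apply_caputo(x: FracSeries, mu: float) -> FracSeries:
    """Order-mu Riemann–Liouville integral of a series, term by term."""
    _check_mu(mu)
    out: dict[Exponent, float] = {}
    for exp, c in x:
        p = exp.value(mu)
        key = Exponent(exp.a, exp.b + 1)
        out[key] = out.get(key, 0.0) + c * _gamma_ratio(p, mu)
    return FracSeries(out)


def apply_cf(x: FracSeries, mu: float) -> FracSeries:
    """Caputo–Fabrizio inverse action: (1-mu)*identity + mu*(one integration)."""
    _check_mu(mu)
    out: dict[Exponent, float] = {}
    for exp, c in x:
        p = exp.value(mu)
        if mu != 1.0:
            out[exp] = out.get(exp, 0.0) + (1.0 - mu) * c
        key = Exponent(exp.a + 1, exp.b)
        out[key] = out.get(key, 0.0) + mu * c / (p + 1.0)
    return FracSeries(out)


def apply_abc(x: FracSeries, mu: float, b_mu: float = 1.0) -> FracSeries:
    """Atangana–Baleanu inverse action: [(1-mu)*id + mu*I^mu] / B(mu)."""
    _check_mu(mu)
    if b_mu <= 0:
        raise ValueError(f"normalization B(mu) must be positive, got {b_mu}")
    out: dict[Exponent, float] = {}
    for exp, c in x:
        p = exp.value(mu)
        if mu != 1.0:
            out[exp] = out.get(exp, 0.0) + (1.0 - mu) * c / b_mu
        key = Exponent(exp.a, exp.b + 1)
        out[key] = out.get(key, 0.0) + mu * c * _gamma_ratio(p, mu) / b_mu
    return FracSeries(out)


@dataclass(frozen=True)
class KernelSpec:
    """A kernel choice together with its fractional order and normalization.

    ``b_mu`` is the normalization of the Mittag–Leffler kernel; it only
    affects the ABC operator and defaults to 1, the value under which the
    ABC series components carry no extra prefactor.
    """

    kernel: Kernel
    mu: float
    b_mu: float = field(default=1.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "kernel", Kernel(self.kernel))
        _check_mu(self.mu)
        if self.b_mu <= 0:
            raise ValueError(f"normalization B(mu) must be positive, got {self.b_mu}")

    def apply(self, x: FracSeries) -> FracSeries:
        """Dispatch the term-wise inverse-transform operator for this kernel."""
        if self.kernel is Kernel.CAPUTO:
            return apply_caputo(x, self.mu)
        if self.kernel is Kernel.CF:
            return apply_cf(x, self.mu)
        if self.kernel is Kernel.ABC:
            return apply_abc(x, self.mu, self.b_mu)
        raise ValueError(f"unknown kernel {self.kernel!r}")  # pragma: no cover


def apply_kernel(spec: KernelSpec, x: FracSeries) -> FracSeries:
    return spec.apply(x)
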