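"""Exact algebra for generalized power series in a fractional order.

Every component produced by the decomposition recursion — under the Caputo,
Caputo–Fabrizio, or Atangana–Baleanu–Caputo kernel — is a finite linear
combination of monomials ``c * tau**(a + b*mu)`` with nonnegative integer
``a`` (plain powers, produced by the exponential-kernel operator) and ``b``
(multiples of the fractional order, produced by the power-law and
Mittag–Leffler operators).  This module implements that closed family
exactly: exponents are integer pairs, never floats, so terms from different
kernels coexist without spurious merging at special values of ``mu``.

Coefficients are double-precision floats; gamma-function factors arising
from fractional integration are folded into them numerically (via log-gamma
for stability, see :mod:`ntdm.kernels`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, NamedTuple


class Exponent(NamedTuple):
    """Exponent of a monomial ``tau**(a + b*mu)``.

    ``a`` counts plain integer powers of tau, ``b`` counts multiples of the
    fractional order mu.  Equality is exact pair equality.
    """

    a: int
    b: int

    def value(self, mu: float) -> float:
        """Numeric exponent ``a + b*mu`` at a concrete fractional order."""
        return self.a + self.b * mu

    def __add__(self, other: "Exponent") -> "Exponent":  # type: ignore[override]
        return Exponent(self.a + other.a, self.b + other.b)

    def validate(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError(f"exponent must be nonnegative, got (a={self.a}, b={self.b})")


@dataclass(frozen=True)
class SeriesTerm:
    """A single monomial ``coefficient * tau**(a + b*mu)``."""

    coefficient: float
    exponent: Exponent

    def __post_init__(self) -> None:
        if not math.isfinite(self.coefficient):
            raise ValueError(f"non-finite coefficient {self.coefficient!r}")
        self.exponent.validate()


class FracSeries:
    """A finite sum of monomials ``c * tau**(a + b*mu)`` with unique exponents.

    Canonical form: no two terms share an exponent pair, and exact-zero
    coefficients are dropped.  Addition, scaling and multiplication are
    exact at the level of exponent keys; only the coefficient arithmetic is
    floating point.
    """

    __slots__ = ("_terms",)

    def __init__(self, terms: Mapping[Exponent, float] | Iterable[tuple[Exponent, float]] = ()):
        items = terms.items() if isinstance(terms, Mapping) else terms
        acc: dict[Exponent, float] = {}
        for exp, coef in items:
            exp = Exponent(*exp)
            exp.validate()
            if not math.isfinite(coef):
                raise ValueError(f"non-finite coefficient {coef!r} at exponent {exp}")
            acc[exp] = acc.get(exp, 0.0) + coef
        self._terms = {exp: c for exp, c in acc.items() if c != 0.0}

    # -- constructors ------------------------------------------------------

    @staticmethod
    def zero() -> "FracSeries":
        return FracSeries()

    @staticmethod
    def constant(c: float) -> "FracSeries":
        """Series with the single term ``c * tau**0``; empty when c == 0."""
        if not math.isfinite(c):
            raise ValueError(f"non-finite constant {c!r}")
        return FracSeries({Exponent(0, 0): c} if c != 0.0 else {})

    @staticmethod
    def monomial(c: float, a: int, b: int) -> "FracSeries":
        return FracSeries({Exponent(a, b): c})

    # -- ring operations ---------------------------------------------------

    def __add__(self, other: "FracSeries") -> "FracSeries":
        if not isinstance(other, FracSeries):
            return NotImplemented
        merged = dict(self._terms)
        for exp, c in other._terms.items():
            merged[exp] = merged.get(exp, 0.0) + c
        return FracSeries(merged)

    def __sub__(self, other: "FracSeries") -> "FracSeries":
        return self + other.scale(-1.0)

    def scale(self, c: float) -> "FracSeries":
        if not math.isfinite(c):
            raise ValueError(f"non-finite scale factor {c!r}")
        if c == 0.0:
            return FracSeries()
        return FracSeries({exp: c * v for exp, v in self._terms.items()})

    def __mul__(self, other: "FracSeries") -> "FracSeries":
        """Full convolution product; exponent pairs add component-wise."""
        if not isinstance(other, FracSeries):
            return NotImplemented
        out: dict[Exponent, float] = {}
        for e1, c1 in self._terms.items():
            for e2, c2 in other._terms.items():
                key = e1 + e2
                out[key] = out.get(key, 0.0) + c1 * c2
        return FracSeries(out)

    # -- evaluation --------------------------------------------------------

    def evaluate(self, tau: float, mu: float) -> float:
        """Evaluate ``sum c * tau**(a + b*mu)`` at a point.

        Terms are summed in ascending numeric-exponent order (ties broken by
        (b, a)) so the result is reproducible.  Convention at tau == 0:
        ``tau**0 == 1`` and any positive power is 0.
        """
        if tau < 0:
            raise ValueError(f"tau must be >= 0, got {tau}")
        if not (0.0 < mu <= 1.0):
            raise ValueError(f"mu must lie in (0, 1], got {mu}")
        total = 0.0
        for exp, c in self.sorted_terms(mu):
            p = exp.value(mu)
            if tau == 0.0:
                total += c if p == 0.0 else 0.0
            else:
                total += c * tau**p
        return total

    def sorted_terms(self, mu: float) -> list[tuple[Exponent, float]]:
        """Terms ordered by ascending ``a + b*mu``, ties broken by (b, a)."""
        return sorted(self._terms.items(), key=lambda kv: (kv[0].value(mu), kv[0].b, kv[0].a))

    # -- container protocol ------------------------------------------------

    @property
    def terms(self) -> dict[Exponent, float]:
        return dict(self._terms)

    def coefficient(self, a: int, b: int) -> float:
        return self._terms.get(Exponent(a, b), 0.0)

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self) -> Iterator[tuple[Exponent, float]]:
        return iter(self._terms.items())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FracSeries):
            return NotImplemented
        return self._terms == other._terms

    def __hash__(self) -> int:  # pragma: no cover - dict keys of series unused
        return hash(frozenset(self._terms.items()))

    def is_zero(self) -> bool:
        return not self._terms

    def max_b(self) -> int:
        return max((e.b for e in self._terms), default=0)

    def max_a(self) -> int:
        return max((e.a for e in self._terms), default=0)

    def allclose(self, other: "FracSeries", atol: float = 0.0, rtol: float = 1e-12) -> bool:
        """Coefficient-wise comparison on the union of exponent keys."""
        keys = set(self._terms) | set(other._terms)
        for k in keys:
            x, y = self._terms.get(k, 0.0), other._terms.get(k, 0.0)
            if abs(x - y) > atol + rtol * max(abs(x), abs(y)):
                return False
        return True

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        terms = sorted(self._terms.items(), key=lambda kv: (kv[0].a, kv[0].b))
        return {"terms": [{"coef": c, "a": e.a, "b": e.b} for e, c in terms]}

    @staticmethod
    def from_dict(data: Mapping) -> "FracSeries":
        return FracSeries({Exponent(t["a"], t["b"]): t["coef"] for t in data["terms"]})

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @staticmethod
    def from_json(text: str) -> "FracSeries":
        return FracSeries.from_dict(json.loads(text))

    def __repr__(self) -> str:
        if not self._terms:
            return "FracSeries(0)"
        parts = []
        for exp, c in sorted(self._terms.items(), key=lambda kv: (kv[0].a, kv[0].b)):
            if exp == (0, 0):
                parts.append(f"{c:g}")
            else:
                bits = []
                if exp.a:
                    bits.append(f"t^{exp.a}" if exp.a != 1 else "t")
                if exp.b:
                    bits.append(f"t^({exp.b}*mu)" if exp.b != 1 else "t^mu")
                parts.append(f"{c:g}*" + "*".join(bits))
        return "FracSeries(" + " + ".join(parts) + ")"


# Thin functional aliases mirroring the operation-style API.

def constant_series(c: float) -> FracSeries:
    return FracSeries.constant(c)


def add(x: FracSeries, y: FracSeries) -> FracSeries:
    return x + y


def scale(x: FracSeries, c: float) -> FracSeries:
    return x.scale(c)


def multiply(x: FracSeries, y: FracSeries) -> FracSeries:
    return x * y


def evaluate(x: FracSeries, tau: float, mu: float) -> float:
    return x.evaluate(tau, mu)
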