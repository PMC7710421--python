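"""Combinatorial representational capacity of a binary population code.

A population of N neurons with exactly A of them active can realise
C(N, A) = N! / (A! (N-A)!) distinct activity patterns; that binomial
coefficient is the representational capacity used throughout.  Capacities at
the scales of interest (N up to ~1000-2000) are astronomically large, so
exact values are kept as Python arbitrary-precision integers and compared as
integers; logarithms of exact values are taken directly on the big integer
(``math.log`` handles integers beyond float range), and ratios of two exact
capacities go through ``fractions.Fraction`` so the float conversion is
correctly rounded.

The Stirling expansion of log-capacity,

    log C(N, pN) ~ N*H(p) - 0.5*log(2*pi*N*p*(1-p)),

with H the binary entropy, is the bridge to the continuous analysis: per
neuron, log-capacity tends to H(p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

__all__ = [
    "NetworkConfig",
    "CapacityResult",
    "exact_capacity",
    "binary_entropy",
    "stirling_log_capacity",
    "normalized_capacity",
    "capacity_table",
]

_LN10 = math.log(10.0)


def _log(x: float, base: float) -> float:
    if base == 10:
        return math.log10(x) if not isinstance(x, int) else math.log(x) / _LN10
    if base == math.e:
        return math.log(x)
    return math.log(x) / math.log(base)


@dataclass(frozen=True)
class NetworkConfig:
    """A population of N neurons of which A are active.

    Sparseness p = A/N is derived.  N >= 1 and 0 <= A <= N are enforced.
    """

    N: int
    A: int

    def __post_init__(self) -> None:
        if not isinstance(self.N, int) or not isinstance(self.A, int):
            raise TypeError("N and A must be integers")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if not (0 <= self.A <= self.N):
            raise ValueError(f"need 0 <= A <= N, got A={self.A}, N={self.N}")

    @property
    def p(self) -> float:
        """Sparseness: fraction of active neurons, A/N."""
        return self.A / self.N


@dataclass(frozen=True)
class CapacityResult:
    """Exact capacity with its log and an optional normalized value.

    ``exact`` is the arbitrary-precision binomial coefficient; ``log_value``
    its logarithm in ``base``; ``normalized`` the ratio to a reference
    network's capacity (None when no reference was given).
    """

    exact: int
    log_value: float
    base: float
    normalized: float | None = None


def exact_capacity(
    net: NetworkConfig,
    base: float = 10.0,
    reference: NetworkConfig | None = None,
) -> CapacityResult:
    """Exact representational capacity C(N, A) of a network.

    Computed with integer arithmetic only (no floating-point factorials).
    When ``reference`` is given, ``normalized`` holds
    C(net) / C(reference) as a correctly rounded float.
    """
    exact = math.comb(net.N, net.A)
    result_norm = None
    if reference is not None:
        result_norm = normalized_capacity(net, reference)
    return CapacityResult(
        exact=exact,
        log_value=_log(exact, base),
        base=base,
        normalized=result_norm,
    )


def binary_entropy(p: float, base: float = math.e) -> float:
    """Binary entropy H(p) = -p log p - (1-p) log(1-p).

    H(0) = H(1) = 0 by continuity.  ``base`` selects the logarithm (nats for
    e, "dits" for 10, bits for 2).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    if p == 0.0 or p == 1.0:
        return 0.0
    return -p * _log(p, base) - (1.0 - p) * _log(1.0 - p, base)


def stirling_log_capacity(
    N: float,
    p: float,
    base: float = math.e,
    variant: str = "standard",
) -> float:
    """Stirling approximation to log C(N, N*p).

    Returns ``N*H(p) - 0.5*log(N) - C`` in the requested base, where the
    correction constant is

    - ``variant="standard"``: C = 0.5*log(2*pi*p*(1-p)), the full
      second-order Stirling correction, so the result is
      N*H(p) - 0.5*log(2*pi*N*p*(1-p));
    - ``variant="no-pi"``: C = 0.5*log(2*p*(1-p)), a variant circulating in
      the sparse-coding literature that drops the factor pi.

    N*p need not be integral; N >= 1 and 0 < p < 1 are required.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N!r}")
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie strictly inside (0, 1), got {p!r}")
    if variant == "standard":
        const = 2.0 * math.pi * p * (1.0 - p)
    elif variant == "no-pi":
        const = 2.0 * p * (1.0 - p)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return (
        N * binary_entropy(p, base)
        - 0.5 * _log(float(N), base)
        - 0.5 * _log(const, base)
    )


def normalized_capacity(net: NetworkConfig, reference: NetworkConfig) -> float:
    """Capacity of ``net`` relative to ``reference``: C(net) / C(ref).

    The exact integer ratio is formed as a Fraction and converted to float,
    which is correctly rounded (relative error < 1e-15), regardless of how
    large the two capacities are.
    """
    num = math.comb(net.N, net.A)
    den = math.comb(reference.N, reference.A)
    return float(Fraction(num, den))


def capacity_table(
    nets: list[NetworkConfig],
    reference: NetworkConfig | None = None,
    base: float = 10.0,
) -> pd.DataFrame:
    """Tabulate capacities: columns (N, A, p, cap_log10, cap_normalized)."""
    rows = []
    for net in nets:
        res = exact_capacity(net, base=base, reference=reference)
        rows.append(
            {
                "N": net.N,
                "A": net.A,
                "p": net.p,
                f"cap_log{base:g}" if base != 10 else "cap_log10": res.log_value,
                "cap_normalized": res.normalized,
            }
        )
    return pd.DataFrame(rows)
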