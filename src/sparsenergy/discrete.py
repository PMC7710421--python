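"""Integer-level searches over networks: iso-capacity families and
fixed-budget capacity maximization.

Two complementary questions are answered at the integer level, before any
continuum limit is taken:

1. *Iso-capacity*: which (N, A) pairs have (approximately) the same
   representational capacity as a reference network?  For each candidate
   active count A, C(N, A) is strictly increasing in N, so there is a single
   N whose capacity is closest to the reference; the scan reports it and
   flags whether it falls within a relative tolerance (5% by convention).

2. *Fixed energy budget*: among all integer networks whose total cost
   fc*N + ac*A falls in a narrow window, which maximizes capacity?  The
   candidate set is enumerated exhaustively and capacities are compared as
   exact big integers, so the argmax is provably correct — the enumeration
   itself is the oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .capacity import CapacityResult, NetworkConfig, exact_capacity

__all__ = [
    "CostWindow",
    "IsoCapacityRow",
    "DiscreteOptimum",
    "iso_capacity_scan",
    "iso_cost_surface",
    "enumerate_fixed_cost",
    "find_discrete_optimum",
    "TABLE1_ACTIVE_COUNTS",
]

#: Active-neuron counts of the canonical iso-capacity family around the
#: benchmark network (N=100, A=50).
TABLE1_ACTIVE_COUNTS: tuple[int, ...] = (
    50, 45, 40, 33, 32, 29, 27, 24, 22, 21, 19, 17, 15, 13,
)


class SearchError(RuntimeError):
    """Raised when a constrained search has no candidates."""


@dataclass(frozen=True)
class CostWindow:
    """An interval of admissible total costs.

    The lower bound is inclusive by default and the upper bound exclusive:
    a budget "between 154 and 156" admits costs in [154, 156).  Both
    inclusivities are configurable.
    """

    lo: float
    hi: float
    include_lo: bool = True
    include_hi: bool = False

    def __post_init__(self) -> None:
        if not (self.lo <= self.hi):
            raise ValueError(f"need lo <= hi, got [{self.lo}, {self.hi}]")

    def contains(self, cost: float) -> bool:
        above = cost >= self.lo if self.include_lo else cost > self.lo
        below = cost <= self.hi if self.include_hi else cost < self.hi
        return above and below


@dataclass(frozen=True)
class IsoCapacityRow:
    """One member of an iso-capacity family: the best N for a given A."""

    net: NetworkConfig
    capacity: CapacityResult
    within_tolerance: bool


@dataclass(frozen=True)
class DiscreteOptimum:
    """Capacity-maximizing integer network under a cost window."""

    net: NetworkConfig
    capacity: CapacityResult
    cost: float
    window: CostWindow
    n_candidates: int = field(default=0)


def iso_capacity_scan(
    reference: NetworkConfig,
    A_values: list[int] | tuple[int, ...] = TABLE1_ACTIVE_COUNTS,
    tolerance: float = 0.05,
    N_max: int = 2000,
    base: float = 10.0,
) -> list[IsoCapacityRow]:
    """For each active count A, the N whose capacity best matches a reference.

    C(N, A) is strictly increasing in N (for N >= A >= 1), so a binary search
    over N in [A, N_max] brackets the reference capacity and the closer of
    the two bracketing N is returned.  A row is flagged ``within_tolerance``
    iff |C(N,A)/C(ref) - 1| <= tolerance.
    """
    if tolerance <= 0:
        raise ValueError(f"tolerance must be > 0, got {tolerance!r}")
    ref_cap = math.comb(reference.N, reference.A)
    rows = []
    for A in A_values:
        if A < 1:
            raise ValueError(f"active counts must be >= 1, got {A}")
        lo, hi = A, N_max
        # largest N with C(N, A) <= ref_cap
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if math.comb(mid, A) <= ref_cap:
                lo = mid
            else:
                hi = mid - 1
        candidates = [lo] if lo >= N_max else [lo, lo + 1]
        best_N = min(candidates, key=lambda n: abs_ratio_err(math.comb(n, A), ref_cap))
        net = NetworkConfig(N=best_N, A=A)
        res = exact_capacity(net, base=base, reference=reference)
        rows.append(
            IsoCapacityRow(
                net=net,
                capacity=res,
                within_tolerance=abs(res.normalized - 1.0) <= tolerance,
            )
        )
    return rows


def abs_ratio_err(value: int, ref: int) -> float:
    """|value/ref - 1| computed exactly enough for argmin comparisons."""
    from fractions import Fraction

    return abs(float(Fraction(value, ref)) - 1.0)


def iso_cost_surface(
    rows: list[IsoCapacityRow],
    r_values: list[float],
    fc: float = 1.0,
) -> pd.DataFrame:
    """Cost of each iso-capacity network across signaling ratios.

    Long-format frame keyed by the row's sparseness p and the ratio r, with
    cost = fc*N + r*fc*A.  No interpolation between rows is performed.
    """
    if not rows:
        raise ValueError("rows must be non-empty")
    if any(r <= 0 for r in r_values):
        raise ValueError("r values must be positive")
    records = []
    for row in rows:
        N, A = row.net.N, row.net.A
        for r in r_values:
            records.append(
                {"p": row.net.p, "r": r, "N": N, "A": A, "cost": fc * N + r * fc * A}
            )
    return pd.DataFrame(records)


def enumerate_fixed_cost(
    r: float,
    window: CostWindow,
    fc: float = 1.0,
    N_max: int = 2000,
) -> list[NetworkConfig]:
    """All integer networks (1 <= A <= N <= N_max) with cost in the window.

    Cost is fc*N + r*fc*A.  For each N the admissible A form a contiguous
    range, recovered directly from the window bounds; an empty result is
    valid (returned as an empty list).
    """
    if fc <= 0:
        raise ValueError(f"fc must be > 0, got {fc!r}")
    out: list[NetworkConfig] = []
    for N in range(1, N_max + 1):
        if fc * N > window.hi:
            break
        if r == 0:
            a_lo, a_hi = 1, N
            if not window.contains(fc * N):
                continue
        else:
            a_lo = math.ceil((window.lo - fc * N) / (r * fc))
            a_hi = math.floor((window.hi - fc * N) / (r * fc))
            a_lo, a_hi = max(a_lo, 1), min(a_hi, N)
        for A in range(a_lo, a_hi + 1):
            if window.contains(fc * N + r * fc * A):
                out.append(NetworkConfig(N=N, A=A))
    return out


def find_discrete_optimum(
    r: float,
    window: CostWindow,
    fc: float = 1.0,
    N_max: int = 2000,
    base: float = 10.0,
) -> DiscreteOptimum:
    """Capacity argmax over all integer networks inside a cost window.

    Capacities are compared as exact integers (no logs, no float ties).
    Ties are broken by lower cost, then lower N.
    """
    candidates = enumerate_fixed_cost(r, window, fc=fc, N_max=N_max)
    if not candidates:
        raise SearchError(
            f"no integer network with cost in [{window.lo}, {window.hi}] "
            f"for r={r}, fc={fc}, N_max={N_max}"
        )
    best: NetworkConfig | None = None
    best_cap = -1
    best_cost = math.inf
    for net in candidates:
        cap = math.comb(net.N, net.A)
        cost = fc * net.N + r * fc * net.A
        if cap > best_cap or (
            cap == best_cap and (cost, net.N) < (best_cost, best.N)  # type: ignore[union-attr]
        ):
            best, best_cap, best_cost = net, cap, cost
    assert best is not None
    return DiscreteOptimum(
        net=best,
        capacity=exact_capacity(best, base=base),
        cost=best_cost,
        window=window,
        n_candidates=len(candidates),
    )


def iso_capacity_frame(rows: list[IsoCapacityRow]) -> pd.DataFrame:
    """Serialize scan rows: (N, A, cap_log10, cap_normalized, p, within_tolerance)."""
    return pd.DataFrame(
        {
            "N": [row.net.N for row in rows],
            "A": [row.net.A for row in rows],
            "cap_log10": [row.capacity.log_value for row in rows],
            "cap_normalized": [row.capacity.normalized for row in rows],
            "p": [row.net.p for row in rows],
            "within_tolerance": [row.within_tolerance for row in rows],
        }
    )
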