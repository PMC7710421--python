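"""Continuous sparseness optimization: entropy per unit energy.

In the large-N limit the log-capacity per neuron of a population with active
fraction p is the binary entropy H(p), while the energy per neuron per unit
time is fc*(1 + r*p).  The capacity-per-cost objective is therefore

    cap(p) = H(p) / (fc * (1 + r*p)),

and its reciprocal is the cost of one unit of capacity.  Both are unimodal on
(0, 0.5]; the maximizer p* of cap and the minimizer of cost coincide, satisfy
the first-order condition

    log((1-p)/p) * (1 + r*p) = r * H(p),

and depend only on r (the base of the logarithm rescales the objective by a
constant and leaves p* unchanged).  The search domain is restricted to
p <= 0.5 because C(N, A) = C(N, N-A): any code with p > 0.5 has a mirror
with the same capacity and strictly lower cost.

For figure-level reproduction the default logarithm base is 10 — the
conventional printed extrema (e.g. max cap 0.1887 at r=1.4) are base-10
values; natural-log values are a factor ln(10) larger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .capacity import binary_entropy

__all__ = [
    "ContinuousOptimum",
    "SweepGrid",
    "cap_per_cost",
    "cost_per_cap",
    "optimize_p",
    "sweep_grid",
    "naive_cost_map",
]

#: Lower clip of the search interval, clear of the p -> 0 singularity.
P_MIN = 1e-9
P_MAX = 0.5


@dataclass(frozen=True)
class ContinuousOptimum:
    """Optimal sparseness for a given signaling ratio r.

    ``p_star`` is the full-precision optimizer of the chosen objective;
    ``objective_value`` is cap(p*) in mode "maximize-cap" or cost(p*) in mode
    "minimize-cost".  Display conventions: p* to 3 dp, objective to 4 dp.
    """

    r: float
    p_star: float
    objective_value: float
    mode: str
    base: float
    tolerance: float


@dataclass(frozen=True)
class SweepGrid:
    """Dense evaluation of cap-per-cost or cost-per-cap over a (p, r) grid."""

    p_axis: np.ndarray
    r_axis: np.ndarray
    values: np.ndarray  # shape (len(r_axis), len(p_axis))
    mode: str

    def row_extremum(self) -> pd.DataFrame:
        """Per-r argmax (cap mode) or argmin (cost mode) along the p axis."""
        pick = np.argmax if self.mode == "cap" else np.argmin
        idx = pick(self.values, axis=1)
        return pd.DataFrame(
            {
                "r": self.r_axis,
                "p_opt": self.p_axis[idx],
                "value": self.values[np.arange(len(self.r_axis)), idx],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format (p, r, value, mode) frame."""
        pp, rr = np.meshgrid(self.p_axis, self.r_axis)
        return pd.DataFrame(
            {
                "p": pp.ravel(),
                "r": rr.ravel(),
                "value": self.values.ravel(),
                "mode": self.mode,
            }
        )


def cap_per_cost(p: float, r: float, fc: float = 1.0, base: float = 10.0) -> float:
    """Representational capacity per unit energy, H(p) / (fc*(1 + r*p)).

    Returns 0 at p = 0 and p = 1 by continuity (the entropy vanishes there
    while the cost stays positive).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p!r}")
    if fc <= 0:
        raise ValueError(f"fc must be > 0, got {fc!r}")
    if r < 0:
        raise ValueError(f"r must be >= 0, got {r!r}")
    return binary_entropy(p, base) / (fc * (1.0 + r * p))


def cost_per_cap(p: float, r: float, fc: float = 1.0, base: float = 10.0) -> float:
    """Energy per unit capacity, fc*(1 + r*p) / H(p); +inf at p in {0, 1}."""
    cap = cap_per_cost(p, r, fc=fc, base=base)
    return math.inf if cap == 0.0 else 1.0 / cap


def optimize_p(
    r: float,
    fc: float = 1.0,
    base: float = 10.0,
    mode: str = "maximize-cap",
    tol: float = 1e-8,
) -> ContinuousOptimum:
    """Optimal sparseness p* on (0, 0.5] for a given signaling ratio.

    A bounded scalar minimizer (Brent with bounds, tolerance ``tol``) is run
    on -cap(p) or +cost(p) according to ``mode``; both modes locate the same
    p* (reciprocal objectives).  At r = 0 the objective reduces to H(p) and
    p* is the boundary 0.5.
    """
    if r < 0:
        raise ValueError(f"r must be >= 0, got {r!r}")
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol!r}")
    if mode == "maximize-cap":
        objective = lambda p: -cap_per_cost(p, r, fc=fc, base=base)  # noqa: E731
    elif mode == "minimize-cost":
        objective = lambda p: cost_per_cap(p, r, fc=fc, base=base)  # noqa: E731
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = minimize_scalar(
        objective, bounds=(P_MIN, P_MAX), method="bounded", options={"xatol": tol}
    )
    p_star = float(res.x)
    # the bounded method cannot land exactly on the boundary; snap when the
    # boundary value is at least as good (r=0 makes p*=0.5 a boundary optimum)
    if objective(P_MAX) <= res.fun:
        p_star = P_MAX
    value = cap_per_cost(p_star, r, fc=fc, base=base)
    if mode == "minimize-cost":
        value = 1.0 / value
    return ContinuousOptimum(
        r=r, p_star=p_star, objective_value=value, mode=mode, base=base, tolerance=tol
    )


def sweep_grid(
    p_axis: np.ndarray,
    r_axis: np.ndarray,
    fc: float = 1.0,
    base: float = 10.0,
    mode: str = "cap",
) -> SweepGrid:
    """Evaluate cap-per-cost or cost-per-cap on a dense (p, r) grid."""
    p_axis = np.asarray(p_axis, dtype=float)
    r_axis = np.asarray(r_axis, dtype=float)
    if np.any(np.diff(p_axis) <= 0) or np.any(np.diff(r_axis) < 0):
        raise ValueError("axes must be sorted ascending")
    if np.any(p_axis <= 0) or np.any(p_axis > P_MAX):
        raise ValueError("p values must lie in (0, 0.5]")
    if np.any(r_axis <= 0):
        raise ValueError("r values must be positive")
    if mode not in ("cap", "cost"):
        raise ValueError(f"unknown mode {mode!r}")
    log = np.log10 if base == 10 else (np.log if base == math.e else None)
    if log is None:
        entropy = lambda p: (-p * np.log(p) - (1 - p) * np.log1p(-p)) / math.log(base)  # noqa: E731
    else:
        entropy = lambda p: -p * log(p) - (1 - p) * log(1 - p)  # noqa: E731
    pp, rr = np.meshgrid(p_axis, r_axis)
    cap = entropy(pp) / (fc * (1.0 + rr * pp))
    values = cap if mode == "cap" else 1.0 / cap
    return SweepGrid(p_axis=p_axis, r_axis=r_axis, values=values, mode=mode)


def naive_cost_map(
    p_axis: np.ndarray,
    r_axis: np.ndarray,
    fc: float = 1.0,
    N: int = 100,
) -> SweepGrid:
    """Raw network cost fc*N*(1 + r*p) on a (p, r) grid, capacity ignored.

    Affine and strictly increasing in both p and r; the baseline picture of
    what energy alone (no coding benefit) looks like.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N!r}")
    p_axis = np.asarray(p_axis, dtype=float)
    r_axis = np.asarray(r_axis, dtype=float)
    pp, rr = np.meshgrid(p_axis, r_axis)
    return SweepGrid(
        p_axis=p_axis,
        r_axis=r_axis,
        values=fc * N * (1.0 + rr * pp),
        mode="cost",
    )


def continuous_optima_table(
    r_values: list[float],
    fc: float = 1.0,
    base: float = 10.0,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Per-r optimum table: (r, p_star, cap_max, cost_min, base)."""
    rows = []
    for r in r_values:
        opt = optimize_p(r, fc=fc, base=base, mode="maximize-cap", tol=tol)
        rows.append(
            {
                "r": r,
                "p_star": opt.p_star,
                "cap_max": opt.objective_value,
                "cost_min": 1.0 / opt.objective_value,
                "base": base,
            }
        )
    return pd.DataFrame(rows)
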