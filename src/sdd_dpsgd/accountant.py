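"""Renyi differential privacy accounting for varying Gaussian noise schedules.

Each optimizer step releases a clipped gradient sum perturbed by Gaussian
noise with standard deviation ``sigma_t * C_t``.  Since the step's L2
sensitivity is exactly the clipping threshold ``C_t``, the threshold cancels
and the accountant sees only the noise *multiplier* ``sigma_t``.  The plain
per-step cost is the Gaussian-mechanism RDP ``alpha / (2 sigma**2)``; costs
compose additively across steps (adaptive sequential composition) and the
final Renyi curve converts to an (epsilon, delta)-DP guarantee via

    epsilon = min_alpha [ rdp(alpha) + ln(1/delta) / (alpha - 1) ].

Two accounting modes are provided:

* ``plain`` (default): no subsampling amplification — conservative, and the
  mode under which the schedule's uniform-expenditure algebra is exact.
* ``subsampled``: the standard integer-order upper bound on the RDP of the
  Poisson-subsampled Gaussian mechanism, for comparability with mainstream
  accountants.  Integer orders only.

:func:`calibrate_sigma0` inverts the whole pipeline: given a target epsilon
and a schedule shape, bisection finds the initial noise multiplier that
spends exactly the requested budget.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .schedule import ScheduleConfig, StageTable, build_table

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "LedgerEntry",
    "PrivacyLedger",
    "RdpCurve",
    "DpGuarantee",
    "CalibrationError",
    "gaussian_rdp",
    "subsampled_gaussian_rdp",
    "compose",
    "to_dp",
    "calibrate_sigma0",
]


def _default_alpha_grid() -> tuple:
    fractional = [1.0 + x / 10.0 for x in range(1, 100)]
    integers = [float(a) for a in range(2, 65)] + [128.0, 256.0]
    return tuple(sorted(set(fractional + integers)))


#: Orders 1.1..10.9 in steps of 0.1, integers 2..64, plus 128 and 256.
DEFAULT_ALPHA_GRID = _default_alpha_grid()


class CalibrationError(RuntimeError):
    """Raised when a privacy target cannot be met within the sigma bracket."""


def gaussian_rdp(alpha: float, sigma: float) -> float:
    """RDP of the Gaussian mechanism at order ``alpha``: ``alpha / (2 sigma**2)``.

    ``sigma`` is the noise multiplier (noise std divided by sensitivity).
    """
    if not alpha > 1.0:
        raise ValueError(f"alpha must be > 1, got {alpha}")
    if sigma < 0.0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0.0:
        return math.inf  # zero noise gives no privacy at all
    return alpha / (2.0 * sigma**2)


def subsampled_gaussian_rdp(alpha: int, sigma: float, q: float) -> float:
    """Upper bound on RDP of the Poisson-subsampled Gaussian at integer order.

    Uses the binomial expansion

        rdp = log( sum_{k=0}^{alpha} C(alpha,k) (1-q)^{alpha-k} q^k
                   exp(k(k-1) / (2 sigma^2)) ) / (alpha - 1),

    which is exact at order 2 and an upper bound for larger integer orders.
    Reduces to :func:`gaussian_rdp` at ``q = 1`` and never exceeds it.
    """
    if float(alpha) != int(alpha) or alpha < 2:
        raise ValueError(
            f"subsampled mode requires integer alpha >= 2, got {alpha}; "
            "use gaussian_rdp (plain mode) for fractional orders"
        )
    if not 0.0 < q <= 1.0:
        raise ValueError(f"q must lie in (0, 1], got {q}")
    if sigma < 0.0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0.0:
        return math.inf
    alpha = int(alpha)
    if q == 1.0:
        return gaussian_rdp(alpha, sigma)
    k = np.arange(alpha + 1)
    log_binom = gammaln(alpha + 1) - gammaln(k + 1) - gammaln(alpha - k + 1)
    log_terms = (
        log_binom
        + k * math.log(q)
        + (alpha - k) * math.log1p(-q)
        + k * (k - 1) / (2.0 * sigma**2)
    )
    val = float(logsumexp(log_terms)) / (alpha - 1)
    return max(0.0, val)


@dataclass(frozen=True)
class LedgerEntry:
    """``count`` steps at noise multiplier ``sigma`` and sampling rate ``q``."""

    sigma: float
    q: float
    count: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        if not 0.0 < self.q <= 1.0:
            raise ValueError(f"q must lie in (0, 1], got {self.q}")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")


@dataclass
class PrivacyLedger:
    """Record of every noisy gradient release in a training run.

    Per-step sensitivity equals the step's clipping threshold, which is
    normalized out; entries carry only the multiplier.  Consecutive steps at
    identical (sigma, q) may be aggregated into one entry — composition is
    linear in counts, so the resulting RDP curve is identical.
    """

    entries: list

    def __post_init__(self) -> None:
        self.entries = [
            e if isinstance(e, LedgerEntry) else LedgerEntry(*e) for e in self.entries
        ]

    @property
    def total_steps(self) -> int:
        return sum(e.count for e in self.entries)

    def append(self, sigma: float, q: float, count: int = 1) -> None:
        self.entries.append(LedgerEntry(sigma, q, count))

    def extend(self, other: "PrivacyLedger") -> None:
        self.entries.extend(other.entries)

    @classmethod
    def from_schedule(cls, table: StageTable, q: float) -> "PrivacyLedger":
        return cls([LedgerEntry(s, q, int(d)) for s, d in zip(table.sigmas, table.durations)])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "sigma": [e.sigma for e in self.entries],
                "q": [e.q for e in self.entries],
                "count": [e.count for e in self.entries],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PrivacyLedger":
        df = pd.read_csv(path)
        missing = {"sigma", "q", "count"} - set(df.columns)
        if missing:
            raise ValueError(f"ledger CSV {path} missing columns {sorted(missing)}")
        return cls(
            [LedgerEntry(r.sigma, r.q, int(r.count)) for r in df.itertuples()]
        )


@dataclass(frozen=True)
class RdpCurve:
    """RDP values over a grid of Renyi orders."""

    alphas: tuple
    rdp: tuple

    def __post_init__(self) -> None:
        if len(self.alphas) != len(self.rdp) or len(self.alphas) == 0:
            raise ValueError("alphas and rdp must be non-empty and aligned")
        object.__setattr__(self, "alphas", tuple(float(a) for a in self.alphas))
        object.__setattr__(self, "rdp", tuple(float(r) for r in self.rdp))

    def __add__(self, other: "RdpCurve") -> "RdpCurve":
        if self.alphas != other.alphas:
            raise ValueError("cannot add RDP curves on different alpha grids")
        return RdpCurve(self.alphas, tuple(a + b for a, b in zip(self.rdp, other.rdp)))


@dataclass(frozen=True)
class DpGuarantee:
    """(epsilon, delta)-DP guarantee with the minimizing Renyi order."""

    epsilon: float
    delta: float
    optimal_alpha: float


def compose(
    ledger: PrivacyLedger,
    alpha_grid: Sequence[float] | None = None,
    mode: str = "plain",
) -> RdpCurve:
    """Total RDP of all ledgered steps over an order grid.

    ``plain`` charges ``alpha / (2 sigma**2)`` per step (no amplification);
    ``subsampled`` uses the Poisson-subsampling bound and restricts the grid
    to integer orders >= 2.
    """
    if not ledger.entries:
        raise ValueError("cannot compose an empty ledger")
    if alpha_grid is None:
        alpha_grid = DEFAULT_ALPHA_GRID
    if mode == "plain":
        alphas = [float(a) for a in alpha_grid]
        per_alpha_cost = lambda a, e: e.count * gaussian_rdp(a, e.sigma)
    elif mode == "subsampled":
        alphas = [float(a) for a in alpha_grid if float(a).is_integer() and a >= 2]
        if not alphas:
            raise ValueError(
                "subsampled mode needs integer orders >= 2 in the alpha grid"
            )
        per_alpha_cost = lambda a, e: e.count * subsampled_gaussian_rdp(
            int(a), e.sigma, e.q
        )
    else:
        raise ValueError(f"unknown accounting mode {mode!r}")
    rdp = [sum(per_alpha_cost(a, e) for e in ledger.entries) for a in alphas]
    return RdpCurve(tuple(alphas), tuple(rdp))


def to_dp(curve: RdpCurve, delta: float) -> DpGuarantee:
    """Convert an RDP curve to (epsilon, delta)-DP, minimizing over orders."""
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    log_inv_delta = math.log(1.0 / delta)
    candidates = [
        (r + log_inv_delta / (a - 1.0), a) for a, r in zip(curve.alphas, curve.rdp)
    ]
    epsilon, alpha = min(candidates)
    return DpGuarantee(epsilon=epsilon, delta=delta, optimal_alpha=alpha)


def epsilon_of_sigma0(
    sigma0: float,
    delta: float,
    shape: ScheduleConfig,
    q: float = 1.0,
    mode: str = "plain",
    alpha_grid: Sequence[float] | None = None,
) -> float:
    """Epsilon spent by the full schedule when started at ``sigma0``."""
    cfg = dataclasses.replace(shape, sigma0=sigma0)
    ledger = PrivacyLedger.from_schedule(build_table(cfg), q)
    return to_dp(compose(ledger, alpha_grid, mode), delta).epsilon


def calibrate_sigma0(
    target_epsilon: float,
    delta: float,
    shape: ScheduleConfig,
    q: float = 1.0,
    mode: str = "plain",
    bracket: tuple[float, float] = (1e-2, 1e4),
    eps_tol: float = 1e-3,
    sigma_tol: float = 1e-9,
    alpha_grid: Sequence[float] | None = None,
) -> float:
    """Bisection for the initial noise multiplier meeting a privacy budget.

    Epsilon is strictly decreasing in ``sigma0`` for a fixed schedule shape,
    so plain bisection over ``bracket`` converges; iteration stops when the
    achieved epsilon is within ``eps_tol`` of the target or the bracket
    shrinks below ``sigma_tol``.
    """
    if target_epsilon <= 0:
        raise ValueError(f"target epsilon must be positive, got {target_epsilon}")
    lo, hi = bracket

    def eps_of(s0: float) -> float:
        return epsilon_of_sigma0(s0, delta, shape, q, mode, alpha_grid)

    e_lo, e_hi = eps_of(lo), eps_of(hi)
    if not e_hi <= target_epsilon <= e_lo:
        raise CalibrationError(
            f"target epsilon {target_epsilon} outside achievable range "
            f"[{e_hi:.6g}, {e_lo:.6g}] for sigma0 in [{lo}, {hi}]"
        )
    while hi - lo > sigma_tol:
        mid = 0.5 * (lo + hi)
        e = eps_of(mid)
        if abs(e - target_epsilon) <= eps_tol:
            return mid
        if e > target_epsilon:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
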