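"""Dual dynamic schedules for differentially private SGD.

Training is split into geometrically growing stages.  Within stage ``i`` the
optimizer uses a fixed noise multiplier ``sigma_i = sigma0 * beta**(-i)``
(growing, since ``beta < 1``) and a fixed clipping threshold
``C_i = C0 * a**i`` (decaying).  Stage durations follow ``D_{i+1} = lambda *
D_i`` with ``lambda = 1/gamma``, so later, noisier stages are longer — the
per-stage Renyi-privacy cost proxy ``D_i / sigma_i**2`` stays flat exactly
when ``beta = sqrt(gamma)``.

The number of stages is not free: the first, low-noise, high-threshold stage
must cover at least a fraction ``rho`` of training (the *protection
horizon*), which pins ``n = floor(log_lambda(1 + (lambda-1)/rho))``.

Two documented ambiguities are exposed as config enums rather than silently
resolved:

* ``stage_convention``: whether ``n`` counts the stages themselves
  (``n_stages``, default — the convention under which ``D0/T >= rho`` holds)
  or the schedule runs ``D_0 .. D_n`` (``n_plus_1_stages``).
* ``n_variant``: the ``floor`` formula (default) versus the more
  conservative ``floor_minus_1`` variant of the same derivation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "ScheduleConfig",
    "StageTable",
    "ScheduleStats",
    "derive_num_steps",
    "stage_durations",
    "stage_durations_real",
    "stage_parameters",
    "build_table",
    "lookup",
    "noise_variance_trajectory",
    "expenditure_profile",
    "schedule_stats",
    "epochs_to_iterations",
    "write_table_csv",
    "read_table_csv",
    "write_table_json",
    "read_table_json",
]

# Guard against log-ratio landing an ulp below an exact integer
# (e.g. rho = 1/(lambda+1) makes the argument exactly lambda**2).
_LOG_EPS = 1e-9

STAGE_CONVENTIONS = ("n_stages", "n_plus_1_stages")
N_VARIANTS = ("floor", "floor_minus_1")


class ConfigurationError(ValueError):
    """Raised when schedule hyperparameters are inconsistent or infeasible."""


def derive_num_steps(lambda_: float, rho: float, variant: str = "floor") -> int:
    """Stage-count parameter ``n`` from the protection-horizon constraint.

    Requiring the first stage to cover at least ``rho * T`` iterations under a
    geometric schedule ``D_i = D0 * lambda**i`` bounds the number of stages:
    ``n = floor(log_lambda(1 + (lambda - 1) / rho))``.

    Parameters
    ----------
    lambda_
        Dynamics factor, strictly > 1 (``lambda = 1`` means equal stages and
        is handled directly by :func:`stage_durations`).
    rho
        Protection constant in (0, 1]: minimum fraction of total training
        that stage 0 must occupy.
    variant
        ``"floor"`` (default) returns the floored logarithm; ``"floor_minus_1"``
        returns that value minus one (never below 1) — a stricter reading of
        the same derivation.
    """
    if not lambda_ > 1.0:
        raise ConfigurationError(f"lambda must be > 1, got {lambda_}")
    if not 0.0 < rho <= 1.0:
        raise ConfigurationError(f"rho must lie in (0, 1], got {rho}")
    if variant not in N_VARIANTS:
        raise ConfigurationError(f"unknown n variant {variant!r}")
    x = math.log1p((lambda_ - 1.0) / rho) / math.log(lambda_)
    n = int(math.floor(x + _LOG_EPS))
    if variant == "floor_minus_1":
        n -= 1
    return max(1, n)


def stage_durations_real(T: float, lambda_: float, stages: int) -> list[float]:
    """Real-valued geometric stage durations summing to ``T``.

    ``D0 = T (lambda - 1) / (lambda**stages - 1)`` and ``D_i = D0 lambda**i``;
    at ``lambda = 1`` this degenerates to equal division.
    """
    if stages < 1:
        raise ConfigurationError(f"stages must be >= 1, got {stages}")
    if lambda_ < 1.0:
        raise ConfigurationError(f"lambda must be >= 1, got {lambda_}")
    if lambda_ == 1.0:
        return [T / stages] * stages
    d0 = T * (lambda_ - 1.0) / (lambda_**stages - 1.0)
    return [d0 * lambda_**i for i in range(stages)]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stage_durations(
    T: int, lambda_: float, n: int, convention: str = "n_stages"
) -> list[int]:
    """Integer stage durations: geometric progression, conserving ``T`` exactly.

    Cumulative real-valued boundaries are rounded half-up and differenced, so
    ``sum(durations) == T`` always.  Every stage must end up non-empty.
    """
    if convention not in STAGE_CONVENTIONS:
        raise ConfigurationError(f"unknown stage convention {convention!r}")
    stages = n if convention == "n_stages" else n + 1
    if T < stages:
        raise ConfigurationError(
            f"T={T} cannot be divided into {stages} nonempty stages"
        )
    real = stage_durations_real(float(T), lambda_, stages)
    cum = np.cumsum(real)
    boundaries = [_round_half_up(c) for c in cum[:-1]] + [T]
    durations = np.diff([0] + boundaries).tolist()
    if any(d < 1 for d in durations):
        raise ConfigurationError(
            f"T={T} too small for {stages} geometric stages (lambda={lambda_}): "
            f"integerized durations {durations}"
        )
    return [int(d) for d in durations]


def stage_parameters(
    sigma0: float, c0: float, beta: float, a: float, stages: int
) -> tuple[list[float], list[float]]:
    """Per-stage noise multipliers and clipping thresholds.

    Closed forms ``sigma_i = sigma0 * beta**(-i)`` and ``C_i = c0 * a**i``
    for ``i = 0 .. stages-1``.  ``beta < 1`` makes the noise grow by ``1/beta``
    per stage; ``a < 1`` makes the threshold decay by ``a`` per stage.
    """
    if sigma0 < 0 or c0 <= 0:
        raise ConfigurationError(
            "c0 must be positive and sigma0 non-negative (0 = no-privacy limit)"
        )
    if not 0.0 < beta <= 1.0:
        raise ConfigurationError(f"beta must lie in (0, 1], got {beta}")
    if not 0.0 < a <= 1.0:
        raise ConfigurationError(f"clip decay a must lie in (0, 1], got {a}")
    if stages < 1:
        raise ConfigurationError(f"stages must be >= 1, got {stages}")
    sigmas = [sigma0 * beta ** (-i) for i in range(stages)]
    clips = [c0 * a**i for i in range(stages)]
    return sigmas, clips


@dataclass(frozen=True)
class ScheduleConfig:
    """All hyperparameters of the dual dynamic schedule.

    ``gamma`` and ``lambda_`` are one dial (``lambda = 1/gamma``); give either,
    or both if consistent to 1e-9.  ``beta`` defaults to ``gamma`` (the
    uniform-expenditure coupling); the conservative experimental choice is
    ``beta = 0.8`` at ``gamma = 0.9``, and ``beta = sqrt(gamma)`` is the
    exactly-neutral scaling.  ``n`` may be fixed by the user or left ``None``
    to be derived from ``(lambda, rho)``.
    """

    total_iterations: int
    sigma0: float
    c0: float
    gamma: float = 0.9
    lambda_: float | None = None
    beta: float | None = None
    clip_decay: float = 0.6
    rho: float = 0.3
    n: int | None = None
    stage_convention: str = "n_stages"
    n_variant: str = "floor"

    def __post_init__(self) -> None:
        if self.total_iterations < 1:
            raise ConfigurationError("total_iterations must be >= 1")
        if not 0.0 < self.gamma <= 1.0:
            raise ConfigurationError(f"gamma must lie in (0, 1], got {self.gamma}")
        if self.lambda_ is None:
            object.__setattr__(self, "lambda_", 1.0 / self.gamma)
        elif abs(self.lambda_ - 1.0 / self.gamma) > 1e-9:
            raise ConfigurationError(
                f"lambda={self.lambda_} inconsistent with gamma={self.gamma} "
                "(require lambda = 1/gamma to 1e-9)"
            )
        if self.beta is None:
            object.__setattr__(self, "beta", self.gamma)
        if not 0.0 < self.beta <= 1.0:
            raise ConfigurationError(f"beta must lie in (0, 1], got {self.beta}")
        if not 0.0 < self.clip_decay <= 1.0:
            raise ConfigurationError(
                f"clip_decay must lie in (0, 1], got {self.clip_decay}"
            )
        if not 0.0 < self.rho <= 1.0:
            raise ConfigurationError(f"rho must lie in (0, 1], got {self.rho}")
        # sigma0 == 0 is the documented no-privacy debugging limit.
        if self.sigma0 < 0 or self.c0 <= 0:
            raise ConfigurationError(
                "c0 must be positive and sigma0 non-negative"
            )
        if self.stage_convention not in STAGE_CONVENTIONS:
            raise ConfigurationError(
                f"unknown stage convention {self.stage_convention!r}"
            )
        if self.n_variant not in N_VARIANTS:
            raise ConfigurationError(f"unknown n variant {self.n_variant!r}")
        if self.n is not None and self.n < 1:
            raise ConfigurationError(f"n must be >= 1, got {self.n}")

    def resolved_n(self) -> int:
        """``n`` as given, or derived from the protection-horizon formula."""
        if self.n is not None:
            return self.n
        if self.lambda_ <= 1.0:
            raise ConfigurationError(
                "n must be given explicitly when lambda = 1 (equal stages)"
            )
        return derive_num_steps(self.lambda_, self.rho, self.n_variant)

    @property
    def num_stages(self) -> int:
        n = self.resolved_n()
        return n if self.stage_convention == "n_stages" else n + 1


@dataclass(frozen=True)
class StageTable:
    """Realized per-stage schedule: durations, noise multipliers, clip thresholds.

    Stage ``i`` covers the half-open iteration interval
    ``[starts[i], starts[i] + durations[i])``.  Durations are integers for a
    trainable schedule; real-valued tables (from ``build_table(...,
    integerize=False)``) support exact analytic checks.
    """

    durations: tuple
    sigmas: tuple
    clips: tuple

    def __post_init__(self) -> None:
        if not (len(self.durations) == len(self.sigmas) == len(self.clips)):
            raise ConfigurationError("durations, sigmas, clips must align")
        if len(self.durations) == 0:
            raise ConfigurationError("empty stage table")
        object.__setattr__(self, "durations", tuple(self.durations))
        object.__setattr__(self, "sigmas", tuple(float(s) for s in self.sigmas))
        object.__setattr__(self, "clips", tuple(float(c) for c in self.clips))

    @property
    def num_stages(self) -> int:
        return len(self.durations)

    @property
    def total_iterations(self):
        return sum(self.durations)

    @property
    def starts(self) -> tuple:
        """0-based first iteration of each stage."""
        return tuple(np.concatenate([[0], np.cumsum(self.durations)[:-1]]).tolist())

    @property
    def ends(self) -> tuple:
        """Exclusive ends of each stage's half-open interval."""
        return tuple(np.cumsum(self.durations).tolist())

    def stage_of(self, t: int) -> int:
        if not 0 <= t < self.total_iterations:
            raise IndexError(
                f"iteration {t} outside [0, {self.total_iterations})"
            )
        return int(np.searchsorted(self.ends, t, side="right"))

    def lookup(self, t: int) -> tuple[float, float]:
        i = self.stage_of(t)
        return self.sigmas[i], self.clips[i]


def build_table(config: ScheduleConfig, integerize: bool = True) -> StageTable:
    """Realize a :class:`ScheduleConfig` into a :class:`StageTable`."""
    stages = config.num_stages
    if integerize:
        durations = stage_durations(
            config.total_iterations, config.lambda_, config.resolved_n(),
            config.stage_convention,
        )
    else:
        durations = stage_durations_real(
            float(config.total_iterations), config.lambda_, stages
        )
    sigmas, clips = stage_parameters(
        config.sigma0, config.c0, config.beta, config.clip_decay, stages
    )
    return StageTable(tuple(durations), tuple(sigmas), tuple(clips))


def lookup(table: StageTable, t: int) -> tuple[float, float]:
    """``(sigma_t, C_t)`` of the stage whose half-open interval contains ``t``."""
    return table.lookup(t)


def noise_variance_trajectory(table: StageTable) -> list[float]:
    """Effective injected noise variance ``V_i = (sigma_i * C_i)**2`` per stage.

    With ``a < beta`` this decays geometrically at ratio ``(a/beta)**2``: the
    relative noise multiplier grows but the absolute noise power vanishes.
    """
    return [(s * c) ** 2 for s, c in zip(table.sigmas, table.clips)]


def expenditure_profile(table: StageTable) -> list[float]:
    """Per-stage Renyi-privacy cost proxy ``D_i / sigma_i**2``.

    Constant (uniform privacy expenditure) exactly when ``beta = sqrt(gamma)``
    on real-valued durations.
    """
    return [d / s**2 for d, s in zip(table.durations, table.sigmas)]


@dataclass(frozen=True)
class ScheduleStats:
    """Duration-weighted summary statistics of the noise schedule."""

    sigma_initial: float
    weighted_mean: float
    weighted_variance: float
    d0_fraction: float
    noise_variance: tuple


def schedule_stats(table: StageTable) -> ScheduleStats:
    """Weighted mean/variance of sigma_t, stage-0 fraction, noise variances."""
    T = table.total_iterations
    d = np.asarray(table.durations, dtype=float)
    s = np.asarray(table.sigmas, dtype=float)
    mu = float(np.sum(d * s) / T)
    var = float(np.sum(d * (s - mu) ** 2) / T)
    return ScheduleStats(
        sigma_initial=table.sigmas[0],
        weighted_mean=mu,
        weighted_variance=var,
        d0_fraction=table.durations[0] / T,
        noise_variance=tuple(noise_variance_trajectory(table)),
    )


def epochs_to_iterations(epochs: int, n_samples: int, batch_size: int) -> int:
    """Convert an epoch budget to optimizer iterations: ``epochs * ceil(N/B)``."""
    if epochs < 1 or n_samples < 1 or batch_size < 1:
        raise ConfigurationError("epochs, n_samples, batch_size must be >= 1")
    return epochs * math.ceil(n_samples / batch_size)


# ---------------------------------------------------------------------------
# IO

def _table_frame(table: StageTable) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stage": np.arange(table.num_stages),
            "duration": table.durations,
            "sigma": table.sigmas,
            "clip": table.clips,
            "v": noise_variance_trajectory(table),
            "cumulative_start": table.starts,
        }
    )


def write_table_csv(table: StageTable, path) -> None:
    _table_frame(table).to_csv(path, index=False)


def read_table_csv(path) -> StageTable:
    df = pd.read_csv(path)
    required = {"stage", "duration", "sigma", "clip"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"schedule CSV {path} missing columns {sorted(missing)}")
    df = df.sort_values("stage")
    durations = df["duration"].tolist()
    if all(float(d).is_integer() for d in durations):
        durations = [int(d) for d in durations]
    return StageTable(tuple(durations), tuple(df["sigma"]), tuple(df["clip"]))


def write_table_json(table: StageTable, path, config: ScheduleConfig | None = None) -> None:
    payload = {
        "config": asdict(config) if config is not None else None,
        "stages": _table_frame(table).to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_table_json(path) -> tuple[StageTable, ScheduleConfig | None]:
    payload = json.loads(Path(path).read_text())
    stages = payload["stages"]
    table = StageTable(
        tuple(int(s["duration"]) if float(s["duration"]).is_integer() else s["duration"] for s in stages),
        tuple(s["sigma"] for s in stages),
        tuple(s["clip"] for s in stages),
    )
    cfg = payload.get("config")
    return table, (ScheduleConfig(**cfg) if cfg else None)
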