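"""Step-wise dual dynamic DP-SGD and its static ablation baseline.

The training loop is standard DP-SGD — per-sample gradients, L2 clipping,
Gaussian noise, SGD update — except that the clipping threshold and noise
multiplier are looked up from a stage schedule at every iteration: early
stages use a high threshold and low noise (protecting fragile minority-class
gradients), later stages decay the threshold and grow the multiplier so the
absolute injected noise power ``(sigma_t C_t)**2`` shrinks while the privacy
cost per step falls.

Models are small analytic classifiers with exact, hand-derived per-sample
gradients (multinomial cross-entropy): softmax regression and a one-hidden-
layer tanh MLP.  This keeps the per-sample gradient path exact and fully
inspectable — the mechanism under study is the optimizer, not the model.

Noise placement: the privacy analysis bounds the sensitivity of the clipped
gradient *sum* by ``C_t``, so the default convention adds noise with std
``sigma_t * C_t`` to the sum and then divides by the (expected) batch size.
A ``literal_mean`` convention — noise of the same scale added to the batch
mean — is kept for fidelity experiments; it injects a factor-of-B larger
effective noise and is not the accounted-for mechanism.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from .accountant import LedgerEntry, PrivacyLedger
from .schedule import ScheduleConfig, build_table

__all__ = [
    "SoftmaxRegression",
    "MLPOneHidden",
    "TrainConfig",
    "TrainResult",
    "make_model",
    "per_sample_gradients",
    "clip_gradient",
    "clip_rows",
    "privatize_batch",
    "sgd_step",
    "train",
    "train_static_baseline",
]

logger = logging.getLogger(__name__)

MODEL_KINDS = ("softmax_regression", "mlp_1hidden")
SAMPLING_MODES = ("poisson", "fixed_size")
NOISE_CONVENTIONS = ("noise_on_sum", "literal_mean")


def _with_bias(X: np.ndarray) -> np.ndarray:
    return np.hstack([X, np.ones((X.shape[0], 1))])


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _one_hot(y: np.ndarray, K: int) -> np.ndarray:
    Y = np.zeros((y.shape[0], K))
    Y[np.arange(y.shape[0]), y] = 1.0
    return Y


class SoftmaxRegression:
    """Multinomial logistic regression with bias; convex in the flat weights."""

    kind = "softmax_regression"

    def __init__(self, n_features: int, n_classes: int):
        self.n_features = n_features
        self.n_classes = n_classes
        self.n_params = n_classes * (n_features + 1)

    def init_weights(self, rng: np.random.Generator | None = None) -> np.ndarray:
        # Zeros: the loss is convex, no symmetry to break.
        return np.zeros(self.n_params)

    def _unpack(self, w: np.ndarray) -> np.ndarray:
        return w.reshape(self.n_classes, self.n_features + 1)

    def probabilities(self, w: np.ndarray, X: np.ndarray) -> np.ndarray:
        return _softmax(_with_bias(X) @ self._unpack(w).T)

    def predict(self, w: np.ndarray, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.probabilities(w, X), axis=1)

    def loss(self, w: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
        p = self.probabilities(w, X)
        return float(-np.mean(np.log(p[np.arange(len(y)), y] + 1e-300)))

    def per_sample_gradients(
        self, w: np.ndarray, X: np.ndarray, y: np.ndarray
    ) -> np.ndarray:
        if X.shape[0] == 0:
            raise ValueError("empty batch")
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        Xb = _with_bias(X)
        P = _softmax(Xb @ self._unpack(w).T)
        delta = P - _one_hot(y, self.n_classes)  # (B, K)
        G = np.einsum("bk,bd->bkd", delta, Xb)  # d(CE_i)/dW
        return G.reshape(X.shape[0], self.n_params)


class MLPOneHidden:
    """One-hidden-layer tanh network with hand-derived per-sample backprop."""

    kind = "mlp_1hidden"

    def __init__(self, n_features: int, n_classes: int, hidden_units: int = 16):
        self.n_features = n_features
        self.n_classes = n_classes
        self.hidden_units = hidden_units
        self._n1 = hidden_units * (n_features + 1)
        self._n2 = n_classes * (hidden_units + 1)
        self.n_params = self._n1 + self._n2

    def init_weights(self, rng: np.random.Generator | None = None) -> np.ndarray:
        if rng is None:
            raise ValueError("MLP initialization requires an rng")
        s1 = np.sqrt(6.0 / (self.n_features + 1 + self.hidden_units))
        s2 = np.sqrt(6.0 / (self.hidden_units + 1 + self.n_classes))
        w1 = rng.uniform(-s1, s1, self._n1)
        w2 = rng.uniform(-s2, s2, self._n2)
        return np.concatenate([w1, w2])

    def _unpack(self, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        W1 = w[: self._n1].reshape(self.hidden_units, self.n_features + 1)
        W2 = w[self._n1 :].reshape(self.n_classes, self.hidden_units + 1)
        return W1, W2

    def _forward(self, w: np.ndarray, X: np.ndarray):
        W1, W2 = self._unpack(w)
        Xb = _with_bias(X)
        H = np.tanh(Xb @ W1.T)  # (B, h)
        Hb = _with_bias(H)
        P = _softmax(Hb @ W2.T)
        return Xb, H, Hb, P, W2

    def probabilities(self, w: np.ndarray, X: np.ndarray) -> np.ndarray:
        return self._forward(w, X)[3]

    def predict(self, w: np.ndarray, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.probabilities(w, X), axis=1)

    def loss(self, w: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
        p = self.probabilities(w, X)
        return float(-np.mean(np.log(p[np.arange(len(y)), y] + 1e-300)))

    def per_sample_gradients(
        self, w: np.ndarray, X: np.ndarray, y: np.ndarray
    ) -> np.ndarray:
        if X.shape[0] == 0:
            raise ValueError("empty batch")
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        B = X.shape[0]
        Xb, H, Hb, P, W2 = self._forward(w, X)
        d2 = P - _one_hot(y, self.n_classes)  # (B, K)
        G2 = np.einsum("bk,bh->bkh", d2, Hb)  # (B, K, h+1)
        d1 = (d2 @ W2[:, : self.hidden_units]) * (1.0 - H**2)  # (B, h)
        G1 = np.einsum("bh,bd->bhd", d1, Xb)  # (B, h, d+1)
        return np.hstack([G1.reshape(B, self._n1), G2.reshape(B, self._n2)])


def make_model(kind: str, n_features: int, n_classes: int, hidden_units: int = 16):
    if kind == "softmax_regression":
        return SoftmaxRegression(n_features, n_classes)
    if kind == "mlp_1hidden":
        return MLPOneHidden(n_features, n_classes, hidden_units)
    raise ValueError(f"unknown model kind {kind!r}")


def per_sample_gradients(model, w: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Matrix of exact per-example cross-entropy gradients (rows = examples)."""
    return model.per_sample_gradients(w, X, y)


def clip_gradient(g: np.ndarray, clip: float) -> np.ndarray:
    """Rescale ``g`` to L2 norm at most ``clip``: ``g * min(1, clip/||g||)``."""
    if clip <= 0:
        raise ValueError(f"clipping threshold must be positive, got {clip}")
    norm = float(np.linalg.norm(g))
    if norm <= clip:
        return np.array(g, copy=True)
    return g * (clip / norm)


def clip_rows(G: np.ndarray, clip: float) -> np.ndarray:
    """Row-wise L2 clipping of a per-sample gradient matrix."""
    if clip <= 0:
        raise ValueError(f"clipping threshold must be positive, got {clip}")
    norms = np.linalg.norm(G, axis=1, keepdims=True)
    factors = np.minimum(1.0, clip / np.maximum(norms, 1e-300))
    return G * factors


def privatize_batch(
    clipped: np.ndarray,
    clip: float,
    sigma: float,
    rng: np.random.Generator,
    convention: str = "noise_on_sum",
    divisor: float | None = None,
) -> np.ndarray:
    """Noisy aggregate of clipped per-sample gradients.

    ``noise_on_sum`` (default, the accounted-for mechanism): Gaussian noise
    with per-coordinate std ``sigma * clip`` is added to the clipped *sum*,
    then divided by ``divisor`` (the expected batch size).  ``literal_mean``
    adds the same-scale noise to the batch mean instead.  Empty batches
    contribute pure noise (on the sum, divided by ``divisor``).
    """
    if rng is None:
        raise ValueError("privatize_batch requires an explicit rng")
    if convention not in NOISE_CONVENTIONS:
        raise ValueError(f"unknown noise convention {convention!r}")
    dim = clipped.shape[1]
    scale = sigma * clip
    noise = rng.normal(0.0, scale, dim) if scale > 0 else np.zeros(dim)
    if convention == "noise_on_sum":
        if divisor is None or divisor <= 0:
            raise ValueError("noise_on_sum requires a positive batch divisor")
        return (clipped.sum(axis=0) + noise) / divisor
    if clipped.shape[0] == 0:
        return noise
    return clipped.mean(axis=0) + noise


def sgd_step(w: np.ndarray, noisy_gradient: np.ndarray, eta: float) -> np.ndarray:
    """Plain gradient step ``w - eta * g``."""
    if w.shape != noisy_gradient.shape:
        raise ValueError("weight/gradient shape mismatch")
    return w - eta * noisy_gradient


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run (schedule included)."""

    schedule: ScheduleConfig
    learning_rate: float = 0.05
    batch_size: int = 128
    sampling: str = "poisson"
    noise_convention: str = "noise_on_sum"
    model_kind: str = "softmax_regression"
    hidden_units: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.sampling not in SAMPLING_MODES:
            raise ValueError(f"unknown sampling mode {self.sampling!r}")
        if self.noise_convention not in NOISE_CONVENTIONS:
            raise ValueError(f"unknown noise convention {self.noise_convention!r}")
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")


@dataclass
class TrainResult:
    """Final weights, loss trace, privacy ledger and stage transition log."""

    weights: np.ndarray
    loss_trace: np.ndarray
    ledger: PrivacyLedger
    stage_log: list
    model: object
    config: TrainConfig

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(self.weights, X)


def train(dataset, config: TrainConfig) -> TrainResult:
    """Run the dual dynamic DP-SGD loop for the schedule's full iteration count.

    One seeded generator per run, split into independent streams for weight
    initialization, batch sampling and noise, so e.g. changing the batch size
    does not perturb the noise stream.  Fully reproducible from the seed.
    """
    if dataset.n_classes < 2:
        raise ValueError("training requires at least 2 classes")
    N = len(dataset)
    B = config.batch_size
    if B > N:
        raise ValueError(f"batch_size {B} exceeds dataset size {N}")
    table = build_table(config.schedule)
    T = config.schedule.total_iterations
    q = B / N
    model = make_model(
        config.model_kind, dataset.n_features, dataset.n_classes, config.hidden_units
    )
    ss = np.random.SeedSequence(config.seed)
    init_rng, sample_rng, noise_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    w = model.init_weights(init_rng)

    X, y = dataset.features, dataset.labels
    loss_trace = np.full(T, np.nan)
    stage_log: list = []
    prev_stage = -1
    for t in range(T):
        stage = table.stage_of(t)
        sigma_t, c_t = table.sigmas[stage], table.clips[stage]
        if stage != prev_stage:
            stage_log.append(t)
            logger.info(
                "iteration %d: entering stage %d (sigma=%.6g, clip=%.6g)",
                t, stage, sigma_t, c_t,
            )
            prev_stage = stage
        if config.sampling == "poisson":
            idx = np.flatnonzero(sample_rng.random(N) < q)
        else:
            idx = sample_rng.choice(N, size=B, replace=False)
        if idx.size > 0:
            G = model.per_sample_gradients(w, X[idx], y[idx])
            Gc = clip_rows(G, c_t)
            loss = model.loss(w, X[idx], y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at iteration {t} (stage {stage}); "
                    "reduce the learning rate or noise scale"
                )
            loss_trace[t] = loss
        else:
            Gc = np.zeros((0, model.n_params))
        g = privatize_batch(
            Gc, c_t, sigma_t, noise_rng, config.noise_convention, divisor=float(B)
        )
        w = sgd_step(w, g, config.learning_rate)

    ledger = PrivacyLedger(
        [LedgerEntry(s, q, int(d)) for s, d in zip(table.sigmas, table.durations)]
    )
    return TrainResult(
        weights=w,
        loss_trace=loss_trace,
        ledger=ledger,
        stage_log=stage_log,
        model=model,
        config=config,
    )


def static_schedule(schedule: ScheduleConfig, sigma: float | None = None,
                    clip: float | None = None) -> ScheduleConfig:
    """Degenerate one-stage schedule: constant sigma and clipping threshold."""
    return dataclasses.replace(
        schedule,
        beta=1.0,
        clip_decay=1.0,
        n=1,
        sigma0=schedule.sigma0 if sigma is None else sigma,
        c0=schedule.c0 if clip is None else clip,
    )


def train_static_baseline(
    dataset, config: TrainConfig, sigma: float | None = None,
    clip: float | None = None,
) -> TrainResult:
    """Standard DP-SGD ablation baseline: fixed noise multiplier and threshold.

    Identical loop, sampling and randomness conventions as :func:`train`,
    with the schedule collapsed to a single stage.
    """
    static_cfg = dataclasses.replace(
        config, schedule=static_schedule(config.schedule, sigma, clip)
    )
    return train(dataset, static_cfg)
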