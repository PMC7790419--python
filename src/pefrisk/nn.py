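"""Compact feed-forward binary classifier with per-layer freezing.

The networks used for personalized risk prediction are small fully
connected nets (one or two hidden layers of 32 ReLU units, sigmoid output)
trained full-batch with Adam on binary cross-entropy. The implementation is
plain numpy: with at most ~1,400 weights, a vectorized forward/backward
pass is faster than any framework overhead, and transfer learning needs
direct control over which layers update.

Conventions
-----------
* The network output is the model's confidence that the day is in the
  *red zone* (zone label 0). Training targets are therefore ``t = 1`` for
  red days and ``t = 0`` for safe days; ``predict_zones`` maps probability
  >= 0.5 back to zone label 0.
* A freeze mask has one boolean per weight-bearing layer (hidden layers
  then output); frozen layers receive no gradient updates and stay
  bit-identical to their initial (source) values.
* Initialization is seeded uniform fan-in scaling: W ~ U(+-1/sqrt(fan_in)),
  biases zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import ConfigError, DataError

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "ParameterAudit",
    "count_parameters",
    "MLP",
]


@dataclass(frozen=True)
class NetworkSpec:
    """Layer sizes of a feed-forward net with a single sigmoid output unit."""

    input_dim: int
    hidden: tuple[int, ...] = (32,)

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ConfigError(f"input_dim must be >= 1, got {self.input_dim}")
        if not self.hidden or any(h < 1 for h in self.hidden):
            raise ConfigError(f"hidden widths must all be >= 1, got {self.hidden}")

    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        """(fan_in, fan_out) for each weight-bearing layer, output last."""
        widths = [self.input_dim, *self.hidden, 1]
        return list(zip(widths[:-1], widths[1:]))

    @property
    def n_layers(self) -> int:
        return len(self.hidden) + 1


def validate_mask(spec: NetworkSpec, mask) -> tuple[bool, ...]:
    mask = tuple(bool(m) for m in mask)
    if len(mask) != spec.n_layers:
        raise ConfigError(
            f"freeze mask length {len(mask)} != number of layers {spec.n_layers}"
        )
    return mask


@dataclass(frozen=True)
class ParameterAudit:
    """Total vs unfrozen (trainable) parameter counts, biases included."""

    total: int
    unfrozen: int

    @property
    def unfrozen_ratio(self) -> float:
        """Percent unfrozen, one decimal, half away from zero."""
        pct = Decimal(100 * self.unfrozen) / Decimal(self.total)
        return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def count_parameters(spec: NetworkSpec, mask=None) -> ParameterAudit:
    """Audit parameter counts under a freeze mask (None = nothing frozen)."""
    mask = validate_mask(spec, mask) if mask is not None else (False,) * spec.n_layers
    per_layer = [fi * fo + fo for fi, fo in spec.layer_dims]
    total = sum(per_layer)
    unfrozen = sum(p for p, frozen in zip(per_layer, mask) if not frozen)
    return ParameterAudit(total=total, unfrozen=unfrozen)


@dataclass(frozen=True)
class TrainConfig:
    """One training phase. Defaults follow the study protocol: Adam at
    learning rate 1e-3, full-batch (batch_size None)."""

    epochs: int
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigError(f"epochs must be >= 1, got {self.epochs}")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")


_CLIP = 1e-7  # probability clip for the cross-entropy


@dataclass
class MLP:
    """A trainable feed-forward net; see module docstring for conventions."""

    spec: NetworkSpec
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)

    @classmethod
    def initialize(cls, spec: NetworkSpec, seed: int) -> "MLP":
        rng = np.random.default_rng(seed)
        weights, biases = [], []
        for fan_in, fan_out in spec.layer_dims:
            bound = 1.0 / np.sqrt(fan_in)
            weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        return cls(spec=spec, weights=weights, biases=biases)

    def copy(self) -> "MLP":
        return MLP(
            spec=self.spec,
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
        )

    def n_parameters(self) -> int:
        return count_parameters(self.spec).total

    # ---- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray):
        """Returns (probabilities, per-layer activations) for backprop."""
        acts = [X]
        a = X
        last = len(self.weights) - 1
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = 1.0 / (1.0 + np.exp(-z)) if l == last else np.maximum(z, 0.0)
            acts.append(a)
        return a[:, 0], acts

    def predict_proba(self, X) -> np.ndarray:
        """P(red zone) per row."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.spec.input_dim:
            raise DataError(
                f"expected feature dimension {self.spec.input_dim}, got {X.shape}"
            )
        return self._forward(X)[0]

    def predict_zones(self, X) -> np.ndarray:
        """Zone labels: 0 (red) where P(red) >= 0.5, else 1 (safe)."""
        return np.where(self.predict_proba(X) >= 0.5, 0, 1)

    def loss(self, X, targets) -> float:
        """Mean binary cross-entropy against red-zone targets in {0, 1}."""
        p = np.clip(self.predict_proba(X), _CLIP, 1.0 - _CLIP)
        t = np.asarray(targets, dtype=float)
        return float(-np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))

    def gradients(self, X, targets):
        """Backprop gradients of the mean BCE loss w.r.t. all parameters."""
        X = np.asarray(X, dtype=float)
        t = np.asarray(targets, dtype=float)
        p, acts = self._forward(X)
        n = len(t)
        # sigmoid + BCE: dL/dz_out = (p - t) / n
        delta = ((p - t) / n)[:, None]
        gW = [np.empty(0)] * len(self.weights)
        gb = [np.empty(0)] * len(self.weights)
        for l in range(len(self.weights) - 1, -1, -1):
            gW[l] = acts[l].T @ delta
            gb[l] = delta.sum(axis=0)
            if l > 0:
                delta = (delta @ self.weights[l].T) * (acts[l] > 0)
        return gW, gb

    # ---- training -----------------------------------------------------------

    def fit(
        self,
        X,
        targets,
        config: TrainConfig,
        freeze_mask=None,
        seed: int = 0,
    ) -> list[float]:
        """Adam training; returns the per-epoch loss trace.

        ``targets`` are red-zone indicators in {0, 1}. Frozen layers are
        excluded from updates entirely (weights and optimizer state).
        """
        X = np.asarray(X, dtype=float)
        t = np.asarray(targets, dtype=float)
        if len(X) != len(t) or len(X) == 0:
            raise DataError("need equal, nonzero numbers of rows and targets")
        mask = (
            validate_mask(self.spec, freeze_mask)
            if freeze_mask is not None
            else (False,) * self.spec.n_layers
        )

        mW = [np.zeros_like(w) for w in self.weights]
        vW = [np.zeros_like(w) for w in self.weights]
        mb = [np.zeros_like(b) for b in self.biases]
        vb = [np.zeros_like(b) for b in self.biases]
        rng = np.random.default_rng(seed)
        step = 0
        trace = []
        for _ in range(config.epochs):
            if config.batch_size is None or config.batch_size >= len(X):
                batches = [(X, t)]
            else:
                order = rng.permutation(len(X))
                batches = [
                    (X[order[i : i + config.batch_size]], t[order[i : i + config.batch_size]])
                    for i in range(0, len(X), config.batch_size)
                ]
            for Xb, tb in batches:
                gW, gb = self.gradients(Xb, tb)
                step += 1
                c1 = 1.0 - config.beta1**step
                c2 = 1.0 - config.beta2**step
                for l in range(len(self.weights)):
                    if mask[l]:
                        continue
                    mW[l] = config.beta1 * mW[l] + (1 - config.beta1) * gW[l]
                    vW[l] = config.beta2 * vW[l] + (1 - config.beta2) * gW[l] ** 2
                    self.weights[l] -= config.learning_rate * (mW[l] / c1) / (
                        np.sqrt(vW[l] / c2) + config.eps
                    )
                    mb[l] = config.beta1 * mb[l] + (1 - config.beta1) * gb[l]
                    vb[l] = config.beta2 * vb[l] + (1 - config.beta2) * gb[l] ** 2
                    self.biases[l] -= config.learning_rate * (mb[l] / c1) / (
                        np.sqrt(vb[l] / c2) + config.eps
                    )
            trace.append(self.loss(X, t))
        return trace
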