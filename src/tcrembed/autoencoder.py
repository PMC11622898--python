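"""Dense two-layer autoencoder for compressing one-hot sequence encodings.

One dense encoder layer (nonlinearity to ``hidden_dim``) and one dense
decoder layer back to the input width, trained to minimize mean squared
reconstruction error with the Adam adaptive-moment update rule. The
implementation is plain numpy: the model is small enough that a deep
learning framework would add nothing but weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import EmbeddingMatrix


@dataclass(frozen=True)
class AutoencoderConfig:
    hidden_dim: int = 50
    epochs: int = 300
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.hidden_dim < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("hidden_dim/epochs must be >= 1, learning_rate > 0")


def _activation(name: str):
    if name == "relu":
        return lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)
    if name == "tanh":
        return np.tanh, lambda z: 1.0 - np.tanh(z) ** 2
    if name == "linear":
        return lambda z: z, lambda z: np.ones_like(z)
    raise ValueError(f"unknown activation {name!r}")


class _Adam:
    """Adam optimizer state for one parameter array."""

    def __init__(self, shape, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def step(self, param: np.ndarray, grad: np.ndarray) -> None:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad**2
        m_hat = self.m / (1 - self.beta1**self.t)
        v_hat = self.v / (1 - self.beta2**self.t)
        param -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train_autoencoder(
    x: np.ndarray, config: AutoencoderConfig
) -> tuple[dict[str, np.ndarray], list[float]]:
    """Train encoder/decoder weights on ``x``; returns (params, per-epoch MSE).

    Weights are initialized small-uniform from the seeded generator and
    minibatches are reshuffled each epoch from the same stream, so a fixed
    seed gives bit-identical results.
    """
    x = np.asarray(x, dtype=float)
    n, d = x.shape
    h = config.hidden_dim
    if h >= d:
        raise ValueError(f"hidden_dim={h} must be smaller than input width {d}")
    rng = np.random.default_rng(config.seed)
    act, act_grad = _activation(config.activation)
    params = {
        "W1": rng.uniform(-0.05, 0.05, size=(d, h)),
        "b1": np.zeros(h),
        "W2": rng.uniform(-0.05, 0.05, size=(h, d)),
        "b2": np.zeros(d),
    }
    opts = {k: _Adam(v.shape, config.learning_rate) for k, v in params.items()}
    losses: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x[idx]
            z1 = xb @ params["W1"] + params["b1"]
            a1 = act(z1)
            recon = a1 @ params["W2"] + params["b2"]
            err = recon - xb  # dL/drecon * (n*d)/2 for L = mean sq error
            scale = 2.0 / err.size
            g_recon = scale * err
            grads = {
                "W2": a1.T @ g_recon,
                "b2": g_recon.sum(axis=0),
            }
            g_a1 = g_recon @ params["W2"].T
            g_z1 = g_a1 * act_grad(z1)
            grads["W1"] = xb.T @ g_z1
            grads["b1"] = g_z1.sum(axis=0)
            for k in params:
                opts[k].step(params[k], grads[k])
        full_recon = act(x @ params["W1"] + params["b1"]) @ params["W2"] + params["b2"]
        losses.append(float(np.mean((full_recon - x) ** 2)))
    return params, losses


def encode(x: np.ndarray, params: dict[str, np.ndarray], activation: str = "relu") -> np.ndarray:
    act, _ = _activation(activation)
    return act(np.asarray(x, dtype=float) @ params["W1"] + params["b1"])


def autoencoder_embed(
    matrix: EmbeddingMatrix,
    config: AutoencoderConfig | None = None,
    *,
    return_losses: bool = False,
):
    """Compress a (one-hot) embedding to ``hidden_dim`` encoder outputs.

    Returns the n x hidden_dim EmbeddingMatrix, or
    ``(matrix, per-epoch losses)`` when ``return_losses`` is set.
    """
    config = config or AutoencoderConfig()
    params, losses = train_autoencoder(matrix.values, config)
    z = encode(matrix.values, params, config.activation)
    out = EmbeddingMatrix(
        z, [f"ae_{i}" for i in range(config.hidden_dim)], list(matrix.source_ids)
    )
    if return_losses:
        return out, losses
    return out
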