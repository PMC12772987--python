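"""1D convolutional event-count regressor, implemented in numpy.

The network maps a standardized airflow segment to a single scalar — the
estimated number of apneic/hypopneic events it contains. It stacks ``Nc``
identical blocks (conv -> batch-norm -> ReLU -> max-pool -> dropout),
flattens the final feature maps and applies one linear output unit. Forward
and backward passes are written explicitly so that gradients with respect to
intermediate feature maps (needed for Grad-CAM) and layer-wise attribution
multipliers (needed for Deep-SHAP) are available without a deep-learning
framework.

Data layout is channels-last ``(N, L, C)`` and convolutions are evaluated as
K shifted (L, C_in) x (C_in, C_out) matrix products, which keeps everything
inside BLAS on a single CPU. Convolutions use stride 1 and "same"
zero-padding, so temporal length is reduced only by the pooling. Arithmetic
runs in float32 by default (float64 available for gradient checking).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelConfig",
    "CNNRegressor",
    "Conv1d",
    "BatchNorm1d",
    "MaxPool1d",
    "Dropout",
    "Dense",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The full-scale configuration uses 256 filters and 6-8 blocks; the desk
    preset (16 filters, 4 blocks) keeps the same structure at a size that
    trains in minutes on a single CPU.
    """

    n_blocks: int = 4
    n_filters: int = 16
    kernel: int = 5
    stride: int = 1
    pool: int = 2
    r_drop: float = 0.1
    input_length: int = 2400
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.kernel % 2 != 1:
            raise ValueError("kernel must be odd (same-padding alignment)")
        if self.stride != 1:
            raise ValueError("only stride 1 is supported")
        if not 0.0 <= self.r_drop < 1.0:
            raise ValueError("r_drop must be in [0, 1)")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be float32 or float64")
        if min(self.block_lengths()) < 1:
            raise ValueError(
                f"input_length {self.input_length} collapses to zero after "
                f"{self.n_blocks} pooling stages"
            )

    def block_lengths(self) -> list[int]:
        """Temporal length after each block's pooling (floor halving)."""
        L, out = self.input_length, []
        for _ in range(self.n_blocks):
            L = L // self.pool
            out.append(L)
        return out

    @classmethod
    def full_scale(cls, input_length: int = 2400, n_blocks: int = 7, r_drop: float = 0.1):
        """Full-scale preset: 256 filters per block."""
        return cls(n_blocks=n_blocks, n_filters=256, r_drop=r_drop, input_length=input_length)

    @classmethod
    def desk(cls, input_length: int = 2400, n_blocks: int = 4, r_drop: float = 0.1):
        """Small preset trainable on one CPU in minutes."""
        return cls(n_blocks=n_blocks, n_filters=16, r_drop=r_drop, input_length=input_length)


# ---------------------------------------------------------------------------
# layers (channels-last: every activation tensor is (N, L, C))


class Conv1d:
    """Stride-1 same-padded 1D convolution with He-initialized weights.

    Weights are stored as ``(K, C_in, C_out)``; the forward pass sums K
    shifted matrix products over views of the zero-padded input.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.W = rng.normal(0.0, scale, (kernel, c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self._xp: np.ndarray | None = None

    @property
    def kernel(self) -> int:
        return self.W.shape[0]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        K = self.kernel
        p = K // 2
        L = x.shape[1]
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        if training:
            self._xp = xp
        out = xp[:, 0:L, :] @ self.W[0]
        for k in range(1, K):
            out += xp[:, k : k + L, :] @ self.W[k]
        out += self.b
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        xp = self._xp
        K = self.kernel
        L = g.shape[1]
        self.gW = np.stack(
            [np.tensordot(xp[:, k : k + L, :], g, axes=([0, 1], [0, 1])) for k in range(K)]
        )
        self.gb = g.sum(axis=(0, 1))
        return self.input_grad(g)

    def input_grad(self, g: np.ndarray) -> np.ndarray:
        """Gradient w.r.t. the layer input (pure linear back-transform)."""
        K = self.kernel
        p = K // 2
        L = g.shape[1]
        gp = np.pad(g, ((0, 0), (p, p), (0, 0)))
        WT = self.W.transpose(0, 2, 1)  # (K, C_out, C_in)
        gx = gp[:, K - 1 : K - 1 + L, :] @ WT[0]
        for k in range(1, K):
            gx += gp[:, K - 1 - k : K - 1 - k + L, :] @ WT[k]
        return gx


class BatchNorm1d:
    """Per-channel batch normalization over the (batch, time) axes."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = np.maximum((x * x).mean(axis=(0, 1)) - mean * mean, 0.0)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(x.dtype)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(x.dtype)
            self._invstd = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
            self._xhat = (x - mean) * self._invstd
            return self.gamma * self._xhat + self.beta
        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma * invstd * (x - self.running_mean) + self.beta

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        self.ggamma = np.sum(g * xhat, axis=(0, 1))
        self.gbeta = g.sum(axis=(0, 1))
        gx_hat = g * self.gamma
        term2 = gx_hat.mean(axis=(0, 1))
        term3 = xhat * (gx_hat * xhat).mean(axis=(0, 1))
        return invstd * (gx_hat - term2 - term3)

    def inference_scale(self) -> np.ndarray:
        """Per-channel affine slope in inference mode (for attribution)."""
        return self.gamma / np.sqrt(self.running_var + self.eps)


class MaxPool1d:
    """Non-overlapping max-pooling over time; a trailing remainder is dropped."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        p = self.pool
        if p == 1:
            self._shape = x.shape
            return x
        N, L, C = x.shape
        L2 = L // p
        xr = x[:, : L2 * p, :].reshape(N, L2, p, C)
        if p == 2:  # fast path: a comparison mask instead of argmax
            a, b = xr[:, :, 0, :], xr[:, :, 1, :]
            if training:
                self._first_wins = a >= b
                self._shape = x.shape
            return np.maximum(a, b)
        if training:
            self._argmax = xr.argmax(axis=2)
            self._shape = x.shape
        return xr.max(axis=2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        p = self.pool
        if p == 1:
            return g
        N, L, C = self._shape
        L2 = g.shape[1]
        gx = np.zeros((N, L2, p, C), dtype=g.dtype)
        if p == 2:
            gx[:, :, 0, :] = np.where(self._first_wins, g, 0)
            gx[:, :, 1, :] = np.where(self._first_wins, 0, g)
        else:
            n, l2, c = np.ogrid[:N, :L2, :C]
            gx[n, l2, self._argmax, c] = g
        gx = gx.reshape(N, L2 * p, C)
        if L2 * p < L:
            gx = np.pad(gx, ((0, 0), (0, L - L2 * p), (0, 0)))
        return gx


class Dropout:
    """Inverted dropout; identity in inference mode."""

    def __init__(self, rate: float):
        self.rate = rate
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        u = rng.random(size=x.shape, dtype=np.float32 if x.dtype == np.float32 else np.float64)
        self._mask = (u < keep).astype(x.dtype) / np.asarray(keep, dtype=x.dtype)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g if self._mask is None else g * self._mask


class Dense:
    """Fully connected layer; used as the single linear output unit."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = rng.normal(0.0, np.sqrt(1.0 / n_in), (n_out, n_in)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.gW = g.T @ self._x
        self.gb = g.sum(axis=0)
        return g @ self.W


# ---------------------------------------------------------------------------
# model


class CNNRegressor:
    """Nc x (conv-BN-ReLU-pool-dropout) -> flatten -> linear scalar output."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.dtype = np.dtype(config.dtype).type
        rng = np.random.default_rng(seed)
        self.blocks: list[dict] = []
        c_in = 1
        for _ in range(config.n_blocks):
            self.blocks.append(
                {
                    "conv": Conv1d(c_in, config.n_filters, config.kernel, rng, self.dtype),
                    "bn": BatchNorm1d(config.n_filters, dtype=self.dtype),
                    "pool": MaxPool1d(config.pool),
                    "drop": Dropout(config.r_drop),
                }
            )
            c_in = config.n_filters
        self.flat_shape = (config.block_lengths()[-1], config.n_filters)
        self.head = Dense(self.flat_shape[0] * self.flat_shape[1], 1, rng, self.dtype)

    # -- forward -----------------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Run a batch of segments ``(N, L)``; returns ``(N,)`` predictions."""
        x = np.asarray(x)
        if x.ndim != 2:
            raise ValueError("expected a batch of segments with shape (N, L)")
        if x.shape[1] != self.config.input_length:
            raise ValueError(
                f"segment length {x.shape[1]} does not match configured "
                f"input_length {self.config.input_length}"
            )
        h = x.astype(self.dtype, copy=False)[:, :, None]
        for blk in self.blocks:
            h = blk["conv"].forward(h, training)
            h = blk["bn"].forward(h, training)
            if training:
                blk["_relu_mask"] = h > 0
            h = np.maximum(h, 0.0)
            h = blk["pool"].forward(h, training)
            h = blk["drop"].forward(h, training, rng=rng)
        h = h.reshape(h.shape[0], -1)
        return self.head.forward(h, training)[:, 0]

    def backward(self, dpred: np.ndarray) -> np.ndarray:
        """Backpropagate ``dLoss/dpred`` (shape ``(N,)``) through the net;
        requires a preceding ``forward(..., training=True)``."""
        g = self.head.backward(dpred.astype(self.dtype)[:, None])
        g = g.reshape(g.shape[0], *self.flat_shape)
        for blk in reversed(self.blocks):
            g = blk["drop"].backward(g)
            g = blk["pool"].backward(g)
            g = g * blk["_relu_mask"]
            g = blk["bn"].backward(g)
            g = blk["conv"].backward(g)
        return g

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference-mode predictions, independent of batch composition."""
        x = np.asarray(x)
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(self.forward(x[i : i + batch_size], training=False))
        return np.concatenate(out).astype(float)

    # -- parameter access --------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        params: dict[str, np.ndarray] = {}
        for i, blk in enumerate(self.blocks):
            params[f"block{i}.conv.W"] = blk["conv"].W
            params[f"block{i}.conv.b"] = blk["conv"].b
            params[f"block{i}.bn.gamma"] = blk["bn"].gamma
            params[f"block{i}.bn.beta"] = blk["bn"].beta
        params["head.W"] = self.head.W
        params["head.b"] = self.head.b
        return params

    def gradients(self) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        for i, blk in enumerate(self.blocks):
            grads[f"block{i}.conv.W"] = blk["conv"].gW
            grads[f"block{i}.conv.b"] = blk["conv"].gb
            grads[f"block{i}.bn.gamma"] = blk["bn"].ggamma
            grads[f"block{i}.bn.beta"] = blk["bn"].gbeta
        grads["head.W"] = self.head.gW
        grads["head.b"] = self.head.gb
        return grads

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.copy() for k, v in self.parameters().items()}
        for i, blk in enumerate(self.blocks):
            state[f"block{i}.bn.running_mean"] = blk["bn"].running_mean.copy()
            state[f"block{i}.bn.running_var"] = blk["bn"].running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, blk in enumerate(self.blocks):
            blk["conv"].W = state[f"block{i}.conv.W"].astype(self.dtype)
            blk["conv"].b = state[f"block{i}.conv.b"].astype(self.dtype)
            blk["bn"].gamma = state[f"block{i}.bn.gamma"].astype(self.dtype)
            blk["bn"].beta = state[f"block{i}.bn.beta"].astype(self.dtype)
            blk["bn"].running_mean = state[f"block{i}.bn.running_mean"].astype(self.dtype)
            blk["bn"].running_var = state[f"block{i}.bn.running_var"].astype(self.dtype)
        self.head.W = state["head.W"].astype(self.dtype)
        self.head.b = state["head.b"].astype(self.dtype)

    def n_parameters(self) -> int:
        """Trainable parameter count (conv + batch-norm + output unit)."""
        return sum(v.size for v in self.parameters().values())
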