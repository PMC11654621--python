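"""Network layers and optimizers for the generator/critic pair.

Convolutions run along the modality axis (length M) with kernel size 2,
stride 1 and same-length zero padding on the right, so a tensor
(n, M, channels) keeps its length through every layer.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, matmul, relu, reshape, shift_left, sqrt


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Tensor(glorot_uniform(rng, n_in, n_out, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.W) + self.b

    def params(self):
        return [self.W, self.b]


class Conv1dK2:
    """1-D convolution, kernel 2, stride 1, 'same' padding (zero on the right).

    out[:, t, :] = x[:, t, :] @ W0 + x[:, t+1, :] @ W1 + b   (x[:, M, :] = 0)
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in, fan_out = 2 * c_in, c_out
        self.W0 = Tensor(glorot_uniform(rng, fan_in, fan_out, (c_in, c_out)), requires_grad=True)
        self.W1 = Tensor(glorot_uniform(rng, fan_in, fan_out, (c_in, c_out)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.W0) + matmul(shift_left(x), self.W1) + self.b

    def params(self):
        return [self.W0, self.W1, self.b]


class BatchNorm:
    """Channel-wise batch normalization over (batch, position) for (n, M, ch)."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            m = x.mean(axis=(0, 1), keepdims=True)
            v = ((x - m) ** 2).mean(axis=(0, 1), keepdims=True)
            mom = self.momentum
            self.running_mean = mom * self.running_mean + (1 - mom) * m.data.ravel()
            self.running_var = mom * self.running_var + (1 - mom) * v.data.ravel()
        else:
            m = Tensor(self.running_mean.reshape(1, 1, -1))
            v = Tensor(self.running_var.reshape(1, 1, -1))
        xhat = (x - m) * ((v + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta

    def params(self):
        return [self.gamma, self.beta]


class Generator:
    """Noise (n, latent_dim) -> synthetic embedding tensor (n, M, C).

    An affine layer lifts the noise to an M-position sequence, followed by
    three convolutions; batch normalization sits after the first and second
    convolution and the output convolution is linear.
    """

    def __init__(self, latent_dim: int, M: int, C: int, filters, rng: np.random.Generator,
                 bn_momentum: float = 0.99, bn_eps: float = 1e-3):
        f0, f1, f2 = filters
        if f2 != C:
            raise ValueError(f"final filter count {f2} must equal C={C}")
        self.latent_dim = latent_dim
        self.M, self.C = M, C
        self.fc = Dense(latent_dim, M * latent_dim, rng)
        self.conv1 = Conv1dK2(latent_dim, f0, rng)
        self.bn1 = BatchNorm(f0, bn_momentum, bn_eps)
        self.conv2 = Conv1dK2(f0, f1, rng)
        self.bn2 = BatchNorm(f1, bn_momentum, bn_eps)
        self.conv3 = Conv1dK2(f1, C, rng)

    def __call__(self, z: Tensor, training: bool) -> Tensor:
        n = z.shape[0]
        h = reshape(self.fc(z), (n, self.M, self.latent_dim))
        h = relu(self.bn1(self.conv1(h), training))
        h = relu(self.bn2(self.conv2(h), training))
        return self.conv3(h)

    def params(self):
        return (self.fc.params() + self.conv1.params() + self.bn1.params()
                + self.conv2.params() + self.bn2.params() + self.conv3.params())


class Critic:
    """Embedding tensor (n, M, C) -> unbounded score per sample.

    Two convolutions and a single affine unit; no normalization layers, as
    required for a well-defined gradient penalty.
    """

    def __init__(self, M: int, C: int, filters, rng: np.random.Generator):
        f0, f1 = filters
        self.M = M
        self.conv1 = Conv1dK2(C, f0, rng)
        self.conv2 = Conv1dK2(f0, f1, rng)
        self.head = Dense(M * f1, 1, rng)
        self._f1 = f1

    def __call__(self, x: Tensor) -> Tensor:
        h = relu(self.conv1(x))
        h = relu(self.conv2(h))
        h = reshape(h, (x.shape[0], self.M * self._f1))
        return reshape(self.head(h), (x.shape[0],))

    def params(self):
        return self.conv1.params() + self.conv2.params() + self.head.params()


class Adam:
    def __init__(self, lr=0.001, beta1=0.5, beta2=0.9, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = None
        self.v = None

    def step(self, params, grads):
        if self.m is None:
            self.m = [np.zeros_like(p.data) for p in params]
            self.v = [np.zeros_like(p.data) for p in params]
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            gd = g.data
            m *= self.b1
            m += (1 - self.b1) * gd
            v *= self.b2
            v += (1 - self.b2) * gd * gd
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class RMSprop:
    def __init__(self, lr=0.0005, rho=0.9, eps=1e-7):
        self.lr, self.rho, self.eps = lr, rho, eps
        self.sq = None

    def step(self, params, grads):
        if self.sq is None:
            self.sq = [np.zeros_like(p.data) for p in params]
        for p, g, s in zip(params, grads, self.sq):
            gd = g.data
            s *= self.rho
            s += (1 - self.rho) * gd * gd
            p.data -= self.lr * gd / (np.sqrt(s) + self.eps)
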