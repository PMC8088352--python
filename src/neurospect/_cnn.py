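"""A small, fully deterministic 1-D convolutional network in numpy.

The feature vectors here are tiny (7 values per subject), so the network is
implemented directly with explicit forward/backward passes rather than a
deep-learning framework: conv -> batch-norm -> ReLU -> max-pool blocks, a
fully connected hidden layer with dropout, and a softmax output trained with
cross-entropy via Adam.  All randomness (init, shuffling, dropout) flows
from a single generator, so identical configs give bitwise-identical
weights and curves.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def relu(x):
    """Rectifier: 0 for negative inputs, identity otherwise (elementwise)."""
    return np.maximum(np.asarray(x, dtype=np.float64), 0.0)


def softmax(scores, axis=-1):
    """Numerically stable softmax along ``axis``; rows sum to 1."""
    scores = np.asarray(scores, dtype=np.float64)
    shifted = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


class _Conv1d:
    """Same-padded 1-D convolution, stride 1."""

    def __init__(self, c_in, c_out, kernel, rng):
        scale = np.sqrt(2.0 / (c_in * kernel))  # He init for ReLU chains
        self.w = rng.standard_normal((c_out, c_in, kernel)) * scale
        self.b = np.zeros(c_out)
        self.kernel = kernel

    def forward(self, x):
        k = self.kernel
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, k - 1 - pad)))
        windows = sliding_window_view(xp, k, axis=2)  # (B, Cin, L, K)
        self._windows = windows
        return np.einsum("bilk,oik->bol", windows, self.w) + self.b[None, :, None]

    def backward(self, grad):
        # grad: (B, Cout, L)
        self.gw = np.einsum("bol,bilk->oik", grad, self._windows)
        self.gb = grad.sum(axis=(0, 2))
        k = self.kernel
        pad = k // 2
        b, _, length = grad.shape
        c_in = self.w.shape[1]
        gxp = np.zeros((b, c_in, length + k - 1))
        for kk in range(k):
            gxp[:, :, kk : kk + length] += np.einsum("bol,oi->bil", grad, self.w[:, :, kk])
        return gxp[:, :, pad : pad + length]

    def params(self):
        return [(self.w, "gw", self), (self.b, "gb", self)]


class _BatchNorm1d:
    def __init__(self, channels):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - _BN_MOMENTUM) * self.running_mean + _BN_MOMENTUM * mean
            self.running_var = (1 - _BN_MOMENTUM) * self.running_var + _BN_MOMENTUM * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + _BN_EPS)
        self._xhat = (x - mean[None, :, None]) / self._std[None, :, None]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, grad):
        n = grad.shape[0] * grad.shape[2]
        self.ggamma = (grad * self._xhat).sum(axis=(0, 2))
        self.gbeta = grad.sum(axis=(0, 2))
        gxhat = grad * self.gamma[None, :, None]
        gx = (
            gxhat
            - gxhat.mean(axis=(0, 2), keepdims=True)
            - self._xhat * (gxhat * self._xhat).mean(axis=(0, 2), keepdims=True)
        ) / self._std[None, :, None]
        return gx

    def params(self):
        return [(self.gamma, "ggamma", self), (self.beta, "gbeta", self)]


class _MaxPool1d:
    """Non-overlapping max pooling (extent 2, stride 2 by default);
    a trailing odd sample is dropped."""

    def __init__(self, extent=2, stride=2):
        if extent != stride:
            raise ValueError("only non-overlapping pooling is supported")
        self.extent = extent

    def forward(self, x):
        b, c, length = x.shape
        out_len = length // self.extent
        trimmed = x[:, :, : out_len * self.extent]
        blocks = trimmed.reshape(b, c, out_len, self.extent)
        self._argmax = blocks.argmax(axis=3)
        self._in_shape = x.shape
        return blocks.max(axis=3)

    def backward(self, grad):
        b, c, out_len = grad.shape
        gx = np.zeros(self._in_shape)
        blocks = gx[:, :, : out_len * self.extent].reshape(b, c, out_len, self.extent)
        bi, ci, li = np.ogrid[:b, :c, :out_len]
        blocks[bi, ci, li, self._argmax] = grad
        return gx

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in, n_out, rng):
        self.w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.b = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [(self.w, "gw", self), (self.b, "gb", self)]


class SmallCNN:
    """conv blocks -> flatten -> dense -> dropout -> dense -> softmax."""

    def __init__(self, input_len, conv_blocks, pool_after, pool_extent,
                 hidden_units, dropout_rate, n_classes, rng):
        self.rng = rng
        self.dropout_rate = dropout_rate
        self.layers = []
        c_in, length = 1, input_len
        for i, (n_filters, kernel, stride) in enumerate(conv_blocks):
            if stride != 1:
                raise ValueError("conv stride must be 1")
            self.layers.append(_Conv1d(c_in, n_filters, kernel, rng))
            self.layers.append(_BatchNorm1d(n_filters))
            self.layers.append("relu")
            if i in pool_after:
                if length < pool_extent:
                    raise ValueError(
                        f"cannot pool length {length} with extent {pool_extent}"
                    )
                self.layers.append(_MaxPool1d(pool_extent, pool_extent))
                length //= pool_extent
            c_in = n_filters
        if length < 1:
            raise ValueError("conv/pool chain collapses the signal to length 0")
        self.flat_dim = c_in * length
        self.fc1 = _Dense(self.flat_dim, hidden_units, rng)
        self.fc2 = _Dense(hidden_units, n_classes, rng)

    def _forward(self, x, training):
        h = x
        self._relu_masks = []
        for layer in self.layers:
            if layer == "relu":
                h = relu(h)
                self._relu_masks.append(h > 0)
            elif isinstance(layer, _BatchNorm1d):
                h = layer.forward(h, training)
            else:
                h = layer.forward(h)
        self._conv_out_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = relu(self.fc1.forward(h))
        self._fc1_mask = h > 0
        if training and self.dropout_rate > 0:
            keep = 1.0 - self.dropout_rate
            self._drop_mask = (self.rng.random(h.shape) < keep) / keep
            h = h * self._drop_mask
        else:
            self._drop_mask = None
        return self.fc2.forward(h)

    def predict_proba(self, x):
        return softmax(self._forward(x, training=False), axis=1)

    def _backward(self, grad_logits):
        g = self.fc2.backward(grad_logits)
        if self._drop_mask is not None:
            g = g * self._drop_mask
        g = g * self._fc1_mask
        g = self.fc1.backward(g)
        g = g.reshape(self._conv_out_shape)
        masks = list(self._relu_masks)
        for layer in reversed(self.layers):
            if layer == "relu":
                g = g * masks.pop()
            elif isinstance(layer, _BatchNorm1d):
                g = layer.backward(g)
            else:
                g = layer.backward(g)
        return g

    def _all_params(self):
        out = []
        for layer in self.layers:
            if layer != "relu":
                out.extend(layer.params())
        out.extend(self.fc1.params())
        out.extend(self.fc2.params())
        return out


def train_cnn(model, x, y_onehot, epochs, learning_rate, batch_size, rng):
    """Adam / cross-entropy training loop.

    Returns per-epoch (accuracy, loss) measured on the full training set in
    evaluation mode after each epoch.
    """
    n = x.shape[0]
    params = model._all_params()
    m_state = [np.zeros_like(p) for p, _, _ in params]
    v_state = [np.zeros_like(p) for p, _, _ in params]
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    step = 0
    curve_acc, curve_loss = [], []
    y_idx = y_onehot.argmax(axis=1)

    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            batch = order[start : start + batch_size]
            logits = model._forward(x[batch], training=True)
            probs = softmax(logits, axis=1)
            grad = (probs - y_onehot[batch]) / len(batch)
            model._backward(grad)
            step += 1
            for i, (p, gname, owner) in enumerate(params):
                g = getattr(owner, gname)
                m_state[i] = beta1 * m_state[i] + (1 - beta1) * g
                v_state[i] = beta2 * v_state[i] + (1 - beta2) * g**2
                mhat = m_state[i] / (1 - beta1**step)
                vhat = v_state[i] / (1 - beta2**step)
                p -= learning_rate * mhat / (np.sqrt(vhat) + adam_eps)
        probs = model.predict_proba(x)
        loss = float(-np.mean(np.log(probs[np.arange(n), y_idx] + 1e-15)))
        acc = float(np.mean(probs.argmax(axis=1) == y_idx))
        curve_acc.append(acc)
        curve_loss.append(loss)
    return np.array(curve_acc), np.array(curve_loss)
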