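"""The two attention blocks: channel-residual attention perceptrons (CRA-MLP)
and position-enhanced self-attention (PESA).

CRA-MLP is a conv-norm-PReLU perceptron stack whose output is re-weighted by a
squeeze-excitation channel gate (reduction ratio 4, bias-free) and added back
to itself through a residual connection:

    omega  = sigmoid(W2 @ relu(W1 @ avgpool(FD)))        (channel weights)
    output = FD * omega + FD

PESA lifts the stage's centroid coordinates to the feature width, gates them
with a gram-matrix feature-attention layer, fuses them multiplicatively with
the incoming features, and runs offset-style self-attention whose weights are
softmax-normalized along the query axis and then l1-renormalized along the
key axis (so every row of A is stochastic). The attended output enters a
conv-BN-ReLU branch as an offset from the fused features, closed by a
residual connection:

    F'  = Po * Fi
    E   = (Wq F')^T (Wk F');  a = softmax_queries(E);  A = a / sum_keys(a)
    Fo  = CBR(A V - F') + F'
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .nn import BatchNorm, Linear, Module, PReLU, PointwiseConv, Sequential

__all__ = ["ChannelAttention", "CRAMLP", "PlainMLP", "PositionEnhance", "PESA"]


class ChannelAttention(Module):
    """Squeeze-excitation channel gate; returns weights in (0, 1) per channel."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 4):
        super().__init__()
        if channels % reduction:
            raise ValueError(f"channels={channels} not divisible by reduction={reduction}")
        self.channels = channels
        self.fc1 = Linear(channels, channels // reduction, rng, bias=False)
        self.fc2 = Linear(channels // reduction, channels, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, C, ...) -> omega: (B, C)."""
        b = x.shape[0]
        pooled = x.reshape(b, self.channels, -1).mean(axis=2)  # global average pool
        return self.fc2(self.fc1(pooled).relu()).sigmoid()


class CRAMLP(Module):
    """Conv-norm-PReLU stack with channel attention and a residual add.

    `widths` are the successive layer outputs; the attention gate acts on the
    final feature map FD and the module returns FD * omega + FD.
    """

    def __init__(self, in_channels: int, widths: list[int],
                 rng: np.random.Generator, reduction: int = 4):
        super().__init__()
        self.out_channels = widths[-1]
        layers = []
        prev = in_channels
        for w in widths:
            layers += [PointwiseConv(prev, w, rng), BatchNorm(w), PReLU(w)]
            prev = w
        self.stack = Sequential(*layers)
        self.se = ChannelAttention(widths[-1], rng, reduction)

    def forward(self, x: Tensor) -> Tensor:
        fd = self.stack(x)
        omega = self.se(fd)  # (B, C)
        shape = (fd.shape[0], self.out_channels) + (1,) * (fd.ndim - 2)
        return fd * omega.reshape(shape) + fd


class PlainMLP(Module):
    """Baseline conv-norm-ReLU perceptron stack (attention-free ablation)."""

    def __init__(self, in_channels: int, widths: list[int], rng: np.random.Generator):
        super().__init__()
        self.out_channels = widths[-1]
        layers = []
        prev = in_channels
        for w in widths:
            layers += [PointwiseConv(prev, w, rng), BatchNorm(w)]
            prev = w
        self.layers = Sequential(*layers)
        # interleave ReLU manually to keep layer naming stable
        self._widths = widths

    def forward(self, x: Tensor) -> Tensor:
        for i in range(0, len(self.layers.layers), 2):
            x = self.layers.layers[i](x)
            x = self.layers.layers[i + 1](x)
            x = x.relu()
        return x


def make_mlp(in_channels: int, widths: list[int], rng: np.random.Generator,
             cra: bool, reduction: int = 4) -> Module:
    return CRAMLP(in_channels, widths, rng, reduction) if cra \
        else PlainMLP(in_channels, widths, rng)


class PositionEnhance(Module):
    """Lift 3D centroid coordinates to `channels` and gate them.

    Pi = relu(BN(conv(P))); the gate is sigmoid(W . rowsum(Pi Pi^T / M)) and
    Po = Pi * gate. With ``gate="none"`` the lift is returned ungated. The
    gram matrix is averaged over points to keep the gate pre-activation at
    unit scale regardless of the stage's point count. All linear maps are
    bias-free so that zero coordinates map to an exactly zero Po.
    """

    def __init__(self, channels: int, rng: np.random.Generator, gate: str = "gram"):
        super().__init__()
        if gate not in ("gram", "none"):
            raise ValueError("gate must be 'gram' or 'none'")
        self.channels = channels
        self.gate = gate
        self.conv = PointwiseConv(3, channels, rng, bias=False)
        self.bn = BatchNorm(channels)
        self.gate_fc = Linear(channels, channels, rng, bias=False)

    def forward(self, p: Tensor) -> Tensor:
        """p: (B, 3, M) -> Po: (B, C, M)."""
        pi = self.bn(self.conv(p)).relu()
        if self.gate == "none":
            return pi
        m = pi.shape[2]
        gram = (pi @ pi.swapaxes(1, 2)) * (1.0 / m)  # (B, C, C)
        summed = gram.sum(axis=1)                    # rows collapsed: (B, C)
        g = self.gate_fc(summed).sigmoid()           # (B, C) in (0, 1)
        return pi * g.reshape(pi.shape[0], self.channels, 1)


class PESA(Module):
    """Position-enhanced offset self-attention over one stage's points."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 4, gate: str = "gram"):
        super().__init__()
        self.channels = channels
        self.pos = PositionEnhance(channels, rng, gate=gate)
        self.wq = PointwiseConv(channels, channels // reduction, rng, bias=False)
        self.wk = PointwiseConv(channels, channels // reduction, rng, bias=False)
        self.wv = PointwiseConv(channels, channels, rng, bias=False)
        self.cbr_conv = PointwiseConv(channels, channels, rng)
        self.cbr_bn = BatchNorm(channels)

    def attention_matrix(self, fused: Tensor) -> Tensor:
        """Row-stochastic attention A from the fused features F'."""
        q = self.wq(fused)  # (B, C/4, N)
        k = self.wk(fused)
        e = q.swapaxes(1, 2) @ k          # (B, N, N), E_ij = q_i . k_j
        a = e.softmax(axis=1)             # softmax along the query axis
        denom = a.sum(axis=2, keepdims=True) + 1e-9
        return a / denom                  # l1 renormalization along keys

    def forward(self, fi: Tensor, p: Tensor) -> Tensor:
        """fi: (B, C, N) features, p: (B, 3, N) coordinates -> (B, C, N)."""
        if fi.shape[2] != p.shape[2]:
            raise ValueError(
                f"feature/position point counts differ: {fi.shape[2]} vs {p.shape[2]}")
        po = self.pos(p)
        fused = po * fi
        attn = self.attention_matrix(fused)          # (B, N, N)
        v = self.wv(fused)                           # (B, C, N)
        fsa = v @ attn.swapaxes(1, 2)                # Fsa_i = sum_j A_ij v_j
        offset = self.cbr_bn(self.cbr_conv(fsa - fused)).relu()
        return offset + fused
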