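"""Building blocks of the segmentation network.

Three units are composed into the encoder-decoder:

* :class:`RFU` — the plain conv3x3 -> batch-norm -> ReLU feature unit used in
  place of pretrained residual blocks throughout the encoder.
* :class:`SEPP` — the squeeze-and-excitation pyramid-pooling bottleneck: four
  parallel branches (one 1x1 branch and three dilated 3x3 branches with
  channel gating) concatenated along channels.
* :class:`SCAFusion` — the self- and channel-attention skip connection: the
  high-level map is channel-reconciled, passed through non-local
  self-attention, globally pooled into a per-channel gate that multiplies the
  low-level skip features, and summed with the bilinearly upsampled
  high-level map.

All blocks are shape-checked and reject non-finite inputs.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


def _check_finite(x: Tensor, where: str):
    if not np.all(np.isfinite(x.data)):
        raise ValueError(f"non-finite values in input to {where}")


class RFU(nn.Module):
    """ReLU feature unit: ReLU(BN(Conv3x3(x))), spatial size preserved."""

    def __init__(self, in_channels: int, out_channels: int, rng):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, out_channels, 3, rng)
        self.bn = nn.BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        _check_finite(x, "RFU")
        return ad.relu(self.bn(self.conv(x)))


class SelfAttention2d(nn.Module):
    """Non-local self-attention over spatial positions.

    Queries/keys are 1x1-projected to ``channels // reduction`` dimensions;
    the N x N affinity matrix (N = H*W) is row-softmaxed so that each output
    position carries a convex combination of value projections, and the
    aggregated map is element-wise multiplied with the input features.

    Attention cost is O(N^2).  Inputs with N above ``budget`` are rejected
    unless ``subsample`` is set, in which case the input is 2x average-pooled
    (repeatedly) until it fits.

    The value projection is zero-initialized, so an untrained block is the
    identity in its effect (mu = 0): attention strength is learned rather
    than injected at random scale, which keeps early activations bounded.
    """

    def __init__(self, channels: int, rng, reduction: int = 8,
                 budget: int = 4096, subsample: bool = False):
        super().__init__()
        inner = max(1, channels // reduction)
        self.query = nn.Conv2d(channels, inner, 1, rng, bias=False, gain=1.0)
        self.key = nn.Conv2d(channels, inner, 1, rng, bias=False, gain=1.0)
        self.value = nn.Conv2d(channels, channels, 1, rng, bias=False)
        self.value.weight.data[:] = 0.0
        self.budget = budget
        self.subsample = subsample

    def forward(self, x: Tensor, return_attention: bool = False):
        _check_finite(x, "self-attention")
        while x.shape[2] * x.shape[3] > self.budget:
            if not self.subsample:
                raise ValueError(
                    f"attention over N={x.shape[2] * x.shape[3]} positions exceeds "
                    f"budget {self.budget}; enable spatial subsampling or raise the budget")
            x = ad.avgpool2x2(x)
        n, c, h, w = x.shape
        L = h * w
        f = self.query(x).reshape((n, -1, L))           # (N, C', L)
        g = self.key(x).reshape((n, -1, L))
        s = ad.matmul(ad.transpose(f, (0, 2, 1)), g)    # s[b, i, j] = f_i . g_j
        beta = ad.softmax(s, axis=-1)                   # rows sum to 1
        hval = self.value(x).reshape((n, c, L))
        agg = ad.matmul(hval, ad.transpose(beta, (0, 2, 1)))  # out_i = sum_j beta[i,j] h_j
        mu = ad.mul(agg.reshape((n, c, h, w)), x)
        if return_attention:
            return mu, beta
        return mu


class SEGate(nn.Module):
    """Squeeze-and-excitation channel gate: x * sigmoid(FC2(ReLU(FC1(avg x))))."""

    def __init__(self, channels: int, rng, reduction: int = 16):
        super().__init__()
        inner = max(1, channels // reduction)
        self.fc1 = nn.Linear(channels, inner, rng)
        self.fc2 = nn.Linear(inner, channels, rng)

    def gate(self, x: Tensor) -> Tensor:
        squeezed = nn.global_avg_pool(x)                 # (N, C)
        return ad.sigmoid(self.fc2(ad.relu(self.fc1(squeezed))))

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        return ad.mul(x, self.gate(x).reshape((n, c, 1, 1)))


class SEPPBranch(nn.Module):
    """One pyramid branch: (dilated) conv -> SE -> 1x1 conv + ReLU.

    The rate-1 slot is a plain 1x1 convolution without channel gating; the
    remaining slots are dilated 3x3 convolutions ('same' padding = dilation)
    with an SE gate.  ``se_order='se_conv'`` swaps gating before convolution.
    """

    def __init__(self, in_channels: int, out_channels: int, rate: int, rng,
                 se_ratio: int = 16, se_order: str = "conv_se"):
        super().__init__()
        if se_order not in ("conv_se", "se_conv"):
            raise ValueError(f"unknown se_order {se_order!r}")
        self.rate = rate
        self.se_order = se_order
        if rate == 1:
            self.conv = nn.Conv2d(in_channels, out_channels, 1, rng)
            self.se = None
        else:
            self.conv = nn.Conv2d(in_channels, out_channels, 3, rng, dilation=rate)
            self.se = SEGate(out_channels if se_order == "conv_se" else in_channels,
                             rng, reduction=se_ratio)
        self.project = nn.Conv2d(out_channels, out_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        if self.se is None:
            y = self.conv(x)
        elif self.se_order == "conv_se":
            y = self.se(self.conv(x))
        else:
            y = self.conv(self.se(x))
        return ad.relu(self.project(y))


class SEPP(nn.Module):
    """Squeeze-and-excitation pyramid pooling bottleneck.

    Four parallel branches at dilation rates ``rates`` (default 1, 6, 12, 12;
    the duplicate 12 is kept deliberately), concatenated along channels.
    Output channels = ``len(rates) * branch_channels``.
    """

    def __init__(self, in_channels: int, branch_channels: int, rng,
                 rates=(1, 6, 12, 12), se_ratio: int = 16, se_order: str = "conv_se"):
        super().__init__()
        self.rates = tuple(rates)
        self.branches = [
            SEPPBranch(in_channels, branch_channels, r, rng,
                       se_ratio=se_ratio, se_order=se_order)
            for r in self.rates
        ]
        self.out_channels = branch_channels * len(self.rates)

    def forward(self, x: Tensor) -> Tensor:
        _check_finite(x, "SEPP")
        return ad.concat([b(x) for b in self.branches], axis=1)


class SCAFusion(nn.Module):
    """Self- and channel-attention skip fusion of one decoder level.

    ``x_hig`` (deep, half resolution) is mapped to the skip's channel count by
    a 1x1 convolution, self-attended into mu, globally average-pooled into a
    per-channel vector X_c, and the output is

        y = X_c * x_low + bilinear_upsample(x_hig')

    With the attention value projection zeroed, mu = 0 and the output reduces
    exactly to the bilinear upsampling of the reconciled high-level map.
    """

    def __init__(self, low_channels: int, hig_channels: int, rng,
                 attention_budget: int = 4096, reduction: int = 8):
        super().__init__()
        self.reconcile = nn.Conv2d(hig_channels, low_channels, 1, rng, gain=1.0)
        self.attention = SelfAttention2d(low_channels, rng, reduction=reduction,
                                         budget=attention_budget, subsample=True)

    def forward(self, x_low: Tensor, x_hig: Tensor) -> Tensor:
        _check_finite(x_low, "SCA (low)")
        _check_finite(x_hig, "SCA (high)")
        if (x_low.shape[2] != 2 * x_hig.shape[2]
                or x_low.shape[3] != 2 * x_hig.shape[3]):
            raise ValueError(
                f"SCA expects the high-level map at half the skip resolution; "
                f"got low {x_low.shape[2:]} vs high {x_hig.shape[2:]}")
        xh = self.reconcile(x_hig)
        mu = self.attention(xh)
        n, c = mu.shape[0], mu.shape[1]
        xc = nn.global_avg_pool(mu).reshape((n, c, 1, 1))
        gated = ad.mul(xc, x_low)
        upsampled = ad.upsample_bilinear(xh, (x_low.shape[2], x_low.shape[3]))
        return ad.add(gated, upsampled)
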