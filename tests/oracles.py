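"""Independent brute-force oracles used by the test suite.

Everything here is written as plain double loops / scalar arithmetic on
numpy arrays, deliberately independent of the package's vectorized
implementations.
"""

import numpy as np


def self_attention_oracle(x, wf, wg, wh):
    """Explicit O(N^2) non-local attention on one (C,H,W) map.

    wf, wg: (C', C); wh: (C, C) channel maps (the 1x1 convolutions).
    Returns (mu, beta) with beta row-stochastic: beta[i, j] is the weight
    position i places on position j.
    """
    c, h, w = x.shape
    n = h * w
    xs = x.reshape(c, n)
    f = wf @ xs
    g = wg @ xs
    hv = wh @ xs
    s = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s[i, j] = float(f[:, i] @ g[:, j])
    beta = np.zeros_like(s)
    for i in range(n):
        e = np.exp(s[i] - s[i].max())
        beta[i] = e / e.sum()
    agg = np.zeros((c, n))
    for i in range(n):
        for j in range(n):
            agg[:, i] += beta[i, j] * hv[:, j]
    mu = agg.reshape(c, h, w) * x
    return mu, beta


def bilinear_upsample_oracle(x, out_h, out_w):
    """Scalar-loop bilinear resize of (C,H,W) with half-pixel centers and
    edge clamping."""
    c, h, w = x.shape
    out = np.zeros((c, out_h, out_w))
    for i in range(out_h):
        for j in range(out_w):
            sy = (i + 0.5) * h / out_h - 0.5
            sx = (j + 0.5) * w / out_w - 0.5
            y0, x0 = int(np.floor(sy)), int(np.floor(sx))
            ty, tx = sy - y0, sx - x0
            y0c, y1c = np.clip([y0, y0 + 1], 0, h - 1)
            x0c, x1c = np.clip([x0, x0 + 1], 0, w - 1)
            out[:, i, j] = ((1 - ty) * (1 - tx) * x[:, y0c, x0c]
                            + (1 - ty) * tx * x[:, y0c, x1c]
                            + ty * (1 - tx) * x[:, y1c, x0c]
                            + ty * tx * x[:, y1c, x1c])
    return out


def sca_fuse_oracle(x_low, x_hig, w_rec, b_rec, wf, wg, wh):
    """Straight-line scalar evaluation of the attention skip fusion."""
    c_low = x_low.shape[0]
    ch, hh, wh_sp = x_hig.shape
    # 1x1 channel reconciliation
    xh = (w_rec @ x_hig.reshape(ch, -1) + b_rec[:, None]).reshape(c_low, hh, wh_sp)
    mu, _ = self_attention_oracle(xh, wf, wg, wh)
    xc = mu.reshape(c_low, -1).mean(axis=1)
    gated = xc[:, None, None] * x_low
    up = bilinear_upsample_oracle(xh, x_low.shape[1], x_low.shape[2])
    return gated + up


def confusion_oracle(pred, truth):
    """Pixel-loop confusion counts."""
    tp = fp = tn = fn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def auc_pairwise_oracle(prob, truth):
    """Exhaustive positive-negative pair comparison, ties count 1/2."""
    prob = prob.ravel()
    truth = truth.ravel().astype(bool)
    pos = prob[truth]
    neg = prob[~truth]
    if len(pos) == 0 or len(neg) == 0:
        return None
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def conv2d_oracle(x, kernel, dilation=1):
    """Scalar-loop 'same' stride-1 dilated cross-correlation of one channel
    pair; x: (H,W), kernel: (k,k)."""
    h, w = x.shape
    k = kernel.shape[0]
    pad = dilation * (k - 1) // 2
    xp = np.pad(x, pad)
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(k):
                for b in range(k):
                    acc += kernel[a, b] * xp[i + a * dilation, j + b * dilation]
            out[i, j] = acc
    return out
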