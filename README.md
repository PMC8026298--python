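# vesselseg

Multiscale structure-preserving vessel segmentation for 2-D grayscale
medical images, built around self- and channel-attention skip connections.

Blood vessels in CTA slices and retinal photographs span widths from one or
two pixels to fifteen or more, and ordinary encoder-decoder segmenters tend
to drop the thinnest branches. `vesselseg` implements an encoder-decoder
network whose skip connections are **SCA** (self- and channel-attention)
fusions and whose bottleneck is **SEPP** (squeeze-and-excitation pyramid
pooling), together with everything needed to train and evaluate it without
any external dataset: a synthetic vessel-phantom generator with exact
ground truth, the training recipe (weighted cross-entropy, Adam, poly
learning-rate decay), segmentation metrics (DSC, MIoU, Sen, Acc, AUC), and
a connected-component post-filter.

## The model

* **Encoder** — ReLU feature units `ReLU(BN(Conv3x3))` (two per stage),
  with 2x2 max pooling between stages; stage *k* has `c·2^k` channels.
* **Bottleneck (SEPP)** — four parallel branches at dilation rates
  1/6/12/12; the dilated branches carry squeeze-and-excitation channel
  gates `sigmoid(FC2(ReLU(FC1(aver x))))`; concatenation is reduced back by
  `BN(Conv1x1)`.
* **Decoder (SCA)** — at each level, with `β` the row-softmax non-local
  affinity, `μ_i = (Σ_j β_{ij} W_H x_j) ⊙ x_i` the attended map of the
  (channel-reconciled) high-level features, the fused output is

      y = aver(μ) ⊙ X_low + upsample(X_hig),

  i.e. a per-channel global gate on the encoder skip plus a bilinear
  upsampling of the deep features; a final 1x1 convolution and softmax
  yield the vessel probability map.

The numerical core (convolutions, batch norm, attention, Adam, reverse-mode
differentiation) is implemented on numpy in `vesselseg.autodiff` /
`vesselseg.nn` and verified against finite differences and brute-force
oracles in the test suite. See `docs/methods.md` for assumptions,
parameter choices, and limitations.

## Worked example

Generate phantoms, train a small network, and evaluate — all from Python:

```python
from vesselseg import phantoms, network, training, metrics

cfg = phantoms.PhantomConfig()                  # 64x64, widths 1-8 px, noise 0.05
train_set = phantoms.generate_dataset(cfg, 200, seed=7)
test_set = phantoms.generate_dataset(cfg, 50, seed=8)

net = network.build_network(network.NetworkConfig(depth=3, base_channels=16), seed=7)
net, log = training.train(net, train_set,
                          training.TrainConfig(max_epochs=20, batch_size=8, seed=7))

pairs = [(network.forward(net, s.image).probabilities, s.mask) for s in test_set]
report = metrics.evaluate_set(pairs, threshold=0.5)
print(f"DSC {100*report.dsc:.2f}%  MIoU {100*report.miou:.2f}%  "
      f"Sen {100*report.sen:.2f}%  AUC {100*report.auc:.2f}%")
```

A run of this configuration (the package's built-in study, seed 7) prints:

```
DSC 98.91%  MIoU 98.80%  Sen 98.94%  AUC 99.98%
```

against a best global-intensity-threshold baseline of DSC 94.90% on the
same held-out phantoms — the attention network recovers the thin, tapering
branches that a single global threshold cannot separate from the bias
field and noise.

The same pipeline is available from the shell:

```sh
vesselseg generate --out data --n 200 --seed 7
vesselseg train --data data --out run --epochs 20 --depth 3 --base-channels 16
vesselseg predict --checkpoint run/checkpoint.npz --images data --out pred --postprocess
vesselseg evaluate --pred pred --truth data --out report.json
```

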