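"""Build the four-decoder network and compare it with the plain U-Net baseline.

The semi-Siamese U-Net shares one encoder among four independent decoders;
with n_outputs=1 the same builder yields a classical U-Net, so the extra cost
of the three additional decoders is exactly 3x one decoding path.
"""

import dataclasses

import numpy as np

from tangleseg import ModelConfig, build_model, count_parameters, decoder_parameters

cfg = ModelConfig()  # 256x256 input, filters 16/32/64/128/256, 5x5 kernels
net = build_model(cfg, init_seed=0)

print("channel schedule:", [cfg.filters_at(l) for l in range(1, cfg.depth + 1)])
print("total parameters:", count_parameters(net))
print("one decoding path:", decoder_parameters(net, 0))

baseline = build_model(dataclasses.replace(cfg, n_outputs=1), init_seed=0)
extra = count_parameters(net) - count_parameters(baseline)
print("plain U-Net baseline:", count_parameters(baseline),
      f"(4-decoder extra = {extra} = 3 x {decoder_parameters(baseline, 0)})")

outs = net.forward(np.zeros((1, 256, 256, 3), np.float32))
print(f"forward pass: {len(outs)} probability maps of shape {outs[0].shape[1:]}")
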