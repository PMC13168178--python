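"""Build the dual-stream network and extract 2048-wide deep features.

The network has a shallow stream (stride-1 stem, three residual
squeeze-excite blocks, CBAM) preserving fine detail and a deep stream
(stride-2 stem and blocks up to 1024 channels, CBAM) capturing context.
Stream outputs are globally pooled, concatenated and passed through a
2048-unit GeLU dense layer whose activations are the deep feature vector.

The full 299x299 configuration is used for the parameter count; feature
extraction below runs at a small input size so the example finishes in
seconds (the feature width is independent of input size).

Run:
    python examples/04_deep_features.py
"""

import numpy as np

from dermfeat.nn import (DSRSENet, NetConfig, count_parameters,
                         extract_features)
from dermfeat.synth import LesionSpec, generate_lesion
from dermfeat.preprocess import resize_image

full = DSRSENet(NetConfig(input_size=299, seed=0))
n = count_parameters(full)
print(f"pinned architecture: {n:,} trainable parameters ({n / 1e6:.2f} M)")

small = DSRSENet(NetConfig(input_size=32, seed=0))
images = []
for seed in range(4):
    img, _, _ = generate_lesion(LesionSpec(image_size=64, base_radius=18,
                                           seed=seed))
    images.append(resize_image(img, 32, 32))
feats = extract_features(small, np.stack(images))
print(f"deep features: {feats.shape} "
      f"(finite: {bool(np.all(np.isfinite(feats)))})")
print(f"first image, first 6 dims: {np.round(feats[0, :6], 4)}")
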