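"""Run the complete pipeline end to end on a synthetic dataset.

Stages: simulate lesions -> stratified 70/10/20 split -> handcrafted
features (asymmetry, serrated-border deltaA, colors, diameter, GLCM,
Fitzpatrick) -> SAMI selection of the handcrafted columns -> deep features
from the dual-stream network -> fusion (z-scored with train statistics) ->
OFS over the fused table -> MLP classification with standard metrics.

This example uses a small configuration (40 images, 32-px network input)
so it runs in about a minute on one CPU; the defaults in PipelineConfig
reflect the full study conditions.

Run:
    python examples/06_full_pipeline.py
"""

import json

from dermfeat.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_images=40, image_size=96, handcrafted_size=128,
                     net_input_size=32, ofs_iterations=8,
                     mlp_max_epochs=15, seed=0)
report = run_pipeline(cfg)

print(f"splits: {report['splits']}")
print(f"SAMI kept {report['sami']['chosen_k']} handcrafted columns: "
      f"{report['sami']['selected']}")
print(f"deep feature width: {report['network']['feature_width']}")
print(f"fused table: {report['fusion']['n_columns']} columns")
print(f"OFS kept k={report['ofs']['k']} "
      f"(alpha={report['ofs']['alpha']:.3f}, "
      f"beta={report['ofs']['beta']:.3f}, "
      f"gamma={report['ofs']['gamma']:.3f})")
print(f"test metrics: {json.dumps(report['metrics'], indent=2)}")
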