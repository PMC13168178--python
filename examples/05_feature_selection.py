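"""SAMI and OFS feature selection on a synthetic feature table.

SAMI (self-attention + mutual information) scores each feature by the norm
of its attention output weighted by its mutual information with the label,
then picks the best top-k by cross-validated MLP accuracy. OFS (optimized
feature selection) searches jointly over the relevance weights (alpha,
beta, gamma) and the number of kept features, updating the weights in
proportion to observed validation-accuracy changes.

Run:
    python examples/05_feature_selection.py
"""

import numpy as np
import pandas as pd

from dermfeat import selection
from dermfeat.classify import MLPConfig
from dermfeat.synth import TableSpec, generate_feature_table

fast = MLPConfig(max_epochs=10, patience=5, seed=0)

# -- SAMI: 3 informative + 4 noise columns ---------------------------------
X, y, mask = generate_feature_table(
    TableSpec(n_samples=400, n_informative=3, n_redundant=0, n_noise=4,
              seed=0))
scores = selection.sami_scores(X, y)
sel = selection.select_k_best(X, y, scores, [2, 3, 4, 5], mlp_config=fast)
print(f"SAMI scores: {np.round(scores, 3)}")
print(f"planted informative columns: {sorted(np.nonzero(mask)[0])}")
print(f"SAMI selected (k={sel.chosen_k}): {sorted(sel.selected)}")

# -- OFS on a wider table ---------------------------------------------------
X, y, mask = generate_feature_table(
    TableSpec(n_samples=500, n_informative=5, n_redundant=10, n_noise=35,
              seed=1))
df = pd.DataFrame(X, columns=[f"c{i}" for i in range(X.shape[1])])
idx = np.random.default_rng(0).permutation(len(y))
splits = {"train": idx[:350], "val": idx[350:400], "test": idx[400:]}
res = selection.ofs_search(df, y, splits, n_iter=20, seed=0, mlp_config=fast)
planted = {f"c{i}" for i in np.nonzero(mask)[0]}
print(f"\nOFS: alpha={res.alpha:.3f} beta={res.beta:.3f} "
      f"gamma={res.gamma:.3f} k={res.k}")
print(f"informative recovered: {len(planted & set(res.selected))}/5, "
      f"test accuracy {res.test_accuracy:.3f}")
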