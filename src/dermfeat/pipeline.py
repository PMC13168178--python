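"""End-to-end orchestration: preprocess → handcrafted → SAMI → deep
features → fuse → OFS → MLP → metrics.

The pipeline operates on in-memory (image, mask, label) samples, either
synthesized by :mod:`dermfeat.synth` or loaded from a manifest CSV, and
emits a JSON-serializable run report recording every stage's selections,
parameters and test metrics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import classify, handcrafted, preprocess, selection, synth
from .classify import MLPConfig
from .nn import (DSRSENet, NetConfig, TrainConfig, count_parameters,
                 extract_features, train as train_net)
from .preprocess import stage_timer

logger = logging.getLogger("dermfeat")


@dataclass
class PipelineConfig:
    # data source: manifest CSV path, or synthetic dataset when None
    manifest: str | None = None
    n_images: int = 120
    image_size: int = 128
    hair_count: int = 0
    # preprocessing
    handcrafted_size: int = 256
    apply_dull_razor: bool = False
    corrected_red: bool = False
    # network
    net_input_size: int = 299
    net_train_epochs: int = 0     # 0: seeded-initialization extractor
    net_seed: int = 0
    # selection
    sami_k_grid: tuple[int, ...] = (2, 4, 6, 8, 10)
    ofs_iterations: int = 50
    ofs_patience: int = 15
    # classifier used inside the selection loops and at the end
    mlp_max_epochs: int = 30
    mlp_patience: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg


def _load_samples(config: PipelineConfig):
    if config.manifest is None:
        pairs, labels, _ = synth.make_binary_dataset(
            config.n_images, seed=config.seed, image_size=config.image_size,
            hair_count=config.hair_count)
        return pairs, labels
    df = preprocess.read_manifest(config.manifest)
    pairs, labels = [], []
    for _, row in df.iterrows():
        img = preprocess.load_image(row["image"])
        msk = (preprocess.load_mask(row["mask"]) if isinstance(row["mask"], str)
               and row["mask"] else preprocess.naive_mask(img))
        pairs.append((img, msk))
        labels.append(1 if row["label"] == "malignant" else 0)
    return pairs, np.array(labels)


def _split_indices(labels: np.ndarray, seed: int) -> dict[str, np.ndarray]:
    df = pd.DataFrame({
        "image": [f"s{i}" for i in range(len(labels))],
        "mask": "",
        "label": np.where(labels == 1, "malignant", "benign"),
    })
    out = preprocess.split_dataset(df, seed=seed)
    return {name: np.nonzero((out["split"] == name).to_numpy())[0]
            for name in ("train", "val", "test")}


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Execute the full hybrid pipeline and return the run report."""
    cfg = config or PipelineConfig()
    report: dict = {"config": asdict(cfg)}

    with stage_timer("load"):
        pairs, labels = _load_samples(cfg)
    if len(pairs) < 10:
        raise RuntimeError("pipeline needs at least 10 samples")

    with stage_timer("preprocess"):
        prepped = []
        for img, msk in pairs:
            img = preprocess.resize_image(img, cfg.handcrafted_size,
                                          cfg.handcrafted_size)
            msk = preprocess.resize_mask(msk, cfg.handcrafted_size,
                                         cfg.handcrafted_size)
            if cfg.apply_dull_razor:
                img = preprocess.dull_razor(img)
            prepped.append((img, msk))

    splits = _split_indices(labels, cfg.seed)
    report["splits"] = {k: int(len(v)) for k, v in splits.items()}

    with stage_timer("handcrafted"):
        rows = [handcrafted.handcrafted_vector(img, msk,
                                               corrected_red=cfg.corrected_red)
                for img, msk in prepped]
        flagged = [i for i, r in enumerate(rows) if r["flagged"]]
        hand = pd.DataFrame(
            [{c: r[c] for c in handcrafted.HANDCRAFTED_COLUMNS}
             for r in rows])
        # impute rare extractor failures with the training-split median
        med = hand.iloc[splits["train"]].median()
        hand = hand.fillna(med)
    report["handcrafted"] = {"columns": list(hand.columns),
                             "n_flagged": len(flagged)}

    with stage_timer("sami"):
        tr = splits["train"]
        scores = selection.sami_scores(hand.to_numpy()[tr], labels[tr])
        k_grid = [k for k in cfg.sami_k_grid if 2 <= k <= hand.shape[1]]
        mlp_cfg = MLPConfig(max_epochs=cfg.mlp_max_epochs,
                            patience=cfg.mlp_patience, seed=cfg.seed)
        sami = selection.select_k_best(
            hand.to_numpy()[tr], labels[tr], scores, k_grid, seed=cfg.seed,
            mlp_config=mlp_cfg, feature_names=list(hand.columns))
    report["sami"] = {"chosen_k": sami.chosen_k, "selected": sami.selected,
                      "cv_accuracies": {int(k): float(v) for k, v
                                        in sami.cv_accuracies.items()}}

    with stage_timer("deep_features"):
        net_cfg = NetConfig(input_size=cfg.net_input_size, seed=cfg.net_seed)
        model = DSRSENet(net_cfg)
        images = np.stack([
            preprocess.resize_image(img, cfg.net_input_size,
                                    cfg.net_input_size)
            for img, _ in pairs])
        if cfg.net_train_epochs > 0:
            tr, va = splits["train"], splits["val"]
            train_net(model, images[tr], labels[tr], images[va], labels[va],
                      TrainConfig(max_epochs=cfg.net_train_epochs,
                                  seed=cfg.seed))
        deep = extract_features(model, images)
    deep_df = pd.DataFrame(deep,
                           columns=[f"f{i:04d}" for i in range(deep.shape[1])])
    report["network"] = {"parameters": count_parameters(model),
                         "feature_width": int(deep.shape[1]),
                         "trained_epochs": cfg.net_train_epochs}

    with stage_timer("fuse"):
        train_mask = np.zeros(len(labels), dtype=bool)
        train_mask[splits["train"]] = True
        fused = selection.fuse(hand[sami.selected], deep_df,
                               train_mask=train_mask)
    report["fusion"] = {"n_columns": int(fused.data.shape[1])}

    with stage_timer("ofs"):
        ofs = selection.ofs_search(fused.data, labels, splits,
                                   n_iter=cfg.ofs_iterations,
                                   patience=cfg.ofs_patience, seed=cfg.seed,
                                   mlp_config=mlp_cfg)
    report["ofs"] = {"alpha": ofs.alpha, "beta": ofs.beta,
                     "gamma": ofs.gamma, "k": ofs.k,
                     "selected": list(ofs.selected),
                     "val_accuracy": ofs.val_accuracy,
                     "iterations_run": len(ofs.history)}

    with stage_timer("final_classifier"):
        X = fused.data.to_numpy()
        cols = [fused.data.columns.get_loc(c) for c in ofs.selected]
        tr, te = splits["train"], splits["test"]
        model = classify.train_mlp(X[tr][:, cols], labels[tr], mlp_cfg)
        pred, probs = classify.predict(model, X[te][:, cols])
        m = classify.metrics(labels[te], pred, probs)
    report["metrics"] = m.as_dict()
    report["test_accuracy"] = m.accuracy
    return report


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
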