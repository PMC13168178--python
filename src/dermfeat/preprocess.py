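"""Image loading, resizing, dull-razor hair removal, dataset splitting and
augmentation.

The dull-razor pipeline is the classical morphology-based hair remover:
grayscale → blackhat with a cross-shaped structuring element → fixed
threshold → inpainting of the flagged pixels. Dataset manifests are plain
CSV tables (``image,mask,label[,split]``).
"""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage as ndi
from skimage import color as skcolor
from skimage import morphology, restoration, transform
from skimage.filters import threshold_otsu
from sklearn.model_selection import train_test_split

logger = logging.getLogger("dermfeat")

LABELS = ("benign", "malignant")


@contextmanager
def stage_timer(name: str):
    t0 = time.perf_counter()
    yield
    logger.info("stage %-18s %.2f s", name, time.perf_counter() - t0)


# -- image IO --------------------------------------------------------------

def load_image(path) -> np.ndarray:
    """RGB image as float32 in [0, 1]."""
    img = np.asarray(Image.open(path).convert("RGB"), dtype=np.float32)
    return img / 255.0


def load_mask(path) -> np.ndarray:
    """Binary mask as uint8 in {0, 1} (PNG stored as 0/255)."""
    m = np.asarray(Image.open(path).convert("L"))
    return (m > 127).astype(np.uint8)


def save_image(path, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8)).save(path)


def save_mask(path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255).save(path)


# -- resizing --------------------------------------------------------------

def resize_image(image: np.ndarray, height: int, width: int) -> np.ndarray:
    """Bilinear resize to (height, width); identity sizes are passthrough."""
    if height <= 0 or width <= 0:
        raise ValueError("target size must be positive")
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.shape[0] == height and image.shape[1] == width:
        return image.copy()
    out = transform.resize(image, (height, width), order=1,
                           preserve_range=True, anti_aliasing=True)
    return out.astype(np.float32)


def resize_mask(mask: np.ndarray, height: int, width: int) -> np.ndarray:
    """Nearest-neighbor resize, re-binarized to {0, 1}."""
    if height <= 0 or width <= 0:
        raise ValueError("target size must be positive")
    mask = np.asarray(mask)
    if mask.shape[0] == height and mask.shape[1] == width:
        return (mask > 0).astype(np.uint8)
    out = transform.resize(mask.astype(float), (height, width), order=0,
                           preserve_range=True, anti_aliasing=False)
    return (out > 0.5).astype(np.uint8)


# -- dull razor ------------------------------------------------------------

def _cross_footprint(size: int = 17) -> np.ndarray:
    fp = np.zeros((size, size), dtype=bool)
    fp[size // 2, :] = True
    fp[:, size // 2] = True
    return fp


def dull_razor(image: np.ndarray, kernel_size: int = 17,
               threshold: int = 10) -> np.ndarray:
    """Remove hair-like dark curvilinear artifacts.

    Grayscale → morphological blackhat (cross structuring element) → fixed
    threshold on the 0-255 scale → inpaint the flagged pixels. A hairless
    image round-trips essentially unchanged (empty blackhat mask).
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("dull_razor expects an RGB image")
    gray = skcolor.rgb2gray(image) * 255.0
    blackhat = morphology.black_tophat(gray, footprint=_cross_footprint(kernel_size))
    hair = blackhat > threshold
    if not hair.any():
        return image.astype(np.float32, copy=True)
    # slight dilation so stroke edges are covered by the inpainting domain
    hair = morphology.dilation(hair, footprint=morphology.disk(1))
    out = restoration.inpaint_biharmonic(image.astype(np.float64), hair,
                                         channel_axis=-1)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def naive_mask(image: np.ndarray) -> np.ndarray:
    """Fallback lesion mask when no segmentation is available.

    Otsu threshold on grayscale (lesion assumed darker than skin), largest
    connected component, holes filled. This is a heuristic stand-in for a
    trained segmentation network and is flagged as such to callers.
    """
    gray = skcolor.rgb2gray(np.asarray(image))
    th = threshold_otsu(gray)
    fg = gray < th
    labeled, n = ndi.label(fg)
    if n == 0:
        return np.zeros(gray.shape, dtype=np.uint8)
    sizes = ndi.sum(fg, labeled, index=np.arange(1, n + 1))
    keep = labeled == (int(np.argmax(sizes)) + 1)
    return ndi.binary_fill_holes(keep).astype(np.uint8)


# -- manifests and splits --------------------------------------------------

def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"image", "mask", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def split_dataset(manifest: pd.DataFrame, seed: int = 0,
                  fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
                  ) -> pd.DataFrame:
    """Assign stratified train/val/test splits (default 70/10/20)."""
    df = manifest.copy()
    if len(df) < 10:
        raise ValueError("need at least 10 records to split")
    if df["image"].duplicated().any():
        raise ValueError("duplicate image paths in manifest")
    if df["label"].nunique() < 2:
        raise ValueError("both classes must be present to stratify")
    f_train, f_val, f_test = fractions
    idx = np.arange(len(df))
    # integer sizes so the fractions are hit exactly up to rounding
    n_test = int(round(f_test * len(df)))
    n_val = int(round(f_val * len(df)))
    n_classes = df["label"].nunique()
    rest, test = train_test_split(idx, test_size=n_test, random_state=seed,
                                  stratify=df["label"].values)
    # a val split smaller than the class count cannot be stratified
    val_strat = (df["label"].values[rest] if n_val >= n_classes else None)
    train, val = train_test_split(rest, test_size=n_val, random_state=seed,
                                  stratify=val_strat)
    split = np.empty(len(df), dtype=object)
    split[train], split[val], split[test] = "train", "val", "test"
    df["split"] = split
    return df


# -- augmentation ----------------------------------------------------------

@dataclass
class AugmentPolicy:
    p_rotation: float = 0.7
    p_zoom: float = 0.3
    p_flip: float = 0.3
    rotation_range: float = 45.0
    zoom_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def validate(self) -> None:
        for p in (self.p_rotation, self.p_zoom, self.p_flip):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def _zoom(arr: np.ndarray, scale: float, order: int) -> np.ndarray:
    """Center zoom preserving the frame size."""
    h, w = arr.shape[:2]
    out = transform.rescale(arr.astype(float), scale, order=order,
                            channel_axis=-1 if arr.ndim == 3 else None,
                            preserve_range=True, anti_aliasing=order > 0)
    oh, ow = out.shape[:2]
    if oh >= h:
        y0, x0 = (oh - h) // 2, (ow - w) // 2
        out = out[y0:y0 + h, x0:x0 + w]
    else:
        pad_y, pad_x = h - oh, w - ow
        pads = [(pad_y // 2, pad_y - pad_y // 2),
                (pad_x // 2, pad_x - pad_x // 2)]
        if arr.ndim == 3:
            pads.append((0, 0))
        out = np.pad(out, pads, mode="edge")
    return out


def transform_pair(image: np.ndarray, mask: np.ndarray, rotation: float,
                   zoom: float, flip: bool) -> tuple[np.ndarray, np.ndarray]:
    """Apply one geometric transform identically to an image and its mask."""
    img, msk = image, mask.astype(float)
    if flip:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rotation != 0.0:
        img = transform.rotate(img, rotation, order=1, mode="edge",
                               preserve_range=True)
        msk = transform.rotate(msk, rotation, order=0, mode="constant",
                               preserve_range=True)
    if zoom != 1.0:
        img = _zoom(img, zoom, order=1)
        msk = _zoom(msk, zoom, order=0)
    return img.astype(np.float32), (msk > 0.5).astype(np.uint8)


def augment_balance(samples: list[dict], policy: AugmentPolicy) -> list[dict]:
    """Up-sample the minority class with augmented copies until parity.

    ``samples`` are dicts with keys ``image``, ``mask``, ``label`` and
    optionally ``split`` (must be ``train`` when present — augmenting
    validation or test data is refused). Each copy independently applies
    rotation w.p. ``p_rotation``, zoom w.p. ``p_zoom`` and horizontal flip
    w.p. ``p_flip``; image and mask receive the same transform.
    """
    policy.validate()
    for s in samples:
        if s.get("split", "train") != "train":
            raise ValueError("augmentation is restricted to the train split")
    labels = np.array([s["label"] for s in samples])
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes to balance")
    rng = np.random.default_rng(policy.seed)
    out = list(samples)
    target = counts.max()
    for cls, cnt in zip(classes, counts):
        pool = [s for s in samples if s["label"] == cls]
        for _ in range(target - cnt):
            src = pool[int(rng.integers(len(pool)))]
            rot = (rng.uniform(-policy.rotation_range, policy.rotation_range)
                   if rng.random() < policy.p_rotation else 0.0)
            zoom = (rng.uniform(*policy.zoom_range)
                    if rng.random() < policy.p_zoom else 1.0)
            flip = bool(rng.random() < policy.p_flip)
            img, msk = transform_pair(src["image"], src["mask"],
                                      rot, zoom, flip)
            copy = dict(src)
            copy.update(image=img, mask=msk, augmented=True,
                        transforms={"rotation": rot, "zoom": zoom,
                                    "flip": flip})
            out.append(copy)
    return out
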