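"""Handcrafted ABCD + texture + Fitzpatrick features.

The 11-feature vector per lesion: asymmetry score, border-irregularity area
gap ΔA (from :mod:`dermfeat.border`), number of reference colors present,
diameter in pixels, Fitzpatrick skin-type ordinal, and six gray-level
co-occurrence (GLCM) statistics (contrast, dissimilarity, homogeneity,
energy, ASM, correlation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor

from . import border as border_mod

HANDCRAFTED_COLUMNS = (
    "asymmetry", "border_delta_area", "n_colors", "diameter_px",
    "fitzpatrick", "contrast", "dissimilarity", "homogeneity",
    "energy", "asm", "correlation",
)


# -- asymmetry -------------------------------------------------------------

@dataclass
class AsymmetryResult:
    mu_de: float                 # mean squared midpoint deviation, px^2
    per_orientation: np.ndarray  # deviation per sampled orientation
    is_asymmetric: bool


def _orientation_deviation(mask: np.ndarray) -> float | None:
    """Mean squared residual of horizontal-chord midpoints about their
    fitted symmetry axis, for the mask as currently oriented."""
    rows = np.nonzero(mask.any(axis=1))[0]
    mids, ys = [], []
    for r in rows:
        cols = np.nonzero(mask[r])[0]
        mids.append((cols[0] + cols[-1]) / 2.0)
        ys.append(r)
    if len(mids) < 3:
        return None
    ys = np.asarray(ys, dtype=float)
    mids = np.asarray(mids, dtype=float)
    # symmetry axis: midpoint position as a linear function of chord row
    C, D = np.polyfit(ys, mids, 1)
    resid = mids - (C * ys + D)
    return float(np.mean(resid ** 2))


def asymmetry(mask: np.ndarray, n_orientations: int = 9,
              threshold: float = 5.0) -> AsymmetryResult:
    """Chord-midpoint asymmetry score.

    For each orientation over [0°, 180°): rotate the mask, take the
    midpoints of chords parallel to the reference axis, fit the straight
    symmetry axis through them, and record the mean squared residual. The
    score is the mean over orientations; scores above ``threshold``
    (default 5, in px²) flag the lesion asymmetric.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty mask")
    devs = []
    for i in range(n_orientations):
        angle = 180.0 * i / n_orientations
        if angle == 0.0:
            rot = mask
        else:
            rot = ndi.rotate(mask.astype(np.uint8), angle, order=0,
                             reshape=True) > 0
        d = _orientation_deviation(rot)
        if d is None:
            warnings.warn(f"orientation {angle:.0f} deg has <3 chords; skipped")
            continue
        devs.append(d)
    per = np.array(devs)
    mu = float(per.mean())
    return AsymmetryResult(mu_de=mu, per_orientation=per,
                          is_asymmetric=mu > threshold)


# -- color -----------------------------------------------------------------

COLOR_NAMES = ("black", "red", "white", "blue-gray", "light-brown",
               "dark-brown")


def _color_masks(r, g, b, corrected_red: bool) -> dict[str, np.ndarray]:
    red_r = (r > 0.8) if corrected_red else (r < 0.8)
    return {
        "black": (r < 0.2) & (g < 0.2) & (b < 0.2),
        "red": red_r & (g < 0.2) & (b < 0.2),
        "white": (r > 0.8) & (g > 0.8) & (b > 0.8),
        "blue-gray": (r < 0.2) & (g > 0.32) & (g < 0.72)
                     & (b > 0.34) & (b < 0.74),
        "light-brown": (r > 0.6) & (r < 1.0) & (g > 0.32) & (g < 0.72)
                       & (b > 0.05) & (b < 0.45),
        "dark-brown": (r > 0.2) & (r < 0.6) & (g > 0.06) & (g < 0.46)
                      & (b > 0.0) & (b < 0.33),
    }


@dataclass
class ColorCounts:
    counts: dict[str, int]
    fractions: dict[str, float]
    n_colors_present: int


def color_features(image: np.ndarray, mask: np.ndarray,
                   presence_frac: float = 0.05,
                   corrected_red: bool = False) -> ColorCounts:
    """Count lesion pixels in each of the six reference-color boxes.

    Channels must be scaled to [0, 1]. A color is *present* when its pixel
    fraction of the lesion reaches ``presence_frac``. The printed red rule
    (R < 0.8) is kept by default; ``corrected_red`` flips it to R > 0.8
    (the direction consistent with red hues). Membership boxes may overlap,
    so one pixel can count toward several colors.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty lesion")
    if image.max() > 1.0 + 1e-6:
        raise ValueError("channels must be scaled to [0, 1]")
    r, g, b = (image[..., i][mask] for i in range(3))
    n = int(mask.sum())
    masks = _color_masks(r, g, b, corrected_red)
    counts = {k: int(v.sum()) for k, v in masks.items()}
    fractions = {k: c / n for k, c in counts.items()}
    present = sum(f >= presence_frac for f in fractions.values())
    return ColorCounts(counts=counts, fractions=fractions,
                       n_colors_present=present)


# -- diameter --------------------------------------------------------------

@dataclass
class DiameterResult:
    diameter: float
    endpoints: tuple[tuple[float, float], tuple[float, float]]


def diameter(contour: np.ndarray, centroid: tuple[float, float],
             tol_deg: float = 2.0) -> DiameterResult:
    """Longest distance between contour points ~180° apart about the centroid."""
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 8:
        raise ValueError("need at least 8 contour points")
    cx, cy = centroid
    ang = np.degrees(np.arctan2(pts[:, 1] - cy, pts[:, 0] - cx)) % 360.0
    diff = np.abs((ang[:, None] - ang[None, :] + 180.0) % 360.0 - 180.0)
    antipodal = np.abs(diff - 180.0) <= tol_deg
    if not antipodal.any():
        warnings.warn("no antipodal pair within 2 deg; widening to 5 deg")
        antipodal = np.abs(diff - 180.0) <= 5.0
        if not antipodal.any():
            raise ValueError("no antipodal contour pairs found")
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=2)
    d2[~antipodal] = -1.0
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    return DiameterResult(diameter=float(math.sqrt(d2[i, j])),
                          endpoints=(tuple(pts[i]), tuple(pts[j])))


# -- GLCM texture ----------------------------------------------------------

@dataclass
class GLCMFeatures:
    contrast: float
    dissimilarity: float
    homogeneity: float
    energy: float
    asm: float
    correlation: float


_GLCM_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def cooccurrence_matrix(levels_img: np.ndarray, mask: np.ndarray,
                        offset: tuple[int, int], n_levels: int) -> np.ndarray:
    """Symmetric normalized co-occurrence of quantized levels under a mask."""
    dy, dx = offset
    h, w = levels_img.shape
    y0, y1 = max(0, -dy), min(h, h - dy)
    x0, x1 = max(0, -dx), min(w, w - dx)
    a = levels_img[y0:y1, x0:x1]
    b = levels_img[y0 + dy:y1 + dy, x0 + dx:x1 + dx]
    valid = mask[y0:y1, x0:x1] & mask[y0 + dy:y1 + dy, x0 + dx:x1 + dx]
    P = np.zeros((n_levels, n_levels), dtype=float)
    np.add.at(P, (a[valid], b[valid]), 1.0)
    P = P + P.T  # symmetric
    total = P.sum()
    return P / total if total > 0 else P


def glcm_statistics(P: np.ndarray) -> GLCMFeatures:
    """The six texture statistics of one normalized co-occurrence matrix.

    Correlation uses the standard (x−μx)(y−μy)/σxσy form; for a constant
    region (σ = 0) it is defined as 1. ASM = ΣP² and energy = √ASM.
    """
    n = P.shape[0]
    x = np.arange(n, dtype=float)
    xx, yy = np.meshgrid(x, x, indexing="ij")
    contrast = float(np.sum((xx - yy) ** 2 * P))
    dissim = float(np.sum(np.abs(xx - yy) * P))
    homog = float(np.sum(P / (1.0 + np.abs(xx - yy))))
    asm = float(np.sum(P ** 2))
    energy = math.sqrt(asm)
    mu_x = float(np.sum(xx * P))
    mu_y = float(np.sum(yy * P))
    var_x = float(np.sum(P * (xx - mu_x) ** 2))
    var_y = float(np.sum(P * (yy - mu_y) ** 2))
    if var_x <= 1e-12 or var_y <= 1e-12:
        corr = 1.0
    else:
        corr = float(np.sum((xx - mu_x) * (yy - mu_y) * P)
                     / math.sqrt(var_x * var_y))
    return GLCMFeatures(contrast=contrast, dissimilarity=dissim,
                        homogeneity=homog, energy=energy, asm=asm,
                        correlation=corr)


def glcm_features(gray: np.ndarray, mask: np.ndarray, levels: int = 64,
                  distance: int = 1,
                  angles: tuple[int, ...] = (0, 45, 90, 135)) -> GLCMFeatures:
    """Masked GLCM statistics averaged over the four standard angles.

    ``gray`` is an 8-bit image (0-255); lesion pixels are quantized to
    ``levels`` gray levels before the co-occurrence counts.
    """
    gray = np.asarray(gray)
    mask = np.asarray(mask) > 0
    if gray.dtype != np.uint8:
        if gray.max() <= 1.0:
            gray = (gray * 255).round().astype(np.uint8)
        else:
            gray = np.clip(gray, 0, 255).round().astype(np.uint8)
    if mask.sum() < 2:
        raise ValueError("lesion must contain at least 2 pixels")
    q = (gray.astype(int) * levels) // 256
    per_angle = []
    for ang in angles:
        dy, dx = _GLCM_OFFSETS[ang]
        P = cooccurrence_matrix(q, mask, (dy * distance, dx * distance), levels)
        per_angle.append(glcm_statistics(P))
    def avg(attr):
        return float(np.mean([getattr(f, attr) for f in per_angle]))
    return GLCMFeatures(contrast=avg("contrast"),
                        dissimilarity=avg("dissimilarity"),
                        homogeneity=avg("homogeneity"), energy=avg("energy"),
                        asm=avg("asm"), correlation=avg("correlation"))


# -- Fitzpatrick skin type -------------------------------------------------

def extract_skin_patch(image: np.ndarray, mask: np.ndarray
                       ) -> tuple[int, int, int, int]:
    """Bounds (y0, y1, x0, x1) of the cleanest skin sub-block.

    The frame is split into quadrants, the quadrant with least lesion
    overlap is split again into four, and the sub-block with least overlap
    is returned. Fails when every candidate is more than half lesion.
    """
    mask = np.asarray(mask) > 0
    h, w = mask.shape

    def quads(y0, y1, x0, x1):
        ym, xm = (y0 + y1) // 2, (x0 + x1) // 2
        return [(y0, ym, x0, xm), (y0, ym, xm, x1),
                (ym, y1, x0, xm), (ym, y1, xm, x1)]

    def overlap(b):
        y0, y1, x0, x1 = b
        return mask[y0:y1, x0:x1].mean()

    q1 = min(quads(0, h, 0, w), key=overlap)
    best = min(quads(*q1), key=overlap)
    if overlap(best) > 0.5:
        raise ValueError("no clean skin region: all sub-blocks >50% lesion")
    return best


def ita_angle(mean_l: float, mean_b: float) -> float:
    """Individual typology angle arctan((L−50)/b)·180/π in degrees."""
    if abs(mean_b) < 1e-6:
        return 90.0 * float(np.sign(mean_l - 50.0))
    return math.degrees(math.atan((mean_l - 50.0) / mean_b))


def fitzpatrick_class(ita: float) -> int:
    """Fitzpatrick ordinal 1-6 from the ITA threshold table."""
    if not np.isfinite(ita):
        raise ValueError("ita must be finite")
    if ita >= 50:
        return 1
    if ita >= 25:
        return 2
    if ita >= 0:
        return 3
    if ita >= -25:
        return 4
    if ita >= -50:
        return 5
    return 6


@dataclass
class FitzpatrickResult:
    ita: float
    skin_type: int
    patch_bounds: tuple[int, int, int, int]
    mean_l: float
    mean_b: float


def fitzpatrick_features(image: np.ndarray, mask: np.ndarray
                         ) -> FitzpatrickResult:
    """ITA and Fitzpatrick type from the cleanest background-skin block."""
    bounds = extract_skin_patch(image, mask)
    y0, y1, x0, x1 = bounds
    patch = np.asarray(image, dtype=float)[y0:y1, x0:x1]
    lab = skcolor.rgb2lab(patch)
    mean_l = float(lab[..., 0].mean())
    mean_b = float(lab[..., 2].mean())
    ita = ita_angle(mean_l, mean_b)
    return FitzpatrickResult(ita=ita, skin_type=fitzpatrick_class(ita),
                             patch_bounds=bounds, mean_l=mean_l,
                             mean_b=mean_b)


# -- assembly --------------------------------------------------------------

def handcrafted_vector(image: np.ndarray, mask: np.ndarray,
                       corrected_red: bool = False) -> dict:
    """The full 11-feature record for one preprocessed lesion.

    Any extractor failure is recorded as a NaN entry with the reason in the
    ``errors`` field and the row flagged via ``flagged``.
    """
    record: dict = {c: float("nan") for c in HANDCRAFTED_COLUMNS}
    errors: dict[str, str] = {}

    def run(name, fn):
        try:
            return fn()
        except Exception as exc:  # record and continue
            errors[name] = str(exc)
            return None

    asym = run("asymmetry", lambda: asymmetry(mask))
    if asym is not None:
        record["asymmetry"] = asym.mu_de
        record["is_asymmetric"] = bool(asym.is_asymmetric)

    bf = run("border", lambda: border_mod.compute_border_features(mask))
    if bf is not None:
        record["border_delta_area"] = bf.delta_area

    col = run("color", lambda: color_features(image, mask,
                                              corrected_red=corrected_red))
    if col is not None:
        record["n_colors"] = float(col.n_colors_present)

    def _diam():
        contour = border_mod.extract_contour(mask)
        ell = border_mod.fit_ellipse(contour)
        return diameter(contour, ell.center)
    diam = run("diameter", _diam)
    if diam is not None:
        record["diameter_px"] = diam.diameter

    fitz = run("fitzpatrick", lambda: fitzpatrick_features(image, mask))
    if fitz is not None:
        record["fitzpatrick"] = float(fitz.skin_type)
        record["ita"] = fitz.ita

    def _glcm():
        gray = skcolor.rgb2gray(np.asarray(image, dtype=float))
        return glcm_features((gray * 255).round().astype(np.uint8), mask)
    tex = run("glcm", _glcm)
    if tex is not None:
        for k in ("contrast", "dissimilarity", "homogeneity", "energy",
                  "asm", "correlation"):
            record[k] = getattr(tex, k)

    record["flagged"] = bool(errors)
    record["errors"] = errors
    return record
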