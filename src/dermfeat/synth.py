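"""Synthetic dermoscopy fixtures with known ground truth.

Three generators make every downstream stage testable without external
datasets:

* :func:`generate_lesion` — a lesion image + binary mask whose boundary is a
  sinusoidally perturbed ellipse ``r(θ) = r_ellipse(θ)·(1 + A·sin(fθ + φ))``
  with optional one-sided radial scaling (asymmetry), a configurable subset
  of the six dermoscopy reference colors, a skin background of known
  individual typology angle (ITA), and dark curvilinear hair strokes.
* :func:`generate_feature_table` — a tabular set with planted informative,
  redundant and noise columns for the feature-selection stages.
* :func:`skin_patch_from_ita` — a bare skin patch whose mean ITA matches a
  requested angle (inverse use of the ITA definition in CIELab).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor

#: Representative RGB (in [0, 1]) for the six dermoscopy reference colors.
#: Each satisfies its color-rule inequality box with margin.
REFERENCE_COLORS: dict[str, tuple[float, float, float]] = {
    "black": (0.10, 0.10, 0.10),
    "red": (0.85, 0.12, 0.10),
    "white": (0.92, 0.92, 0.92),
    "blue-gray": (0.12, 0.52, 0.54),
    "light-brown": (0.78, 0.52, 0.25),
    "dark-brown": (0.40, 0.26, 0.15),
}


@dataclass
class LesionSpec:
    """Ground-truth description of one synthetic lesion."""

    image_size: int = 256
    base_radius: float = 60.0
    border_amplitude: float = 0.0
    border_frequency: int = 6
    asymmetry_ratio: float = 0.0
    color_set: tuple[str, ...] = ("dark-brown",)
    background_ita: float = 40.0
    hair_count: int = 0
    ellipse_aspect: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.base_radius <= 2:
            raise ValueError("degenerate spec: base_radius must exceed 2 px")
        if self.base_radius >= self.image_size / 2:
            raise ValueError("base_radius must be below image_size / 2")
        if self.border_amplitude < 0:
            raise ValueError("border_amplitude must be non-negative")
        if not 0 < self.ellipse_aspect <= 1:
            raise ValueError("ellipse_aspect must be in (0, 1]")
        unknown = set(self.color_set) - set(REFERENCE_COLORS)
        if unknown:
            raise ValueError(f"unknown reference colors: {sorted(unknown)}")
        if not -85 <= self.background_ita <= 85:
            raise ValueError("background_ita outside [-85, 85] degrees")


@dataclass
class TableSpec:
    """Planted tabular feature set for the selection stages."""

    n_samples: int = 500
    n_informative: int = 3
    n_redundant: int = 2
    n_noise: int = 5
    effect_size: float = 1.5
    redundancy_corr: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples must be at least 10")
        if self.n_informative < 0 or self.n_redundant < 0 or self.n_noise < 0:
            raise ValueError("column counts must be non-negative")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant columns require informative parents")
        if not 0 < self.redundancy_corr < 1:
            raise ValueError("redundancy_corr must be in (0, 1)")


def skin_patch_from_ita(ita: float, size: int = 64,
                        seed: int = 0) -> np.ndarray:
    """RGB skin patch (float in [0, 1]) with mean ITA ≈ ``ita`` degrees.

    ITA = arctan((L − 50)/b)·180/π in CIELab, so the patch is synthesized in
    Lab: the yellow-blue chroma b is fixed at a plausible skin value (shrunk
    when the implied lightness would leave gamut) and L = 50 + b·tan(ITA).
    """
    if not -85 <= ita <= 85:
        raise ValueError("ita outside the supported [-85, 85] degree range")
    t = np.tan(np.deg2rad(ita))
    b = 16.0
    # keep L within [8, 96] so the Lab->RGB conversion stays in gamut
    if abs(t) > 1e-9:
        b = min(b, 42.0 / abs(t))
        b = max(b, 1.0)
    L = 50.0 + b * t
    rng = np.random.default_rng(seed)
    lab = np.empty((size, size, 3), dtype=np.float64)
    lab[..., 0] = L + rng.normal(0, 1.0, (size, size))
    lab[..., 1] = 13.0 + rng.normal(0, 0.8, (size, size))  # mild redness
    lab[..., 2] = b + rng.normal(0, 0.8, (size, size))
    rgb = skcolor.lab2rgb(lab)
    return np.clip(rgb, 0.0, 1.0).astype(np.float32)


def _boundary_radius(theta: np.ndarray, spec: LesionSpec,
                     phase: float) -> np.ndarray:
    a = spec.base_radius
    b = spec.base_radius * spec.ellipse_aspect
    r_ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    r = r_ell * (1.0 + spec.border_amplitude
                 * np.sin(spec.border_frequency * theta + phase))
    # one-sided radial scaling: inflate the upper half only
    r = r * (1.0 + spec.asymmetry_ratio * np.maximum(np.sin(theta), 0.0))
    return r


def _draw_hairs(image: np.ndarray, n_hairs: int,
                rng: np.random.Generator) -> np.ndarray:
    """Overlay dark anti-aliased cubic Bezier strokes 1-3 px wide."""
    if n_hairs <= 0:
        return image
    size = image.shape[0]
    alpha = np.zeros((size, size), dtype=np.float32)
    yy, xx = np.mgrid[0:size, 0:size]
    t = np.linspace(0.0, 1.0, 4 * size)
    basis = np.stack([(1 - t) ** 3, 3 * t * (1 - t) ** 2,
                      3 * t ** 2 * (1 - t), t ** 3], axis=1)
    for _ in range(n_hairs):
        ctrl = rng.uniform(0, size, size=(4, 2))
        width = rng.uniform(1.0, 3.0)
        pts = basis @ ctrl
        half = width / 2.0
        r = int(np.ceil(half)) + 1
        for px, py in pts:
            xi, yi = int(round(px)), int(round(py))
            x0, x1 = max(xi - r, 0), min(xi + r + 1, size)
            y0, y1 = max(yi - r, 0), min(yi + r + 1, size)
            if x0 >= x1 or y0 >= y1:
                continue
            d = np.hypot(xx[y0:y1, x0:x1] - px, yy[y0:y1, x0:x1] - py)
            cov = np.clip(half + 0.5 - d, 0.0, 1.0)  # anti-aliased coverage
            np.maximum(alpha[y0:y1, x0:x1], cov, out=alpha[y0:y1, x0:x1])
    shade = rng.uniform(0.04, 0.12)
    return image * (1.0 - alpha[..., None]) + shade * alpha[..., None]


def generate_lesion(spec: LesionSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render one lesion.

    Returns ``(rgb, mask, record)``: float RGB image in [0, 1], a uint8 mask
    in {0, 1}, and a ground-truth record of every spec value plus derived
    geometry (center, semi-axes).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    cy = cx = (size - 1) / 2.0
    phase = rng.uniform(0.0, 2.0 * np.pi)

    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - cx, yy - cy
    theta = np.arctan2(dy, dx)
    rho = np.hypot(dx, dy)
    mask = (rho <= _boundary_radius(theta, spec, phase)).astype(np.uint8)

    image = skin_patch_from_ita(spec.background_ita, size,
                                seed=int(rng.integers(2 ** 31)))
    # angular color sectors inside the lesion
    colors = list(spec.color_set) or ["dark-brown"]
    sector_rot = rng.uniform(0.0, 2.0 * np.pi)
    sector = ((theta + sector_rot) % (2 * np.pi)) / (2 * np.pi) * len(colors)
    sector = np.minimum(sector.astype(int), len(colors) - 1)
    lesion = np.zeros_like(image)
    for i, name in enumerate(colors):
        ref = np.array(REFERENCE_COLORS[name], dtype=np.float32)
        lesion[sector == i] = ref
    lesion += rng.normal(0.0, 0.01, lesion.shape).astype(np.float32)
    inside = mask.astype(bool)
    image[inside] = np.clip(lesion[inside], 0.0, 1.0)

    image = _draw_hairs(image, spec.hair_count, rng)
    record = {
        "image_size": size, "base_radius": spec.base_radius,
        "border_amplitude": spec.border_amplitude,
        "border_frequency": spec.border_frequency,
        "asymmetry_ratio": spec.asymmetry_ratio,
        "color_set": tuple(colors), "n_colors": len(colors),
        "background_ita": spec.background_ita,
        "hair_count": spec.hair_count, "seed": spec.seed,
        "center": (cx, cy),
        "semi_axes": (spec.base_radius,
                      spec.base_radius * spec.ellipse_aspect),
        "diameter": 2.0 * spec.base_radius,
        "phase": phase,
    }
    return image.astype(np.float32), mask, record


def generate_feature_table(
        spec: TableSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted feature matrix with balanced binary labels.

    Returns ``(X, y, informative_mask)``. Informative columns differ between
    classes by ``effect_size`` standard deviations; each redundant column is
    a noisy copy of an informative parent targeting ``redundancy_corr``;
    noise columns are independent of the labels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    y = np.zeros(n, dtype=int)
    y[n // 2:] = 1
    rng.shuffle(y)

    cols: list[np.ndarray] = []
    informative: list[np.ndarray] = []
    for _ in range(spec.n_informative):
        x = rng.normal(0.0, 1.0, n) + spec.effect_size * y
        informative.append(x)
        cols.append(x)
    rho = spec.redundancy_corr
    for j in range(spec.n_redundant):
        parent = informative[j % max(spec.n_informative, 1)]
        sigma = parent.std() * np.sqrt(1.0 / rho ** 2 - 1.0)
        cols.append(parent + rng.normal(0.0, sigma, n))
    for _ in range(spec.n_noise):
        cols.append(rng.normal(0.0, 1.0, n))
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    mask = np.zeros(X.shape[1], dtype=bool)
    mask[:spec.n_informative] = True
    return X, y, mask


def make_binary_dataset(n: int, seed: int = 0, image_size: int = 128,
                        hair_count: int = 0) -> tuple[list, np.ndarray, list]:
    """Balanced benign/malignant lesion set separable by color and border.

    Benign lesions are smooth single-color (light-brown) ellipses; malignant
    lesions have serrated multi-color borders and one-sided asymmetry.
    Returns ``(pairs, labels, records)`` with ``pairs[i] = (image, mask)``.
    """
    rng = np.random.default_rng(seed)
    pairs, labels, records = [], [], []
    for i in range(n):
        malignant = i % 2
        sub = int(rng.integers(2 ** 31))
        if malignant:
            spec = LesionSpec(
                image_size=image_size,
                base_radius=image_size * rng.uniform(0.22, 0.3),
                border_amplitude=rng.uniform(0.2, 0.35),
                border_frequency=int(rng.integers(5, 9)),
                asymmetry_ratio=rng.uniform(0.2, 0.4),
                color_set=("black", "blue-gray", "dark-brown"),
                background_ita=rng.uniform(20, 55),
                hair_count=hair_count, seed=sub)
        else:
            spec = LesionSpec(
                image_size=image_size,
                base_radius=image_size * rng.uniform(0.18, 0.26),
                border_amplitude=rng.uniform(0.0, 0.03),
                asymmetry_ratio=0.0,
                color_set=("light-brown",),
                background_ita=rng.uniform(20, 55),
                hair_count=hair_count, seed=sub)
        image, mask, record = generate_lesion(spec)
        pairs.append((image, mask))
        labels.append(malignant)
        records.append(record)
    return pairs, np.array(labels), records
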