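"""Serrated-contour border-irregularity feature and auxiliary shape features.

The border-irregularity score contrasts the true lesion boundary with a
*serrated contour*: an ellipse is fitted to the boundary, the angular
positions where boundary and ellipse cross are collected, and radial rays
cast from the ellipse center at the mean crossing angle sample the boundary
into a polygon. The signed area gap ΔA = A_contour − A_serrated grows with
boundary waviness and is the "B" feature of the ABCD rule here. A k-means
step over ΔA plus classical shape descriptors (fractal dimension, Zernike
magnitudes, circularity, solidity, convexity, eccentricity) splits lesions
into regular/irregular border categories.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from skimage import measure
from sklearn.cluster import KMeans


class DegenerateGeometryError(ValueError):
    """Raised when the contour/ellipse configuration admits no serration."""


# -- contour extraction ----------------------------------------------------

# Moore neighborhood in clockwise screen order starting W: (dy, dx)
_DIRS = [(0, -1), (-1, -1), (-1, 0), (-1, 1),
         (0, 1), (1, 1), (1, 0), (1, -1)]


def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered boundary pixels of a single component (Moore tracing)."""
    pad = np.pad(mask.astype(bool), 1)
    ys, xs = np.nonzero(pad)
    start = (int(ys[0]), int(xs[0]))  # topmost-leftmost foreground pixel
    prev = (start[0], start[1] - 1)   # its W neighbor is background
    boundary = [start]
    current = start
    first_state = None
    max_steps = 4 * pad.size
    for _ in range(max_steps):
        di = _DIRS.index((prev[0] - current[0], prev[1] - current[1]))
        nxt = None
        for k in range(1, 9):
            d = _DIRS[(di + k) % 8]
            cand = (current[0] + d[0], current[1] + d[1])
            if pad[cand]:
                nxt = cand
                back = _DIRS[(di + k - 1) % 8]
                prev = (current[0] + back[0], current[1] + back[1])
                break
        if nxt is None:  # isolated pixel
            break
        current = nxt
        state = (current, prev)
        if first_state is None:
            first_state = state
        elif state == first_state:
            break
        if current != start or len(boundary) == 0:
            boundary.append(current)
        else:
            # re-entered start; loop closes here unless state differs
            boundary.append(current)
    # strip the duplicated closing start point(s)
    pts = []
    for p in boundary:
        if len(pts) >= 2 and p == boundary[0] and pts[-1] != boundary[0]:
            break
        pts.append(p)
    while len(pts) > 1 and pts[-1] == pts[0]:
        pts.pop()
    arr = np.array([(x - 1, y - 1) for (y, x) in pts], dtype=float)
    return arr


def extract_contour(mask: np.ndarray) -> np.ndarray:
    """External contour of the largest 8-connected component, CCW.

    Returns an (n, 2) float array of ordered (x=column, y=row) boundary
    pixel coordinates; counter-clockwise means positive shoelace area in
    (x, y) coordinates.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty mask")
    labeled, n = ndi.label(mask, structure=np.ones((3, 3)))
    if n > 1:
        sizes = ndi.sum(mask, labeled, index=np.arange(1, n + 1))
        mask = labeled == (int(np.argmax(sizes)) + 1)
    pts = _trace_boundary(mask)
    if len(pts) >= 3 and _signed_area(pts) < 0:
        pts = pts[::-1]
    return pts


# -- ellipse fitting -------------------------------------------------------

@dataclass
class EllipseFit:
    center: tuple[float, float]       # (x_c, y_c), pixels
    semi_axes: tuple[float, float]    # (a, b), a >= b, pixels
    rotation: float                   # degrees, angle of the major axis

    @property
    def eccentricity(self) -> float:
        a, b = self.semi_axes
        return math.sqrt(max(1.0 - (b / a) ** 2, 0.0))

    def radius_at(self, angle_deg: np.ndarray) -> np.ndarray:
        """Boundary radius along the given directions from the center."""
        a, b = self.semi_axes
        u = np.deg2rad(angle_deg) - math.radians(self.rotation)
        return a * b / np.sqrt((b * np.cos(u)) ** 2 + (a * np.sin(u)) ** 2)


def fit_ellipse(contour: np.ndarray) -> EllipseFit:
    """Direct least-squares ellipse fit to contour points."""
    pts = np.asarray(contour, dtype=float)
    if len(pts) < 5:
        raise ValueError("need at least 5 points to fit an ellipse")
    # collinearity check: rank of centered points
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) contour points")
    if hasattr(measure.EllipseModel, "from_estimate"):
        model = measure.EllipseModel.from_estimate(pts)
        if not model or not np.all(np.isfinite(
                [*model.center, *model.axis_lengths, model.theta])):
            raise ValueError("ellipse fit failed")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:  # older scikit-image
        model = measure.EllipseModel()
        if not model.estimate(pts) or not np.all(np.isfinite(model.params)):
            raise ValueError("ellipse fit failed")
        xc, yc, a, b, theta = model.params
    if a < b:
        a, b = b, a
        theta += math.pi / 2
    if a <= 0 or b <= 0:
        raise ValueError("degenerate ellipse fit")
    rot = math.degrees(theta) % 180.0
    return EllipseFit(center=(float(xc), float(yc)),
                      semi_axes=(float(a), float(b)), rotation=rot)


# -- intersections ---------------------------------------------------------

@dataclass
class IntersectionSet:
    points: np.ndarray        # (k, 2) representative point per contiguous run
    angles: np.ndarray        # degrees in [0, 360), one per run
    mean_angle: float         # circular mean, degrees in [0, 360)
    resultant: float          # circular mean resultant length in [0, 1]
    n_runs: int
    fraction_on_ellipse: float  # fraction of contour points within tol


def _runs_on_cycle(indices: np.ndarray, n: int) -> list[np.ndarray]:
    """Group sorted indices into contiguous runs on a cyclic index set."""
    if len(indices) == 0:
        return []
    indices = np.sort(indices)
    breaks = np.nonzero(np.diff(indices) > 1)[0]
    runs = np.split(indices, breaks + 1)
    # merge wrap-around run
    if len(runs) > 1 and indices[0] == 0 and indices[-1] == n - 1:
        runs[0] = np.concatenate([runs[-1], runs[0]])
        runs.pop()
    return runs


def intersections(contour: np.ndarray, ellipse: EllipseFit,
                  tol: float = 1.0) -> IntersectionSet:
    """Contour points lying on the fitted ellipse (within ``tol`` pixels).

    Contiguous runs of near-ellipse contour points are deduplicated to one
    representative point each; angles are measured at the ellipse center
    with the full-quadrant arctangent, mapped to [0, 360).
    """
    pts = np.asarray(contour, dtype=float)
    xc, yc = ellipse.center
    dx, dy = pts[:, 0] - xc, pts[:, 1] - yc
    ang = np.degrees(np.arctan2(dy, dx)) % 360.0
    rho = np.hypot(dx, dy)
    dist = np.abs(rho - ellipse.radius_at(ang))
    hits = np.nonzero(dist <= tol)[0]
    if len(hits) == 0:
        raise DegenerateGeometryError(
            "no contour/ellipse intersections within tolerance")
    runs = _runs_on_cycle(hits, len(pts))
    reps = np.array([run[len(run) // 2] for run in runs])
    rep_angles = ang[reps]
    rad = np.deg2rad(rep_angles)
    s, c = np.sin(rad).mean(), np.cos(rad).mean()
    resultant = float(np.hypot(s, c))
    mean_angle = float(np.degrees(np.arctan2(s, c)) % 360.0)
    return IntersectionSet(points=pts[reps], angles=rep_angles,
                           mean_angle=mean_angle, resultant=resultant,
                           n_runs=len(runs),
                           fraction_on_ellipse=len(hits) / len(pts))


# -- serrated contour ------------------------------------------------------

def _ray_polygon_crossings(origin: np.ndarray, direction: np.ndarray,
                           poly: np.ndarray) -> np.ndarray:
    """Distances t >= 0 where the ray origin + t*direction crosses polygon
    edges."""
    a = poly
    b = np.roll(poly, -1, axis=0)
    e = b - a
    # solve origin + t*d = a + u*e, 0<=u<=1, t>=0
    denom = direction[0] * (-e[:, 1]) - direction[1] * (-e[:, 0])
    rel = a - origin
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rel[:, 0] * (-e[:, 1]) - rel[:, 1] * (-e[:, 0])) / denom
        u = (direction[0] * rel[:, 1] - direction[1] * rel[:, 0]) / denom
    ok = np.isfinite(t) & np.isfinite(u) & (t >= 0) & (u >= -1e-9) & (u <= 1 + 1e-9)
    return t[ok]


def serrated_contour(contour: np.ndarray, centroid: tuple[float, float],
                     mean_angle: float, anchor: float = 0.0) -> np.ndarray:
    """Sample the boundary with radial rays stepped by ``mean_angle``.

    Rays leave ``centroid`` at angles {anchor, anchor + μΘ, anchor + 2μΘ,
    ...} degrees; each ray's farthest crossing with the contour polygon is
    kept, and the kept points joined in angular order form the closed
    serrated polygon. Anchoring the fan to a shape landmark (rather than
    the fixed 0° default) makes the sampled polygon co-rotate with the
    lesion.
    """
    if not 0.0 < mean_angle <= 120.0:
        raise ValueError("mean_angle must lie in (0, 120] degrees")
    poly = np.asarray(contour, dtype=float)
    origin = np.asarray(centroid, dtype=float)
    n_rays = int(math.floor(360.0 / mean_angle + 1e-9))
    if n_rays < 3:
        raise DegenerateGeometryError("fewer than 3 serration rays")
    points = []
    for k in range(n_rays):
        ang = math.radians(anchor + k * mean_angle)
        d = np.array([math.cos(ang), math.sin(ang)])
        ts = _ray_polygon_crossings(origin, d, poly)
        if len(ts) == 0:
            continue
        points.append(origin + ts.max() * d)
    if len(points) < 3:
        raise DegenerateGeometryError("serration produced fewer than 3 points")
    return np.array(points)


# -- areas -----------------------------------------------------------------

def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_area(points: np.ndarray) -> float:
    """Absolute polygon area by the shoelace formula."""
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValueError("polygon needs at least 3 points")
    return abs(_signed_area(points))


def area_difference(contour: np.ndarray, serrated: np.ndarray) -> float:
    """Signed area gap ΔA = A_contour − A_serrated."""
    return polygon_area(contour) - polygon_area(serrated)


# -- auxiliary shape features ---------------------------------------------

_ZERNIKE_ORDER = 8


def _zernike_radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        c = ((-1) ** s * math.factorial(n - s)
             / (math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)))
        out += c * rho ** (n - 2 * s)
    return out


def zernike_magnitudes(mask: np.ndarray, order: int = _ZERNIKE_ORDER
                       ) -> np.ndarray:
    """Zernike moment magnitudes of the binary shape up to radial order 8.

    The shape is mapped onto the unit disk circumscribing it (centered at
    the mask centroid) and treated as a unit-mass density, which makes the
    magnitudes translation- and scale-robust and rotation-invariant.
    """
    mask = np.asarray(mask) > 0
    ys, xs = np.nonzero(mask)
    cy, cx = ys.mean(), xs.mean()
    dx, dy = xs - cx, ys - cy
    r = np.hypot(dx, dy)
    rmax = r.max()
    if rmax == 0:
        rmax = 1.0
    rho = r / rmax
    theta = np.arctan2(dy, dx)
    w = 1.0 / mask.sum()
    mags = []
    for n in range(order + 1):
        for m in range(n % 2, n + 1, 2):
            rad = _zernike_radial(n, m, rho)
            re = (rad * np.cos(m * theta)).sum() * w
            im = (rad * np.sin(m * theta)).sum() * w
            mags.append((n + 1) / math.pi * math.hypot(re, im))
    return np.array(mags)


def fractal_dimension(mask: np.ndarray) -> float:
    """Box-counting dimension of the mask boundary."""
    mask = np.asarray(mask) > 0
    boundary = mask & ~ndi.binary_erosion(mask)
    h, w = boundary.shape
    max_box = min(h, w) // 4
    sizes = []
    s = 2
    while s <= max_box:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        raise ValueError("mask too small for box counting")
    counts = []
    for s in sizes:
        hh = (h + s - 1) // s * s
        ww = (w + s - 1) // s * s
        padded = np.zeros((hh, ww), dtype=bool)
        padded[:h, :w] = boundary
        blocks = padded.reshape(hh // s, s, ww // s, s).any(axis=(1, 3))
        counts.append(max(blocks.sum(), 1))
    slope = np.polyfit(np.log(1.0 / np.array(sizes, dtype=float)),
                       np.log(np.array(counts, dtype=float)), 1)[0]
    return float(slope)


@dataclass
class BorderFeatures:
    delta_area: float
    area_contour: float
    area_serrated: float
    mean_angle: float
    n_intersections: int
    fractal_dimension: float
    zernike: np.ndarray
    circularity: float
    solidity: float
    convexity: float
    eccentricity: float

    def as_row(self) -> dict:
        row = {
            "delta_area": self.delta_area,
            "area_contour": self.area_contour,
            "area_serrated": self.area_serrated,
            "fractal_dim": self.fractal_dimension,
            "circularity": self.circularity,
            "solidity": self.solidity,
            "convexity": self.convexity,
            "eccentricity": self.eccentricity,
        }
        for i, z in enumerate(self.zernike):
            row[f"zernike_{i}"] = float(z)
        return row


def aux_shape_features(mask: np.ndarray) -> dict:
    """Fractal dimension, Zernike magnitudes and classical descriptors."""
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("empty mask")
    if (mask[0].any() or mask[-1].any()
            or mask[:, 0].any() or mask[:, -1].any()):
        warnings.warn("mask touches the image border; contour is clipped")
    area = float(mask.sum())
    perim = float(measure.perimeter_crofton(mask, directions=4))
    contour = extract_contour(mask)
    hull = ConvexHull(contour)
    hull_pts = contour[hull.vertices]
    hull_perim = float(np.sum(np.linalg.norm(
        np.diff(np.vstack([hull_pts, hull_pts[:1]]), axis=0), axis=1)))
    hull_area = float(hull.volume)
    ell = fit_ellipse(contour)
    return {
        "fractal_dimension": fractal_dimension(mask),
        "zernike": zernike_magnitudes(mask),
        "circularity": min(4.0 * math.pi * area / perim ** 2, 1.05),
        "solidity": min(area / hull_area, 1.0),
        "convexity": hull_perim / perim,
        "eccentricity": ell.eccentricity,
    }


# -- full border feature pipeline -----------------------------------------

_NEAR_ELLIPSE_FRACTION = 0.9
_FALLBACK_STEP_DEG = 10.0


def _serration_step(inter: IntersectionSet) -> float:
    """Ray step angle from the intersection set.

    Uses the circular mean of the crossing angles when it is well defined
    and within the admissible (0, 120] degree range; otherwise (symmetric
    crossing patterns make the circular mean degenerate) falls back to the
    mean angular gap between crossing runs, clipped into (0, 120].
    """
    if inter.fraction_on_ellipse >= _NEAR_ELLIPSE_FRACTION:
        return _FALLBACK_STEP_DEG
    mu = inter.mean_angle
    if inter.resultant >= 0.1 and 0.0 < mu <= 120.0:
        return mu
    gap = 360.0 / max(inter.n_runs, 3)
    return float(np.clip(gap, 1.0, 120.0))


def compute_border_features(mask: np.ndarray, tol: float = 1.0
                            ) -> BorderFeatures:
    """Run the full serrated-contour pipeline on one lesion mask."""
    contour = extract_contour(mask)
    ell = fit_ellipse(contour)
    try:
        inter = intersections(contour, ell, tol=tol)
        step = _serration_step(inter)
        mean_angle = inter.mean_angle
        n_inter = inter.n_runs
        # anchor the ray fan at the crossing run farthest from the ellipse
        # center, a landmark that co-rotates with the lesion, so ΔA is
        # invariant to rigid motions of the mask
        rho = np.hypot(inter.points[:, 0] - ell.center[0],
                       inter.points[:, 1] - ell.center[1])
        anchor = float(inter.angles[int(np.argmax(rho))])
    except DegenerateGeometryError:
        step, mean_angle, n_inter = _FALLBACK_STEP_DEG, float("nan"), 0
        anchor = 0.0
    serr = serrated_contour(contour, ell.center, step, anchor=anchor)
    a_c = polygon_area(contour)
    a_s = polygon_area(serr)
    aux = aux_shape_features(mask)
    return BorderFeatures(
        delta_area=a_c - a_s, area_contour=a_c, area_serrated=a_s,
        mean_angle=mean_angle, n_intersections=n_inter,
        fractal_dimension=aux["fractal_dimension"], zernike=aux["zernike"],
        circularity=aux["circularity"], solidity=aux["solidity"],
        convexity=aux["convexity"], eccentricity=aux["eccentricity"])


def border_feature_table(masks: list[np.ndarray]) -> pd.DataFrame:
    rows = [compute_border_features(m).as_row() for m in masks]
    return pd.DataFrame(rows)


def classify_borders(features: pd.DataFrame, seed: int = 0) -> np.ndarray:
    """K-means (k=2) regular/irregular categorization of border feature rows.

    Columns are z-scored (zero-variance columns dropped with a warning);
    initialization is deterministic and order-invariant: the rows with the
    smallest and largest |ΔA| seed the two clusters. The cluster with larger
    mean |ΔA| is labeled ``irregular``.
    """
    if len(features) < 4:
        raise ValueError("need at least 4 lesions to cluster")
    X = features.to_numpy(dtype=float)
    std = X.std(axis=0)
    keep = std > 1e-12
    if not keep.any():
        raise ValueError("all feature rows identical; clustering degenerate")
    if not keep.all():
        warnings.warn("dropping zero-variance feature columns")
    Xz = (X[:, keep] - X[:, keep].mean(axis=0)) / std[keep]
    abs_da = np.abs(features["delta_area"].to_numpy(dtype=float))
    init = np.vstack([Xz[int(np.argmin(abs_da))], Xz[int(np.argmax(abs_da))]])
    km = KMeans(n_clusters=2, init=init, n_init=1, random_state=seed)
    assign = km.fit_predict(Xz)
    mean_da = [np.abs(abs_da[assign == c]).mean() if (assign == c).any()
               else -np.inf for c in (0, 1)]
    irregular = int(np.argmax(mean_da))
    return np.where(assign == irregular, "irregular", "regular")
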