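"""Functional typing of fascicles from neighborhood texture.

Per-pixel descriptor: along each of the four standard directions (0, 45,
90, 135 degrees) through the pixel, the intensity profile over the
(2r+1)-pixel neighborhood is differenced once (first-order gradient curve,
2r values) and twice (second-order curve, 2r-1 values).  Each curve is
summarized by three numbers — maximum amplitude, second-largest amplitude,
and average peak interval — per RGB channel, giving (4 + 4) curves x 3
descriptors x 3 channels = 72 features regardless of r.

Pixels are then grouped by rough K-means (k = 3): each point joins the
lower approximation of its nearest center unless a second center is almost
as close (distance ratio d2/d1 <= eps), in which case it joins the upper
approximations of both.  Cluster-to-type naming follows mean grayscale:
darkest cluster = sensory, lightest = motor, middle = mixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as _MplPath

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborhoodSpec",
    "GradientCurves",
    "RoughClustering",
    "BorderError",
    "directional_gradient_curves",
    "curve_descriptors",
    "feature_vector",
    "build_feature_matrix",
    "rough_kmeans",
    "init_centers",
    "label_fascicles",
    "FEATURE_DIM",
]

FEATURE_DIM = 72
DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))  # 0, 45, 90, 135 degrees as (drow, dcol)
TYPE_ORDER_BY_DARKNESS = ("sensory", "mixed", "motor")  # darkest -> lightest


class BorderError(ValueError):
    """The sampled pixel sits closer than r to the image border."""


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Neighborhood scale and sampling directions. ``side = 2r + 1``."""

    r: int = 11

    def __post_init__(self):
        if self.r < 5:
            raise ValueError("neighborhood scale r must be >= 5")

    @property
    def side(self) -> int:
        return 2 * self.r + 1


@dataclass
class GradientCurves:
    """First- and second-order curves per direction and channel.

    ``first_order[d][k]`` has length 2r; ``second_order[d][k]`` length 2r-1
    (d indexes the 4 directions, k the RGB channels).
    """

    first_order: list
    second_order: list
    r: int


def directional_gradient_curves(image: np.ndarray, pixel, spec: NeighborhoodSpec) -> GradientCurves:
    """Directional intensity-difference curves around one pixel.

    For each direction the (2r+1)-sample profile through ``pixel`` is taken
    with nearest-neighbor sampling (diagonal steps move one pixel in both
    axes); first-order curve = successive differences of the profile,
    second-order curve = successive differences of the first-order curve.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[..., None]
    H, W, C = img.shape
    m, n = int(pixel[0]), int(pixel[1])
    r = spec.r
    if not (r <= m < H - r and r <= n < W - r):
        raise BorderError(f"pixel {pixel} closer than r={r} to the border")
    offsets = np.arange(-r, r + 1)
    first, second = [], []
    for drow, dcol in DIRECTIONS:
        rows = m + offsets * drow
        cols = n + offsets * dcol
        profile = img[rows, cols, :]  # (2r+1, C)
        d1 = np.diff(profile, axis=0)  # (2r, C)
        d2 = np.diff(d1, axis=0)  # (2r-1, C)
        first.append([d1[:, k] for k in range(C)])
        second.append([d2[:, k] for k in range(C)])
    return GradientCurves(first_order=first, second_order=second, r=r)


def _peak_indices(mag: np.ndarray) -> np.ndarray:
    """Strict local maxima of a 1-D sequence; plateaus count once, at their
    leftmost index."""
    n = len(mag)
    peaks = []
    i = 1
    while i < n - 1:
        if mag[i] > mag[i - 1]:
            j = i
            while j + 1 < n and mag[j + 1] == mag[i]:
                j += 1
            if j < n - 1 and mag[j + 1] < mag[i]:
                peaks.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(peaks, dtype=int)


def curve_descriptors(curve: np.ndarray):
    """(max amplitude, second-largest amplitude, average peak interval).

    Amplitudes are the two largest values of ``|curve|``; peaks are strict
    local maxima of ``|curve|``; the interval is the mean index difference
    between successive peaks, 0 when there are fewer than two peaks.
    """
    c = np.abs(np.asarray(curve, dtype=float))
    if len(c) < 2:
        raise ValueError("curve must have at least 2 values")
    top2 = np.sort(c)[-2:]
    peaks = _peak_indices(c)
    interval = float(np.mean(np.diff(peaks))) if len(peaks) >= 2 else 0.0
    return float(top2[1]), float(top2[0]), interval


def feature_vector(image: np.ndarray, pixel, spec: NeighborhoodSpec | None = None) -> np.ndarray:
    """72-feature descriptor of one pixel neighborhood.

    Layout (fixed): channel-major — for each RGB channel k, for each of the
    8 curves (first-order at 0/45/90/135 degrees, then second-order in the
    same direction order), the triple (max amplitude, second amplitude,
    average peak interval).
    """
    spec = spec or NeighborhoodSpec()
    curves = directional_gradient_curves(image, pixel, spec)
    n_channels = len(curves.first_order[0])
    feats = []
    for k in range(n_channels):
        for bank in (curves.first_order, curves.second_order):
            for d in range(len(DIRECTIONS)):
                feats.extend(curve_descriptors(bank[d][k]))
    return np.asarray(feats, dtype=float)


def build_feature_matrix(image: np.ndarray, n_pixels: int,
                         spec: NeighborhoodSpec | None = None, seed: int = 0,
                         mask: np.ndarray | None = None):
    """Feature matrix of ``n_pixels`` uniformly sampled interior pixels.

    Parameters
    ----------
    mask
        Optional boolean raster restricting eligible pixels (e.g. fascicle
        foreground); border-adjacent pixels are always excluded.

    Returns
    -------
    (features, coords)
        ``features``: (n_pixels, 72); ``coords``: (n_pixels, 2) int, in
        sampling order.  Fixed seed gives an identical matrix.
    """
    spec = spec or NeighborhoodSpec()
    img = np.asarray(image)
    H, W = img.shape[:2]
    r = spec.r
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    if H <= spec.side or W <= spec.side:
        raise ValueError("image smaller than the neighborhood")
    eligible = np.zeros((H, W), dtype=bool)
    eligible[r : H - r, r : W - r] = True
    if mask is not None:
        eligible &= np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(eligible)
    if n_pixels > len(idx):
        raise ValueError(f"requested {n_pixels} pixels but only {len(idx)} eligible")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=n_pixels, replace=False)
    coords = np.stack(np.unravel_index(chosen, (H, W)), axis=1)
    feats = np.empty((n_pixels, FEATURE_DIM))
    for i, (rr, cc) in enumerate(coords):
        feats[i] = feature_vector(img, (rr, cc), spec)
    return feats, coords


# ---------------------------------------------------------------------------
# rough K-means

@dataclass
class RoughClustering:
    centers: np.ndarray  # (k, d)
    lower: np.ndarray  # (n,) cluster index, or -1 for ambiguous points
    upper: list  # per point: sorted tuple of cluster indices (len 1 or >= 2)
    w_lower: float
    w_upper: float
    eps: float
    iterations: int = 0

    @property
    def k(self) -> int:
        return len(self.centers)

    def lower_members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.lower == cluster)

    def upper_members(self, cluster: int) -> np.ndarray:
        return np.asarray([i for i, u in enumerate(self.upper) if cluster in u], dtype=int)

    def hard_assignment(self) -> np.ndarray:
        """Lower-set label where available, else the first (nearest) upper
        cluster — a defuzzified view for scoring and voting."""
        out = self.lower.copy()
        for i in np.flatnonzero(out < 0):
            out[i] = self.upper[i][0] if self.upper[i] else -1
        return out


def init_centers(features: np.ndarray, k: int, seed: int,
                 n_restarts: int = 5) -> np.ndarray:
    """Deterministic seeded k-means++ style initialization.

    Draws ``n_restarts`` candidate center sets (first center uniform, later
    centers sampled proportionally to squared distance from the chosen set)
    and returns the one with the lowest total point-to-nearest-center cost.
    """
    X = np.asarray(features, dtype=float)
    rng = np.random.default_rng(seed)
    best, best_cost = None, np.inf
    for _ in range(n_restarts):
        idx = [int(rng.integers(len(X)))]
        d2 = np.sum((X - X[idx[0]]) ** 2, axis=1)
        for _ in range(1, k):
            total = d2.sum()
            if total <= 0:
                nxt = int(rng.integers(len(X)))
            else:
                nxt = int(rng.choice(len(X), p=d2 / total))
            idx.append(nxt)
            d2 = np.minimum(d2, np.sum((X - X[nxt]) ** 2, axis=1))
        cost = d2.sum()
        if cost < best_cost:
            best, best_cost = idx, cost
    return X[best].copy()


def rough_kmeans(features: np.ndarray, k: int = 3, w_lower: float = 0.7,
                 w_upper: float = 0.3, eps: float = 1.15, seed: int = 0,
                 max_iter: int = 100, n_init: int = 4,
                 init: np.ndarray | None = None) -> RoughClustering:
    """Rough-set K-means with lower/upper approximations.

    A point whose second-nearest center is within relative distance
    ``d2/d1 <= eps`` of the nearest is *ambiguous*: it enters the upper
    approximations of both clusters and no lower set.  ``eps = 0`` (or any
    value < 1) therefore reduces exactly to classical k-means.  Centers are
    updated as ``w_lower * mean(lower) + w_upper * mean(upper \\ lower)``,
    falling back to the plain mean of whichever set is non-empty.  Pass
    ``eps="auto"`` to take eps from the data as the 0.9 quantile of the
    d2/d1 ratios at initialization, capped at 1.5.

    Unless an explicit ``init`` is given, ``n_init`` seeded runs are
    performed and the result with the lowest within-cluster squared distance
    (under hard assignment) is kept — all deterministic for a fixed seed.
    """
    X = np.asarray(features, dtype=float)
    if len(np.unique(X, axis=0)) < k:
        raise ValueError("k exceeds the number of distinct feature rows")
    if not (w_lower > 0 and w_upper > 0 and abs(w_lower + w_upper - 1.0) < 1e-9):
        raise ValueError("weights must be positive and sum to 1")
    if init is None and n_init > 1:
        best, best_cost = None, np.inf
        for j in range(n_init):
            res = rough_kmeans(X, k=k, w_lower=w_lower, w_upper=w_upper, eps=eps,
                               seed=seed + 1000 * j, max_iter=max_iter, n_init=1)
            d = np.sqrt(np.maximum(
                np.sum(X**2, axis=1)[:, None] + np.sum(res.centers**2, axis=1)[None, :]
                - 2 * X @ res.centers.T, 0.0))
            cost = float(np.sum(d.min(axis=1) ** 2))
            if cost < best_cost:
                best, best_cost = res, cost
        return best
    centers = init_centers(X, k, seed) if init is None else np.asarray(init, dtype=float).copy()

    def _distances(C):
        return np.sqrt(np.maximum(
            np.sum(X**2, axis=1)[:, None] + np.sum(C**2, axis=1)[None, :] - 2 * X @ C.T, 0.0
        ))

    if eps == "auto":
        d = np.sort(_distances(centers), axis=1)
        ratios = d[:, 1] / np.maximum(d[:, 0], 1e-12)
        eps = float(min(np.quantile(ratios, 0.9), 1.5))

    it = 0
    lower = np.full(len(X), -1)
    upper: list = [()] * len(X)
    for it in range(1, max_iter + 1):
        d = _distances(centers)
        order = np.argsort(d, axis=1, kind="stable")
        d1 = d[np.arange(len(X)), order[:, 0]]
        lower = np.full(len(X), -1)
        upper = []
        for i in range(len(X)):
            near = order[i, 0]
            ambiguous = ()
            if eps >= 1.0:  # ratios d2/d1 are always >= 1, so eps < 1 means none
                ambiguous = tuple(j for j in order[i, 1:] if d[i, j] <= eps * d1[i])
            if ambiguous:
                upper.append((near,) + tuple(sorted(ambiguous)))  # nearest first
            else:
                lower[i] = near
                upper.append((near,))
        new_centers = np.empty_like(centers)
        for c in range(k):
            lo = X[lower == c]
            fringe = np.asarray([i for i, u in enumerate(upper) if c in u and lower[i] == -1])
            up_only = X[fringe] if len(fringe) else np.empty((0, X.shape[1]))
            if len(lo) and len(up_only):
                new_centers[c] = w_lower * lo.mean(axis=0) + w_upper * up_only.mean(axis=0)
            elif len(lo):
                new_centers[c] = lo.mean(axis=0)
            elif len(up_only):
                new_centers[c] = up_only.mean(axis=0)
            else:
                new_centers[c] = centers[c]
        if np.max(np.abs(new_centers - centers)) < 1e-6:
            centers = new_centers
            break
        centers = new_centers
    return RoughClustering(centers=centers, lower=lower, upper=upper,
                           w_lower=w_lower, w_upper=w_upper,
                           eps=float(eps), iterations=it)


# ---------------------------------------------------------------------------
# fascicle labeling

def cluster_type_names(image: np.ndarray, clustering: RoughClustering,
                       coords: np.ndarray) -> dict:
    """Map cluster index -> type name by mean grayscale of lower-set pixels
    (darkest = sensory, lightest = motor, middle = mixed).

    Grayscale is smoothed to region scale first: the raw value of a sampled
    pixel reflects whichever granule it happens to sit on, not the darkness
    of its fascicle.
    """
    from scipy import ndimage as _ndi

    img = np.asarray(image, dtype=float)
    gray = img.mean(axis=2) if img.ndim == 3 else img
    gray = _ndi.gaussian_filter(gray, 5.0)
    means = []
    for c in range(clustering.k):
        members = clustering.lower_members(c)
        if len(members) == 0:
            members = clustering.upper_members(c)
        vals = gray[coords[members, 0], coords[members, 1]]
        means.append(vals.mean() if len(vals) else np.inf)
    order = np.argsort(means, kind="stable")
    names = {}
    for rank, c in enumerate(order):
        names[int(c)] = TYPE_ORDER_BY_DARKNESS[min(rank, len(TYPE_ORDER_BY_DARKNESS) - 1)]
    return names


def label_fascicles(contours: list, clustering: RoughClustering,
                    coords: np.ndarray, image: np.ndarray) -> list:
    """Assign each contour a functional type by majority vote.

    Votes come from lower-approximation pixels falling inside the contour
    polygon; vote ties resolve to ``mixed``; contours containing no sampled
    pixel are labeled ``unknown`` and logged.
    """
    names = cluster_type_names(image, clustering, coords)
    pts = coords[:, ::-1].astype(float)  # matplotlib paths take (x, y) = (col, row)
    labels = []
    for ci, contour in enumerate(contours):
        verts = np.asarray(getattr(contour, "vertices", contour), dtype=float)
        path = _MplPath(verts[:, ::-1], closed=True)
        inside = path.contains_points(pts)
        votes: dict = {}
        for i in np.flatnonzero(inside):
            if clustering.lower[i] >= 0:
                t = names[int(clustering.lower[i])]
                votes[t] = votes.get(t, 0) + 1
        if not votes:
            logger.warning("contour %d contains no sampled pixels; labeled unknown", ci)
            labels.append("unknown")
            continue
        top = max(votes.values())
        winners = sorted(t for t, v in votes.items() if v == top)
        labels.append(winners[0] if len(winners) == 1 else "mixed")
    return labels
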