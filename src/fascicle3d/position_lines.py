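"""Fiducial-dot ("position line") recognition.

Each section carries four dark circular fiducial dots of 12-15 px diameter.
A 15x15 template window is classified as *circle-like* or *non-circular* by
a least-squares support vector machine (LS-SVM) with an RBF kernel; the dot
center is reported at the window center (row 8 / column 8 in 1-based
counting, i.e. index (7, 7)).  A dark-blob prefilter proposes candidate
windows so the classifier never scans the full raster.

The LS-SVM dual problem is a single linear solve (no iterative optimizer),

    [ 0   y^T          ] [b]   [0]
    [ y   Omega + I/g  ] [a] = [1],    Omega_ij = y_i y_j K(x_i, x_j),

with RBF kernel K(x, z) = exp(-||x - z||^2 / sigma2).  Hyperparameters
(sigma2, gamma) are tuned by a real-coded genetic algorithm minimizing the
misclassification rate on a held-out template set.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "RingTemplate",
    "LSSVMModel",
    "LandmarkSet",
    "DetectionCountError",
    "DegenerateTrainingError",
    "canonical_labels",
    "make_ring_template",
    "window_features",
    "train_detector",
    "tune_detector",
    "detect_position_lines",
    "save_model",
    "load_model",
]

TEMPLATE_SIZE = 15
TEMPLATE_CENTER = (7, 7)  # eighth row / eighth column, 0-based
RING_INNER = 6.0
RING_OUTER = 7.5
LANDMARK_LABELS = ("S_a", "S_b", "S_c", "S_d")

# prefilter: dark connected components whose area matches a 12-15 px
# diameter disk (pi*6^2 .. pi*7.5^2 ~ 113..177), with tolerance so a true
# fiducial is never rejected before the classifier sees it
PREFILTER_AREA_MIN = 80
PREFILTER_AREA_MAX = 260
NMS_RADIUS = 8.0


class DetectionCountError(RuntimeError):
    """Raised when a section does not yield exactly four fiducial detections."""

    def __init__(self, count: int):
        super().__init__(f"expected 4 position-line detections, found {count}")
        self.count = count


class DegenerateTrainingError(ValueError):
    """Raised when the LS-SVM linear system is singular (e.g. duplicate
    windows with conflicting labels)."""


@dataclass(frozen=True)
class RingTemplate:
    """The 15x15 ring-band template; ``band_mask`` marks the annulus where a
    circle-like blob's edge pixels must fall."""

    band_mask: np.ndarray
    size: int = TEMPLATE_SIZE
    center_index: tuple = TEMPLATE_CENTER


def make_ring_template() -> RingTemplate:
    yy, xx = np.meshgrid(np.arange(TEMPLATE_SIZE), np.arange(TEMPLATE_SIZE), indexing="ij")
    d = np.hypot(yy - TEMPLATE_CENTER[0], xx - TEMPLATE_CENTER[1])
    # one pixel of slack inward: rasterized edge pixels of a radius-6 disk
    # sit just inside the nominal 6-7.5 px ring
    band = (d >= RING_INNER - 1.0) & (d <= RING_OUTER + 0.6)
    return RingTemplate(band_mask=band)


def canonical_labels(points: np.ndarray):
    """Assign S_a..S_d by angle around the 4-point centroid.

    Angles are measured in standard orientation (col axis = +x, row axis
    pointing *up*), sorted ascending from [0, 2*pi) — i.e. counterclockwise
    starting at the smallest angle.  Returns labels aligned with the input
    point order.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    ang = np.arctan2(-(pts[:, 0] - centroid[0]), pts[:, 1] - centroid[1])
    ang = np.mod(ang, 2 * np.pi)
    order = np.argsort(ang, kind="stable")
    labels = [None] * len(pts)
    for lab, idx in zip(LANDMARK_LABELS, order):
        labels[idx] = lab
    return labels


@dataclass
class LandmarkSet:
    """The four labeled fiducial centers of one section plus their centroid."""

    section_index: int
    centers: dict  # label -> (row, col)
    section_center: tuple

    def as_array(self) -> np.ndarray:
        """(4, 2) array in canonical label order."""
        return np.array([self.centers[lab] for lab in LANDMARK_LABELS], dtype=float)


# ---------------------------------------------------------------------------
# LS-SVM

def window_features(windows: np.ndarray) -> np.ndarray:
    """Flattened min-max-normalized grayscale of each 15x15 patch.

    Constant patches normalize to all zeros.
    """
    w = np.asarray(windows, dtype=float)
    if w.ndim == 3:
        w = w[None]
    gray = w.mean(axis=3) if w.ndim == 4 else w
    flat = gray.reshape(len(gray), -1)
    lo = flat.min(axis=1, keepdims=True)
    hi = flat.max(axis=1, keepdims=True)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    return (flat - lo) / span


@dataclass
class LSSVMModel:
    """Trained LS-SVM classifier (all training points are retained)."""

    support_vectors: np.ndarray  # (n, d) feature rows
    labels: np.ndarray  # (n,) in {-1, +1}
    alpha: np.ndarray  # (n,) dual coefficients
    bias: float
    sigma2: float
    gamma: float
    feature_mean: np.ndarray
    feature_std: np.ndarray

    def _standardize(self, feats: np.ndarray) -> np.ndarray:
        return (feats - self.feature_mean) / self.feature_std

    def decision_function(self, windows: np.ndarray) -> np.ndarray:
        feats = self._standardize(window_features(windows))
        K = _rbf_kernel(feats, self.support_vectors, self.sigma2)
        return K @ (self.alpha * self.labels) + self.bias

    def predict(self, windows: np.ndarray) -> np.ndarray:
        d = self.decision_function(windows)
        out = np.where(d >= 0, 1, -1)
        return out


def _rbf_kernel(X: np.ndarray, Z: np.ndarray, sigma2: float) -> np.ndarray:
    # squared distance normalized by dimensionality, so that useful kernel
    # widths are O(1)-O(10) regardless of the window feature length
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Z**2, axis=1)[None, :]
        - 2.0 * X @ Z.T
    ) / X.shape[1]
    return np.exp(-np.maximum(d2, 0.0) / sigma2)


def train_detector(windows: np.ndarray, labels: np.ndarray,
                   sigma2: float = 2.0, gamma: float = 100.0) -> LSSVMModel:
    """Solve the LS-SVM linear system for the labeled template windows.

    Parameters
    ----------
    windows : (n, 15, 15[, 3]) array
    labels : (n,) array of +1 (circle-like) / -1 (non-circular)
    sigma2 : RBF kernel width parameter, > 0
    gamma : regularization parameter, > 0
    """
    y = np.asarray(labels, dtype=float)
    if sigma2 <= 0 or gamma <= 0:
        raise ValueError("sigma2 and gamma must be positive")
    if len(set(np.unique(y)) - {-1.0, 1.0}) > 0:
        raise ValueError("labels must be +1/-1")
    if (y == 1).sum() < 1 or (y == -1).sum() < 1:
        raise ValueError("need at least one window per class")
    feats = window_features(windows)
    mean = feats.mean(axis=0)
    std = feats.std(axis=0)
    std = np.where(std > 1e-12, std, 1.0)
    X = (feats - mean) / std
    n = len(X)
    K = _rbf_kernel(X, X, sigma2)
    Omega = (y[:, None] * y[None, :]) * K
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = y
    A[1:, 0] = y
    A[1:, 1:] = Omega + np.eye(n) / gamma
    rhs = np.concatenate([[0.0], np.ones(n)])
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateTrainingError(str(exc)) from exc
    if not np.all(np.isfinite(sol)):
        raise DegenerateTrainingError("non-finite LS-SVM solution")
    return LSSVMModel(
        support_vectors=X, labels=y, alpha=sol[1:], bias=float(sol[0]),
        sigma2=float(sigma2), gamma=float(gamma),
        feature_mean=mean, feature_std=std,
    )


def misclassification_rate(model: LSSVMModel, windows, labels) -> float:
    pred = model.predict(windows)
    return float(np.mean(pred != np.asarray(labels)))


# ---------------------------------------------------------------------------
# GA hyperparameter search

@dataclass
class GAConfig:
    population: int = 30
    generations: int = 50
    sigma2_bounds: tuple = (0.1, 50.0)
    gamma_bounds: tuple = (1.0, 1000.0)
    seed: int = 0
    crossover_rate: float = 0.8
    mutation_rate: float = 0.25
    tournament_k: int = 3
    include_default: tuple = (2.0, 100.0)  # seeded into the initial population


def tune_detector(train_windows, train_labels, test_windows, test_labels,
                  ga_config: GAConfig | None = None):
    """Real-coded GA over (sigma2, gamma) minimizing held-out error.

    Fitness of an individual = misclassification rate on ``test_windows`` of
    the LS-SVM trained at that parameter pair.  Elitism keeps the best
    individual, and the conventional default (2, 100) is seeded into the
    initial population so the tuned result can never be worse than it.

    Returns ``(sigma2, gamma, test_error)``.
    """
    cfg = ga_config or GAConfig()
    if len(np.asarray(test_labels)) == 0:
        raise ValueError("empty test set")
    lo = np.array([cfg.sigma2_bounds[0], cfg.gamma_bounds[0]])
    hi = np.array([cfg.sigma2_bounds[1], cfg.gamma_bounds[1]])
    if np.any(lo <= 0):
        raise ValueError("bounds must be positive")
    rng = np.random.default_rng(cfg.seed)
    span = hi - lo

    cache: dict = {}

    def fitness(ind) -> float:
        key = (round(float(ind[0]), 10), round(float(ind[1]), 10))
        if key not in cache:
            model = train_detector(train_windows, train_labels,
                                   sigma2=key[0], gamma=key[1])
            cache[key] = misclassification_rate(model, test_windows, test_labels)
        return cache[key]

    if np.all(span == 0):  # degenerate search space
        return float(lo[0]), float(lo[1]), fitness(lo)

    pop = lo + rng.random((cfg.population, 2)) * span
    if cfg.include_default is not None:
        pop[0] = np.clip(cfg.include_default, lo, hi)
    fits = np.array([fitness(ind) for ind in pop])

    for _ in range(cfg.generations):
        order = np.argsort(fits, kind="stable")
        elite = pop[order[0]].copy()
        elite_fit = fits[order[0]]
        children = [elite]
        while len(children) < cfg.population:
            # tournament selection of two parents
            parents = []
            for _p in range(2):
                idx = rng.integers(0, cfg.population, size=cfg.tournament_k)
                parents.append(pop[idx[np.argmin(fits[idx])]])
            p1, p2 = parents
            if rng.random() < cfg.crossover_rate:  # blend (BLX-style)
                w = rng.random(2)
                child = w * p1 + (1 - w) * p2
            else:
                child = p1.copy()
            if rng.random() < cfg.mutation_rate:
                child = child + rng.normal(0, 0.1, size=2) * span
            children.append(np.clip(child, lo, hi))
        pop = np.stack(children)
        fits = np.array([fitness(ind) for ind in pop])
        fits[0] = elite_fit  # elite carried over unchanged

    best = int(np.argmin(fits))
    s2, g = float(pop[best][0]), float(pop[best][1])
    return s2, g, float(fitness(pop[best]))


# ---------------------------------------------------------------------------
# detection

def _candidate_centers(gray: np.ndarray) -> np.ndarray:
    """Dark-blob prefilter: threshold on darkness, keep connected components
    whose size matches a fiducial-dot disk, return their centroids."""
    dark = gray < 95.0
    lbl, _ = ndimage.label(dark)
    out = []
    for region in measure.regionprops(lbl):
        if PREFILTER_AREA_MIN <= region.area <= PREFILTER_AREA_MAX:
            out.append(region.centroid)
    return np.asarray(out, dtype=float).reshape(-1, 2)


def detect_position_lines(image, model: LSSVMModel,
                          section_index: int = 0) -> LandmarkSet:
    """Locate the four fiducial dots of one section.

    Candidate centers come from the dark-blob prefilter; each candidate's
    15x15 window is scored by the LS-SVM; positives are pruned by
    non-maximum suppression (radius 8 px, ties broken by smaller (row, col));
    anything other than exactly 4 survivors raises
    :class:`DetectionCountError`.
    """
    img = np.asarray(getattr(image, "pixels", image))
    if img.shape[0] < TEMPLATE_SIZE or img.shape[1] < TEMPLATE_SIZE:
        raise ValueError("image smaller than the 15x15 template")
    gray = img.mean(axis=2) if img.ndim == 3 else img.astype(float)
    H, W = gray.shape
    half = TEMPLATE_SIZE // 2
    cands = _candidate_centers(gray)
    hits = []
    for cr, cc in cands:
        # floor(x + 0.5) instead of round(): half-to-even rounding would
        # break exact translation equivariance of the detections
        r0 = int(np.clip(np.floor(cr + 0.5), half, H - 1 - half))
        c0 = int(np.clip(np.floor(cc + 0.5), half, W - 1 - half))
        win = img[r0 - half : r0 + half + 1, c0 - half : c0 + half + 1]
        score = float(model.decision_function(win[None])[0])
        if score >= 0:
            hits.append((score, r0, c0))
    # non-maximum suppression: keep highest score within radius
    hits.sort(key=lambda h: (-h[0], h[1], h[2]))
    kept = []
    for score, r0, c0 in hits:
        if all(np.hypot(r0 - kr, c0 - kc) > NMS_RADIUS for _, kr, kc in kept):
            kept.append((score, r0, c0))
    if len(kept) != 4:
        raise DetectionCountError(len(kept))
    pts = np.array([[r, c] for _, r, c in kept], dtype=float)
    labels = canonical_labels(pts)
    centers = {lab: (float(r), float(c)) for lab, (r, c) in zip(labels, pts)}
    centroid = pts.mean(axis=0)
    return LandmarkSet(
        section_index=section_index,
        centers=centers,
        section_center=(float(centroid[0]), float(centroid[1])),
    )


# ---------------------------------------------------------------------------
# model persistence: a single portable zip archive

_MODEL_FORMAT_VERSION = 1


def save_model(model: LSSVMModel, path) -> None:
    meta = {
        "format_version": _MODEL_FORMAT_VERSION,
        "sigma2": model.sigma2,
        "gamma": model.gamma,
        "bias": model.bias,
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for name, arr in [
            ("support_vectors", model.support_vectors),
            ("labels", model.labels),
            ("alpha", model.alpha),
            ("feature_mean", model.feature_mean),
            ("feature_std", model.feature_std),
        ]:
            zf.writestr(name + ".json", json.dumps(np.asarray(arr).tolist()))


def load_model(path) -> LSSVMModel:
    with zipfile.ZipFile(path, "r") as zf:
        meta = json.loads(zf.read("meta.json"))
        if meta.get("format_version") != _MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        arrs = {
            name: np.asarray(json.loads(zf.read(name + ".json")))
            for name in ["support_vectors", "labels", "alpha", "feature_mean", "feature_std"]
        }
    return LSSVMModel(
        support_vectors=arrs["support_vectors"], labels=arrs["labels"],
        alpha=arrs["alpha"], bias=float(meta["bias"]),
        sigma2=float(meta["sigma2"]), gamma=float(meta["gamma"]),
        feature_mean=arrs["feature_mean"], feature_std=arrs["feature_std"],
    )
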