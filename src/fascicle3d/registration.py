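"""Landmark-based serial-section registration with a bilinear coordinate map.

Coordinates are 0-based ``(row, col)`` with row increasing downward.  In the
transform equations the first coordinate (``x``) is the row and the second
(``y``) is the column:

    x' = a0 + a1*x + a2*y + a3*x*y
    y' = b0 + b1*x + b2*y + b3*x*y

Four matched control-point pairs determine the eight coefficients exactly
(two independent 4x4 linear systems).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "BilinearTransform",
    "SingularGeometryError",
    "fit_bilinear",
    "warp_section",
    "register_stack",
]


class SingularGeometryError(ValueError):
    """Raised when the four control points do not determine the transform."""


@dataclass(frozen=True)
class BilinearTransform:
    """Coordinate map with terms ``1, x, y, xy`` per output coordinate."""

    a: np.ndarray  # (a0, a1, a2, a3) for the row coordinate
    b: np.ndarray  # (b0, b1, b2, b3) for the col coordinate

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        if self.a.shape != (4,) or self.b.shape != (4,):
            raise ValueError("coefficient vectors must each have 4 entries")

    @classmethod
    def identity(cls) -> "BilinearTransform":
        return cls(a=np.array([0.0, 1.0, 0.0, 0.0]), b=np.array([0.0, 0.0, 1.0, 0.0]))

    @property
    def is_identity(self) -> bool:
        return bool(
            np.allclose(self.a, [0, 1, 0, 0], atol=1e-12)
            and np.allclose(self.b, [0, 0, 1, 0], atol=1e-12)
        )

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Map an ``(N, 2)`` array of (row, col) points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        x, y = p[:, 0], p[:, 1]
        basis = np.stack([np.ones_like(x), x, y, x * y], axis=1)
        out = np.stack([basis @ self.a, basis @ self.b], axis=1)
        return out if np.asarray(points).ndim == 2 else out[0]

    def jacobian(self, points: np.ndarray) -> np.ndarray:
        """Per-point 2x2 Jacobians, shape ``(N, 2, 2)``."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        x, y = p[:, 0], p[:, 1]
        J = np.empty((len(p), 2, 2))
        J[:, 0, 0] = self.a[1] + self.a[3] * y
        J[:, 0, 1] = self.a[2] + self.a[3] * x
        J[:, 1, 0] = self.b[1] + self.b[3] * y
        J[:, 1, 1] = self.b[2] + self.b[3] * x
        return J

    def inverse_map(self, points: np.ndarray, n_iter: int = 25) -> np.ndarray:
        """Numerically invert the map at the given points (Newton iteration).

        The bilinear family is not closed under inversion, so the inverse is
        evaluated pointwise.  Near-identity transforms converge to machine
        precision in a handful of iterations.
        """
        q = np.atleast_2d(np.asarray(points, dtype=float))
        p = q.copy()
        for _ in range(n_iter):
            r = self(p) - q
            J = self.jacobian(p)
            det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
            dp0 = (J[:, 1, 1] * r[:, 0] - J[:, 0, 1] * r[:, 1]) / det
            dp1 = (-J[:, 1, 0] * r[:, 0] + J[:, 0, 0] * r[:, 1]) / det
            p[:, 0] -= dp0
            p[:, 1] -= dp1
            if np.max(np.abs(r)) < 1e-13:
                break
        return p if np.asarray(points).ndim == 2 else p[0]

    def as_row(self) -> np.ndarray:
        return np.concatenate([self.a, self.b])


def fit_bilinear(reference_points: np.ndarray, moving_points: np.ndarray) -> BilinearTransform:
    """Fit the transform mapping each moving point onto its reference partner.

    Parameters
    ----------
    reference_points, moving_points
        ``(4, 2)`` arrays of matched (row, col) control points, same label
        order in both.

    Returns
    -------
    BilinearTransform
        Satisfies ``t(moving_points) == reference_points`` to ~1e-9.

    Raises
    ------
    SingularGeometryError
        If the moving points are in degenerate position (the 4x4 Vandermonde
        style system is singular).
    """
    ref = np.asarray(reference_points, dtype=float)
    mov = np.asarray(moving_points, dtype=float)
    if ref.shape != (4, 2) or mov.shape != (4, 2):
        raise ValueError("exactly 4 matched control points are required")
    x, y = mov[:, 0], mov[:, 1]
    M = np.stack([np.ones(4), x, y, x * y], axis=1)
    if np.linalg.cond(M) > 1e12:
        raise SingularGeometryError("control points are in degenerate position")
    a = np.linalg.solve(M, ref[:, 0])
    b = np.linalg.solve(M, ref[:, 1])
    return BilinearTransform(a=a, b=b)


def _modal_border_color(image: np.ndarray) -> np.ndarray:
    """Most frequent color among the 1-px border (used as fill value)."""
    border = np.concatenate(
        [image[0], image[-1], image[:, 0], image[:, -1]], axis=0
    ).reshape(-1, image.shape[2] if image.ndim == 3 else 1)
    colors, counts = np.unique(border, axis=0, return_counts=True)
    return colors[np.argmax(counts)]


def warp_section(image: np.ndarray, t: BilinearTransform) -> np.ndarray:
    """Resample ``image`` under ``t`` interpreted as the backward map.

    ``t`` maps output-frame coordinates to input-frame coordinates; intensity
    is pulled back with bilinear interpolation.  Pixels mapping outside the
    input frame are filled with the modal border color.
    """
    img = np.asarray(image)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[..., None]
    H, W = img.shape[:2]
    rows, cols = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    pts = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(float)
    src = t(pts)
    coords = [src[:, 0].reshape(H, W), src[:, 1].reshape(H, W)]
    fill = _modal_border_color(img)
    out = np.empty_like(img)
    for c in range(img.shape[2]):
        out[..., c] = ndimage.map_coordinates(
            img[..., c].astype(float), coords, order=1, mode="constant",
            cval=float(fill[c]),
        ).round().astype(img.dtype) if np.issubdtype(img.dtype, np.integer) else ndimage.map_coordinates(
            img[..., c], coords, order=1, mode="constant", cval=float(fill[c])
        )
    return out[..., 0] if squeeze else out


@dataclass
class RegistrationResult:
    """Output of :func:`register_stack`."""

    images: list
    transforms: list  # forward (moving -> reference) BilinearTransform or None
    reference_index: int
    gaps: list = field(default_factory=list)  # section indices lacking landmarks


def register_stack(stack, landmarks, reference_index: int = 0) -> RegistrationResult:
    """Register every section onto the reference section's frame.

    Parameters
    ----------
    stack
        Sequence of image arrays (or objects with a ``pixels`` attribute).
    landmarks
        Per-section ``(4, 2)`` arrays of labeled landmark centers in canonical
        label order, or ``None`` for sections where detection failed.
    reference_index
        Section whose frame all others are mapped into; returned unchanged.

    Sections with missing landmarks are passed through unwarped, recorded in
    ``gaps``, and logged — the stack analogue of discarding failed sections.
    """
    imgs = [getattr(s, "pixels", s) for s in stack]
    if len(imgs) != len(landmarks):
        raise ValueError("stack and landmarks length mismatch")
    if landmarks[reference_index] is None:
        raise ValueError("reference section has no landmarks")
    ref_pts = np.asarray(landmarks[reference_index], dtype=float)

    out_images, transforms, gaps = [], [], []
    for i, (img, lm) in enumerate(zip(imgs, landmarks)):
        if lm is None:
            logger.warning("section %d has no landmark set; left unregistered", i)
            gaps.append(i)
            out_images.append(img)
            transforms.append(None)
            continue
        mov_pts = np.asarray(lm, dtype=float)
        forward = fit_bilinear(ref_pts, mov_pts)
        transforms.append(forward)
        if i == reference_index:
            out_images.append(img)
            continue
        backward = fit_bilinear(mov_pts, ref_pts)  # output (ref) -> input (moving)
        out_images.append(warp_section(img, backward))
    return RegistrationResult(
        images=out_images, transforms=transforms,
        reference_index=reference_index, gaps=gaps,
    )
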