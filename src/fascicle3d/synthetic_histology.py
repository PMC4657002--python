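"""Synthetic serial-section stacks with full ground truth.

Generates histology-like section images: fascicles rendered as granular
dark-pixel textures with internal voids, four dark circular fiducial dots
("position lines") near the image corners, per-section misalignment drawn
from a similarity transform plus a small xy-coupled term (so the bilinear
family is the correct model to recover), and scripted split/merge events
along the stack.

Geometry lives in a common *reference frame*; each section k records a
bilinear misalignment transform ``t_k`` mapping section coordinates back to
the reference frame.  Fascicle membership of a section pixel p is evaluated
as ``t_k(p) in disk`` so the recorded transform is exact by construction.

Three texture classes map onto the functional types: sensory fascicles are
rendered relatively darker, motor fascicles relatively lighter, and mixed
fascicles carry light granules interspersed with darker granule groups, so
that mean region intensity orders sensory < mixed < motor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .registration import BilinearTransform

__all__ = [
    "StackConfig",
    "SectionImage",
    "GroundTruth",
    "TextureParams",
    "generate_stack",
    "generate_template_windows",
    "DEFAULT_TEXTURES",
    "BACKGROUND_COLOR",
    "LANDMARK_COLOR",
]

Z_SPACING_MM = 0.5  # section planes are 0.5 mm apart; 15 um thickness is metadata

BACKGROUND_COLOR = np.array([236, 229, 233], dtype=np.uint8)
LANDMARK_COLOR = np.array([36, 38, 122], dtype=np.uint8)  # dark blue fiducial dots

TYPES = ("sensory", "motor", "mixed")


@dataclass(frozen=True)
class TextureParams:
    """Granule scatter parameters for one functional type.

    ``granule_color`` is the mean RGB of granule pixels; ``density`` the
    granule count per unit area (granules / px^2); ``void_fraction`` the
    fraction of the fascicle left granule-free (carved out as blank patches);
    ``dark_mix`` the probability that a granule uses the dark sensory color
    (nonzero only for the mixed class).
    """

    granule_color: tuple
    density: float
    void_fraction: float
    dark_mix: float = 0.0
    granule_radius: tuple = (1.0, 2.1)


DEFAULT_TEXTURES = {
    # sensory: dense, dark blue-teal granules -> darkest mean intensity,
    # large R-channel amplitude but small G-channel amplitude
    "sensory": TextureParams(granule_color=(90, 175, 90), density=0.080, void_fraction=0.08),
    # motor: light magenta granules, dense enough for stable window
    # statistics -> lightest mean intensity, large G-channel amplitude
    "motor": TextureParams(granule_color=(220, 70, 212), density=0.070, void_fraction=0.10),
    # mixed: motor-like granules interleaved with dark sensory granules ->
    # intermediate mean intensity, large amplitudes in all channels
    "mixed": TextureParams(granule_color=(220, 70, 212), density=0.075, void_fraction=0.10,
                           dark_mix=0.40),
}


@dataclass
class StackConfig:
    """Configuration of one synthetic stack."""

    n_sections: int = 16
    image_size: tuple = (768, 1024)  # (rows, cols)
    n_fascicles_initial: int = 3
    split_merge_events: list = field(default_factory=list)  # (section, event, fascicle_id)
    type_assignment: dict = field(default_factory=dict)  # fascicle_id -> type
    landmark_diameter_px: int = 13
    misalignment_scale: float = 3.0
    texture_params: dict = field(default_factory=lambda: dict(DEFAULT_TEXTURES))
    rng_seed: int = 0
    fascicle_radius_range: tuple = (26.0, 38.0)
    drift_px_per_section: float = 0.08

    def validate(self) -> None:
        if self.n_sections < 1:
            raise ValueError("n_sections must be >= 1")
        if not 12 <= self.landmark_diameter_px <= 15:
            raise ValueError("landmark_diameter_px must lie in [12, 15]")
        if self.n_fascicles_initial < 1:
            raise ValueError("need at least one fascicle")
        if self.misalignment_scale < 0:
            raise ValueError("misalignment_scale must be non-negative")
        n_merges = sum(1 for _, ev, _ in self.split_merge_events if ev == "merge")
        n_splits = sum(1 for _, ev, _ in self.split_merge_events if ev == "split")
        if self.n_fascicles_initial + n_splits - n_merges < 1:
            raise ValueError("fascicle count would drop to zero after merges")
        for sec, ev, _ in self.split_merge_events:
            if not 0 < sec < self.n_sections:
                raise ValueError("split/merge section index out of range")
            if ev not in ("split", "merge"):
                raise ValueError(f"unknown event {ev!r}")


@dataclass
class SectionImage:
    """One RGB section raster with stack index and physical z position."""

    pixels: np.ndarray  # (H, W, 3) uint8
    index: int
    z_mm: float

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class GroundTruth:
    """Everything downstream stages are scored against."""

    landmarks: list  # per section: dict label -> (row, col) float, section frame
    landmark_ref_positions: dict  # label -> (row, col) in the reference frame
    transforms: list  # per section: BilinearTransform, section frame -> reference frame
    fascicle_geometry: list  # per section: dict fid -> (center_row, center_col, radius), ref frame
    masks: list  # per section: dict fid -> bool array (section frame)
    contours: list  # per section: dict fid -> (K, 2) float polygon (section frame)
    types: dict  # fid -> type string
    lineage: nx.DiGraph  # nodes fascicle ids, edges parent -> child
    landmark_masks: list  # per section: bool array of fiducial-dot pixels
    config: StackConfig

    def fascicle_count(self, section: int) -> int:
        return len(self.fascicle_geometry[section])

    def aligned_mask(self, section: int, fid: int) -> np.ndarray:
        """Rasterize fascicle ``fid`` of ``section`` on the reference grid.

        Uses the recorded misalignment: a reference pixel q belongs to the
        aligned mask iff its image under the inverse transform falls in the
        section-frame fascicle region (whose membership test is itself
        ``t(p) in disk``).
        """
        t = self.transforms[section]
        cr, cc, rad = self.fascicle_geometry[section][fid]
        H, W = self.config.image_size
        # invert only within a bounding box around the disk for speed
        c_ref = np.array([cr, cc])
        lo = np.maximum(np.floor(c_ref - rad - 8).astype(int), 0)
        hi = np.minimum(np.ceil(c_ref + rad + 8).astype(int), [H, W])
        rr, cc_ = np.meshgrid(np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), indexing="ij")
        q = np.stack([rr.ravel(), cc_.ravel()], axis=1).astype(float)
        p = t.inverse_map(q)        # section-frame coordinates
        back = t(p)                 # reference frame again, via the recorded map
        inside = (back[:, 0] - cr) ** 2 + (back[:, 1] - cc) ** 2 <= rad**2
        out = np.zeros((H, W), dtype=bool)
        out[rr.ravel()[inside], cc_.ravel()[inside]] = True
        return out


# ---------------------------------------------------------------------------
# misalignment

def _draw_misalignment(rng: np.random.Generator, scale: float,
                       image_size: tuple) -> BilinearTransform:
    """Similarity transform (translation <= scale px, rotation <= 5 deg) plus
    a small xy-coupled term, about the image center."""
    if scale == 0:
        return BilinearTransform.identity()
    H, W = image_size
    cx, cy = (H - 1) / 2.0, (W - 1) / 2.0
    theta = np.deg2rad(rng.uniform(-1, 1) * min(5.0, scale))
    tx, ty = rng.uniform(-scale, scale, size=2)
    # xy coupling sized so its displacement stays below ~0.5*scale anywhere
    cmax = 0.5 * scale / (H * W)
    a3 = rng.uniform(-cmax, cmax)
    b3 = rng.uniform(-cmax, cmax)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # x' = cx + cos*(x-cx) - sin*(y-cy) + tx + a3*x*y   (x=row, y=col)
    a = np.array([cx - cos_t * cx + sin_t * cy + tx, cos_t, -sin_t, a3])
    b = np.array([cy - sin_t * cx - cos_t * cy + ty, sin_t, cos_t, b3])
    return BilinearTransform(a=a, b=b)


# ---------------------------------------------------------------------------
# layout

def _layout_fascicles(rng, config: StackConfig):
    """Place the initial non-overlapping disks, clear of the fiducial dots.

    When a merge is scripted, fascicles 0 and 1 are placed adjacent (small
    gap) so the pre-merge approach phase only needs a few px per section and
    consecutive-section contour overlap stays high.
    """
    H, W = config.image_size
    r_lo, r_hi = config.fascicle_radius_range
    margin = 95 + r_hi  # stay away from the corner fiducials and the border
    has_merge = any(ev == "merge" for _, ev, _ in config.split_merge_events)
    placed = {}
    for fid in range(config.n_fascicles_initial):
        for attempt in range(100):
            rad = rng.uniform(r_lo, r_hi)
            if has_merge and fid == 1 and 0 in placed:
                pr0, pc0, prad0 = placed[0]
                ang = rng.uniform(0, 2 * np.pi)
                d = rad + prad0 + rng.uniform(34, 46)
                cr = pr0 + d * np.cos(ang)
                cc = pc0 + d * np.sin(ang)
                if not (margin <= cr <= H - margin and margin <= cc <= W - margin):
                    continue
            else:
                cr = rng.uniform(margin, H - margin)
                cc = rng.uniform(margin, W - margin)
            ok = all(
                np.hypot(cr - pr, cc - pc) >= rad + prad + 28
                for pr, pc, prad in placed.values()
            )
            if ok:
                placed[fid] = (cr, cc, rad)
                break
        else:
            raise RuntimeError("could not place fascicles without overlap after 100 attempts")
    return placed


def _evolve_geometry(rng, config: StackConfig):
    """Per-section reference-frame geometry plus the lineage graph.

    Returns ``(geometry, lineage, types)`` where geometry[k] maps alive
    fascicle ids to (row, col, radius).
    """
    base = _layout_fascicles(rng, config)
    lineage = nx.DiGraph()
    types = {}
    for fid in base:
        lineage.add_node(fid)
        types[fid] = config.type_assignment.get(fid, TYPES[fid % 3])

    drifts = {fid: rng.uniform(-1, 1, size=2) * config.drift_px_per_section for fid in base}
    events = sorted(config.split_merge_events)
    next_id = max(base) + 1
    alive = dict(base)  # fid -> geometry at the *current* section
    geometry = []
    merge_records = []  # (section, fid, partner) for the approach phase below
    split_records = []  # (section, child1, child2, child_r) for the separation phase
    for k in range(config.n_sections):
        for sec, ev, fid in events:
            if sec != k:
                continue
            if fid not in alive:
                raise ValueError(f"event references fascicle {fid} not alive at section {sec}")
            if ev == "split":
                cr, cc, rad = alive.pop(fid)
                child_r = max(0.75 * rad, 20.0)
                ang = rng.uniform(0, 2 * np.pi)
                off = 1.35 * child_r
                u = np.array([np.cos(ang), np.sin(ang)])
                kids = []
                for sgn in (+1, -1):
                    cid = next_id
                    next_id += 1
                    alive[cid] = (cr + sgn * off * u[0], cc + sgn * off * u[1], child_r)
                    lineage.add_edge(fid, cid)
                    types[cid] = types[fid]
                    drifts[cid] = drifts[fid]
                    kids.append(cid)
                split_records.append((k, kids[0], kids[1], child_r))
            else:  # merge with the nearest alive partner
                if len(alive) < 2:
                    raise ValueError("merge requested with fewer than 2 alive fascicles")
                cr, cc, rad = alive[fid]
                # prefer a size-comparable partner: a very small partner can
                # never reach the overlap threshold against the merged disk
                comparable = [
                    p for p in alive
                    if p != fid and min(alive[p][2], rad) / max(alive[p][2], rad) >= 0.6
                ]
                pool = comparable or [p for p in alive if p != fid]
                partner = min(
                    pool, key=lambda p: np.hypot(alive[p][0] - cr, alive[p][1] - cc)
                )
                pr, pc, prad = alive.pop(partner)
                alive.pop(fid)
                w1, w2 = rad**2, prad**2
                cid = next_id
                next_id += 1
                merged_r = min(np.sqrt(rad**2 + prad**2), 1.8 * min(rad, prad), 40.0)
                alive[cid] = (
                    (w1 * cr + w2 * pr) / (w1 + w2),
                    (w1 * cc + w2 * pc) / (w1 + w2),
                    merged_r,
                )
                lineage.add_edge(fid, cid)
                lineage.add_edge(partner, cid)
                types[cid] = types[fid] if rad >= prad else types[partner]
                drifts[cid] = drifts[fid]
                merge_records.append((k, fid, partner, cid))
        geometry.append(dict(alive))
        alive = {
            fid: (cr + drifts[fid][0], cc + drifts[fid][1], rad)
            for fid, (cr, cc, rad) in alive.items()
        }

    # approach phase: in the sections leading up to each merge the two
    # partners converge until nearly touching, so that consecutive-section
    # contour overlap stays high through the event (fascicle confluence is
    # continuous along the nerve, not a jump)
    for s, fid, partner, cid in merge_records:
        approach = min(6, s)
        final_mid = None
        for j, k in enumerate(range(s - approach, s)):
            f = (j + 1) / approach
            if fid not in geometry[k] or partner not in geometry[k]:
                continue  # a partner may itself only appear mid-stack
            (ar, ac, arad) = geometry[k][fid]
            (br, bc, brad) = geometry[k][partner]
            mid = np.array([(ar + br) / 2.0, (ac + bc) / 2.0])
            # parents end up overlapping by ~25% so both clear the lineage
            # overlap threshold against the merged disk
            gap = 0.65 * (arad + brad)
            d = np.hypot(ar - br, ac - bc)
            u = np.array([ar - br, ac - bc]) / d if d > 0 else np.array([1.0, 0.0])
            ta = mid + u * gap / 2.0
            tb = mid - u * gap / 2.0
            geometry[k][fid] = (ar + f * (ta[0] - ar), ac + f * (ta[1] - ac), arad)
            geometry[k][partner] = (br + f * (tb[0] - br), bc + f * (tb[1] - bc), brad)
            final_mid = mid
        if final_mid is not None and cid in geometry[s]:
            # put the merged child where the parents actually met
            (mr, mc, mrad) = geometry[s][cid]
            delta = final_mid - np.array([mr, mc])
            for k in range(s, len(geometry)):
                if cid not in geometry[k]:
                    break
                (xr, xc, xrad) = geometry[k][cid]
                geometry[k][cid] = (xr + delta[0], xc + delta[1], xrad)

    # separation phase: split children start adjacent inside the parent's
    # footprint and drift apart over the following sections (the std-based
    # clusterer resolves them immediately; the contour overlap to the parent
    # stays above the lineage-link threshold)
    for s, c1, c2, child_r in split_records:
        for k in range(s, len(geometry)):
            if c1 not in geometry[k] or c2 not in geometry[k]:
                break
            off = child_r * (0.70 + 0.65 * min(1.0, (k - s) / 4.0))
            (ar, ac, arad) = geometry[k][c1]
            (br, bc, brad) = geometry[k][c2]
            mid = np.array([(ar + br) / 2.0, (ac + bc) / 2.0])
            d = np.hypot(ar - br, ac - bc)
            u = np.array([ar - br, ac - bc]) / d if d > 0 else np.array([1.0, 0.0])
            geometry[k][c1] = (mid[0] + u[0] * off, mid[1] + u[1] * off, arad)
            geometry[k][c2] = (mid[0] - u[0] * off, mid[1] - u[1] * off, brad)
    return geometry, lineage, types


# ---------------------------------------------------------------------------
# rendering

def _disk_coords(center, radius, shape):
    cr, cc = center
    H, W = shape
    lo_r = max(int(np.floor(cr - radius)) - 1, 0)
    hi_r = min(int(np.ceil(cr + radius)) + 2, H)
    lo_c = max(int(np.floor(cc - radius)) - 1, 0)
    hi_c = min(int(np.ceil(cc + radius)) + 2, W)
    rr, cc_ = np.meshgrid(np.arange(lo_r, hi_r), np.arange(lo_c, hi_c), indexing="ij")
    keep = (rr - cr) ** 2 + (cc_ - cc) ** 2 <= radius**2
    return rr[keep], cc_[keep]


def _render_fascicle(img, mask, params: TextureParams, rng, dark_color):
    """Scatter 1-2 px granules inside ``mask``, leaving void patches blank.

    Granule centers are drawn from a slightly dilated mask (pixels clipped to
    the mask) so texture coverage stays uniform right up to the boundary.
    """
    from scipy import ndimage as _ndi

    area = int(mask.sum())
    if area == 0:
        return
    dilated = _ndi.binary_dilation(mask, iterations=2)
    rows, cols = np.nonzero(dilated)
    # carve voids: blank circular patches that granules avoid
    void = np.zeros_like(mask)
    n_voids = max(1, int(params.void_fraction * area / (np.pi * 36)))
    for _ in range(n_voids):
        i = rng.integers(len(rows))
        vr, vc = _disk_coords((rows[i], cols[i]), rng.uniform(3, 6), mask.shape)
        void[vr, vc] = True
    n_granules = rng.poisson(params.density * area)
    idx = rng.integers(0, len(rows), size=n_granules)
    light = np.asarray(params.granule_color, dtype=float)
    dark = np.asarray(dark_color, dtype=float)
    # deterministic alternation keeps the dark fraction exact and spatially
    # interleaved (granule positions are already random)
    phase = 0.0
    for i in idx:
        gr, gc = rows[i], cols[i]
        if void[gr, gc]:
            continue
        rad = rng.uniform(*params.granule_radius)
        phase += params.dark_mix
        if phase >= 1.0:
            phase -= 1.0
            color = dark
        else:
            color = light
        jitter = rng.normal(0, 4, size=3)
        rr, cc_ = _disk_coords((gr, gc), rad, mask.shape)
        inside = mask[rr, cc_]
        img[rr[inside], cc_[inside]] = np.clip(color + jitter, 0, 255).astype(np.uint8)


def _circle_polygon(t: BilinearTransform, center, radius, n=96):
    """Reference-frame circle mapped into the section frame as a polygon."""
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    ref = np.stack([center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)], axis=1)
    return t.inverse_map(ref)


def generate_stack(config: StackConfig):
    """Render the full stack.

    Returns
    -------
    (sections, truth)
        ``sections`` is a list of :class:`SectionImage`; ``truth`` a
        :class:`GroundTruth`.  Identical config and seed give bit-identical
        pixel arrays.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    H, W = config.image_size
    geometry, lineage, types = _evolve_geometry(rng, config)

    # fiducial reference positions: corner insets, slight jitter, canonical labels
    inset = 42.0
    corners = np.array([
        [inset, inset], [inset, W - 1 - inset],
        [H - 1 - inset, W - 1 - inset], [H - 1 - inset, inset],
    ]) + rng.uniform(-6, 6, size=(4, 2))
    from .position_lines import canonical_labels  # shared labeling rule
    labels = canonical_labels(corners)
    landmark_ref = {lab: tuple(pt) for lab, pt in zip(labels, corners)}

    lm_radius = config.landmark_diameter_px / 2.0
    sections, landmarks, transforms = [], [], []
    masks_all, contours_all, lm_masks = [], [], []
    for k in range(config.n_sections):
        t = _draw_misalignment(rng, config.misalignment_scale, config.image_size)
        transforms.append(t)
        img = np.empty((H, W, 3), dtype=np.uint8)
        img[:] = BACKGROUND_COLOR
        noise = rng.normal(0, 2.5, size=(H, W, 1))
        img = np.clip(img.astype(float) + noise, 0, 255).astype(np.uint8)

        # fascicles: membership via t(p) in disk, evaluated on a bounding box
        sec_masks, sec_contours = {}, {}
        dark_color = config.texture_params["sensory"].granule_color
        for fid, (cr, cc, rad) in geometry[k].items():
            c_sec = t.inverse_map(np.array([cr, cc], dtype=float))
            lo = np.maximum(np.floor(c_sec - rad - 10).astype(int), 0)
            hi = np.minimum(np.ceil(c_sec + rad + 10).astype(int) + 1, [H, W])
            rr, cc_ = np.meshgrid(np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), indexing="ij")
            pts = np.stack([rr.ravel(), cc_.ravel()], axis=1).astype(float)
            ref = t(pts)
            inside = (ref[:, 0] - cr) ** 2 + (ref[:, 1] - cc) ** 2 <= rad**2
            mask = np.zeros((H, W), dtype=bool)
            mask[rr.ravel()[inside], cc_.ravel()[inside]] = True
            sec_masks[fid] = mask
            sec_contours[fid] = _circle_polygon(t, (cr, cc), rad)
            _render_fascicle(img, mask, config.texture_params[types[fid]], rng, dark_color)

        # fiducial dots
        sec_lm = {}
        lm_mask = np.zeros((H, W), dtype=bool)
        for lab, ref_pt in landmark_ref.items():
            p = t.inverse_map(np.asarray(ref_pt, dtype=float))
            rr, cc_ = _disk_coords(p, lm_radius, (H, W))
            shade = np.clip(
                LANDMARK_COLOR.astype(float) + rng.normal(0, 6, size=(len(rr), 3)), 0, 255
            ).astype(np.uint8)
            img[rr, cc_] = shade
            lm_mask[rr, cc_] = True
            sec_lm[lab] = (float(p[0]), float(p[1]))
        landmarks.append(sec_lm)
        lm_masks.append(lm_mask)
        masks_all.append(sec_masks)
        contours_all.append(sec_contours)
        sections.append(SectionImage(pixels=img, index=k, z_mm=k * Z_SPACING_MM))

    truth = GroundTruth(
        landmarks=landmarks,
        landmark_ref_positions=landmark_ref,
        transforms=transforms,
        fascicle_geometry=geometry,
        masks=masks_all,
        contours=contours_all,
        types=types,
        lineage=lineage,
        landmark_masks=lm_masks,
        config=config,
    )
    return sections, truth


# ---------------------------------------------------------------------------
# template windows

def generate_template_windows(n_positive: int, n_negative: int, seed: int,
                              noise: float = 10.0, contrast_fade: float = 0.0):
    """Labeled 15x15 RGB windows for training the fiducial-dot classifier.

    Positives contain a centered dark disk whose edge lies in the ring band
    at radius 6-7.5 px from the window center; negatives are texture patches,
    partial blobs, off-center blobs, or wrong-size blobs.

    ``contrast_fade`` in [0, 1) randomly pulls each blob's color toward the
    background by up to that fraction, making the two classes genuinely
    overlap (useful for hyperparameter-tuning experiments); 0 keeps the
    full-contrast fiducial appearance used for detector training.

    Returns
    -------
    (windows, labels)
        ``windows``: (n, 15, 15, 3) uint8; ``labels``: (n,) int, +1 circle-like,
        -1 non-circular.
    """
    if n_positive < 1 or n_negative < 1:
        raise ValueError("need at least one window per class")
    rng = np.random.default_rng(seed)
    size = 15
    center = (size - 1) / 2.0
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")

    def base():
        img = np.empty((size, size, 3), dtype=float)
        img[:] = BACKGROUND_COLOR
        img += rng.normal(0, noise, size=img.shape)
        return img

    def paint_disk(img, cr, cc, radius, color=LANDMARK_COLOR):
        d2 = (yy - cr) ** 2 + (xx - cc) ** 2
        sel = d2 <= radius**2
        col = np.asarray(color, float)
        if contrast_fade > 0:
            f = rng.uniform(0, contrast_fade)
            col = col + f * (BACKGROUND_COLOR.astype(float) - col)
        img[sel] = col + rng.normal(0, noise, size=(sel.sum(), 3))

    windows, labels = [], []
    for _ in range(n_positive):
        img = base()
        radius = rng.uniform(6.0, 7.3)
        jit = rng.uniform(-0.4, 0.4, size=2)
        paint_disk(img, center + jit[0], center + jit[1], radius)
        windows.append(img)
        labels.append(1)
    neg_kinds = ["texture", "offcenter", "partial", "small", "large", "blank"]
    for i in range(n_negative):
        img = base()
        kind = neg_kinds[int(rng.integers(len(neg_kinds)))]
        if kind == "texture":
            n_gr = rng.integers(6, 16)
            for _ in range(n_gr):
                paint_disk(img, rng.uniform(0, 14), rng.uniform(0, 14),
                           rng.uniform(0.8, 1.8), color=(80, 60, 115))
        elif kind == "offcenter":
            ang = rng.uniform(0, 2 * np.pi)
            shift = rng.uniform(2.0, 6.0)  # edge leaves the ring band from ~2 px
            paint_disk(img, center + shift * np.cos(ang), center + shift * np.sin(ang),
                       rng.uniform(6.0, 7.3))
        elif kind == "partial":
            paint_disk(img, center, center, rng.uniform(6.0, 7.3))
            cut = int(rng.integers(5, 9))
            img[:, :cut] = BACKGROUND_COLOR
            img[:, :cut] += rng.normal(0, noise, size=(size, cut, 3))
        elif kind == "small":
            paint_disk(img, center, center, rng.uniform(3.0, 5.2))
        elif kind == "large":
            paint_disk(img, center, center, rng.uniform(8.2, 10.0))
        # blank: background only
        windows.append(img)
        labels.append(-1)
    arr = np.clip(np.stack(windows), 0, 255).astype(np.uint8)
    return arr, np.asarray(labels, dtype=int)
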