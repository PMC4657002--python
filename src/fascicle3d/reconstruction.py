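"""Contour-stack 3D reconstruction.

Typed fascicle contours in the common registered frame are linked across
consecutive sections by polygon overlap (Jaccard >= 0.3), with one-to-two
links recorded as splits and two-to-one as merges.  Each constant-type
track segment is lofted into an open triangulated tube: rings resampled to
a common vertex count, rotationally aligned by minimizing summed vertex
distance over cyclic shifts, quads triangulated along their shorter
diagonal.  x and y stay in pixels, z in mm (section index * 0.5 mm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from skimage.draw import polygon as _rasterize_polygon

logger = logging.getLogger(__name__)

__all__ = [
    "ContourTrack",
    "FascicleMesh",
    "link_contours",
    "build_meshes",
    "export_model",
    "write_ply",
    "read_ply",
    "write_obj",
    "write_labelmap",
    "rasterize_contour",
    "TYPE_COLORS",
    "JACCARD_LINK_THRESHOLD",
    "Z_SPACING_MM",
]

Z_SPACING_MM = 0.5
JACCARD_LINK_THRESHOLD = 0.3

# colors as printed in the figures: purple = mixed, green = motor, yellow = sensory
TYPE_COLORS = {
    "mixed": (128, 0, 160),
    "motor": (0, 170, 60),
    "sensory": (235, 200, 0),
    "unknown": (128, 128, 128),
}


def rasterize_contour(vertices: np.ndarray, shape) -> np.ndarray:
    """Filled boolean mask of a closed (row, col) polygon."""
    v = np.asarray(vertices, dtype=float)
    rr, cc = _rasterize_polygon(v[:, 0], v[:, 1], shape=shape)
    out = np.zeros(shape, dtype=bool)
    out[rr, cc] = True
    return out


def _mask_jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union else 0.0


@dataclass
class ContourTrack:
    """A chain of corresponding contours with a constant type label."""

    nodes: list  # ordered (section_index, contour_index) pairs
    type_label: str
    parents: list = field(default_factory=list)  # track indices feeding this track
    children: list = field(default_factory=list)

    @property
    def sections(self):
        return [s for s, _ in self.nodes]


def _section_masks(contours_by_section, shape):
    return [
        [rasterize_contour(np.asarray(getattr(c, "vertices", c)), shape) for c in sec]
        for sec in contours_by_section
    ]


def link_contours(contours_by_section: list, types_by_section: list,
                  shape) -> tuple:
    """Link contours across consecutive sections into lineage tracks.

    Parameters
    ----------
    contours_by_section
        Per section: list of closed (row, col) polygons (or SnakeContour).
    types_by_section
        Parallel per-contour type labels.
    shape
        Raster shape used for overlap computation.

    Returns
    -------
    (tracks, lineage)
        ``tracks``: list of :class:`ContourTrack`; ``lineage``: DiGraph over
        (section, contour) nodes with split/merge structure.

    Many-to-many overlap ambiguity is resolved greedily by descending
    Jaccard (each contour keeps at most 2 links per side, logged).
    """
    masks = _section_masks(contours_by_section, shape)
    G = nx.DiGraph()
    for s, sec in enumerate(contours_by_section):
        for i in range(len(sec)):
            G.add_node((s, i), type=types_by_section[s][i])
    for s in range(len(contours_by_section) - 1):
        pairs = []
        for i, ma in enumerate(masks[s]):
            for j, mb in enumerate(masks[s + 1]):
                jac = _mask_jaccard(ma, mb)
                if jac >= JACCARD_LINK_THRESHOLD:
                    pairs.append((jac, i, j))
        pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
        out_deg: dict = {}
        in_deg: dict = {}
        for jac, i, j in pairs:
            if out_deg.get(i, 0) >= 2 or in_deg.get(j, 0) >= 2:
                logger.info("section %d: extra overlap %d->%d (J=%.2f) dropped", s, i, j, jac)
                continue
            G.add_edge((s, i), (s + 1, j), jaccard=jac)
            out_deg[i] = out_deg.get(i, 0) + 1
            in_deg[j] = in_deg.get(j, 0) + 1

    # tracks = maximal chains broken at branch points and type changes
    def is_chain_edge(u, v):
        return (
            G.out_degree(u) == 1 and G.in_degree(v) == 1
            and G.nodes[u]["type"] == G.nodes[v]["type"]
        )

    tracks = []
    node_track = {}
    for node in sorted(G.nodes):
        if node in node_track:
            continue
        preds = list(G.predecessors(node))
        if len(preds) == 1 and is_chain_edge(preds[0], node):
            continue  # not a chain head
        chain = [node]
        cur = node
        while True:
            succs = list(G.successors(cur))
            if len(succs) == 1 and is_chain_edge(cur, succs[0]):
                cur = succs[0]
                chain.append(cur)
            else:
                break
        t = ContourTrack(nodes=chain, type_label=G.nodes[node]["type"])
        for n in chain:
            node_track[n] = len(tracks)
        tracks.append(t)
    for ti, t in enumerate(tracks):
        head, tail = t.nodes[0], t.nodes[-1]
        t.parents = sorted({node_track[p] for p in G.predecessors(head)})
        t.children = sorted({node_track[c] for c in G.successors(tail)})
    return tracks, G


# ---------------------------------------------------------------------------
# meshing

@dataclass
class FascicleMesh:
    vertices: np.ndarray  # (n, 3): x=col px, y=row px, z=mm
    faces: np.ndarray  # (m, 3) int
    color: tuple
    type_label: str

    def surface_area(self) -> float:
        v = self.vertices
        a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        return float(0.5 * np.sum(np.linalg.norm(np.cross(a, b), axis=1)))

    def euler_characteristic(self) -> int:
        edges = set()
        for f in self.faces:
            for e in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
                edges.add(tuple(sorted(e)))
        return len(self.vertices) - len(edges) + len(self.faces)


def _resample_ring(verts: np.ndarray, n: int) -> np.ndarray:
    closed = np.vstack([verts, verts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0, s[-1], n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, s, closed[:, 0])
    out[:, 1] = np.interp(targets, s, closed[:, 1])
    return out


def _align_ring(prev: np.ndarray, ring: np.ndarray) -> np.ndarray:
    """Cyclic shift (and orientation flip) minimizing summed vertex distance."""
    best, best_cost = ring, np.inf
    for cand in (ring, ring[::-1]):
        for shift in range(len(cand)):
            rolled = np.roll(cand, shift, axis=0)
            cost = np.sum(np.hypot(*(rolled - prev).T))
            if cost < best_cost:
                best, best_cost = rolled, cost
    return best


def _loft(rings: np.ndarray, zs: np.ndarray, color, type_label) -> FascicleMesh:
    """Triangulate consecutive aligned rings by shortest diagonal."""
    m, n = rings.shape[:2]
    verts = np.empty((m * n, 3))
    for j in range(m):
        verts[j * n : (j + 1) * n, 0] = rings[j][:, 1]  # x = col
        verts[j * n : (j + 1) * n, 1] = rings[j][:, 0]  # y = row
        verts[j * n : (j + 1) * n, 2] = zs[j]
    faces = []
    for j in range(m - 1):
        for i in range(n):
            a = j * n + i
            b = j * n + (i + 1) % n
            c = (j + 1) * n + i
            d = (j + 1) * n + (i + 1) % n
            # split the quad (a, b, d, c) along its shorter diagonal
            if np.linalg.norm(verts[a] - verts[d]) <= np.linalg.norm(verts[b] - verts[c]):
                faces.append((a, b, d))
                faces.append((a, d, c))
            else:
                faces.append((a, b, c))
                faces.append((b, d, c))
    return FascicleMesh(vertices=verts, faces=np.asarray(faces, dtype=int),
                        color=color, type_label=type_label)


def build_meshes(tracks: list, contours_by_section: list,
                 z_spacing_mm: float = Z_SPACING_MM, ring_vertices: int = 64) -> list:
    """Loft every track of length >= 2 into an open triangulated tube.

    Length-1 tracks produce no surface and are skipped with a warning.
    Junction continuity is handled by each branch starting at its own first
    ring; parent/child rings share a section plane, fan-stitching the
    junction visually without requiring a watertight joint there.
    """
    meshes = []
    for ti, track in enumerate(tracks):
        if len(track.nodes) < 2:
            logger.warning("track %d has a single section; degenerate mesh skipped", ti)
            continue
        rings, zs = [], []
        prev = None
        for s, ci in track.nodes:
            poly = np.asarray(getattr(contours_by_section[s][ci], "vertices",
                                      contours_by_section[s][ci]), dtype=float)
            ring = _resample_ring(poly, ring_vertices)
            if prev is not None:
                ring = _align_ring(prev, ring)
            rings.append(ring)
            zs.append(s * z_spacing_mm)
            prev = ring
        color = TYPE_COLORS.get(track.type_label, TYPE_COLORS["unknown"])
        meshes.append(_loft(np.stack(rings), np.asarray(zs), color, track.type_label))
    return meshes


# ---------------------------------------------------------------------------
# export

def write_ply(meshes: list, path) -> None:
    """ASCII PLY with per-face RGB colors, all meshes concatenated."""
    n_verts = sum(len(m.vertices) for m in meshes)
    n_faces = sum(len(m.faces) for m in meshes)
    lines = [
        "ply", "format ascii 1.0",
        "comment fascicle3d surface model (x,y in px; z in mm)",
        f"element vertex {n_verts}",
        "property float x", "property float y", "property float z",
        f"element face {n_faces}",
        "property list uchar int vertex_indices",
        "property uchar red", "property uchar green", "property uchar blue",
        "end_header",
    ]
    for m in meshes:
        for v in m.vertices:
            lines.append(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
    offset = 0
    for m in meshes:
        r, g, b = m.color
        for f in m.faces:
            lines.append(f"3 {f[0]+offset} {f[1]+offset} {f[2]+offset} {r} {g} {b}")
        offset += len(m.vertices)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_ply(path):
    """Minimal ASCII PLY reader for round-trip verification.

    Returns ``(vertices, faces, face_colors)``.
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    n_verts = n_faces = 0
    header_end = 0
    for i, line in enumerate(tokens):
        if line.startswith("element vertex"):
            n_verts = int(line.split()[-1])
        elif line.startswith("element face"):
            n_faces = int(line.split()[-1])
        elif line.strip() == "end_header":
            header_end = i + 1
            break
    verts = np.array([list(map(float, tokens[header_end + i].split()))
                      for i in range(n_verts)])
    faces, colors = [], []
    for i in range(n_faces):
        parts = tokens[header_end + n_verts + i].split()
        cnt = int(parts[0])
        faces.append(list(map(int, parts[1 : 1 + cnt])))
        colors.append(tuple(map(int, parts[1 + cnt : 4 + cnt])))
    return verts, np.asarray(faces, dtype=int), colors


def write_obj(meshes: list, path) -> None:
    """OBJ + MTL pair with one material per functional type."""
    import os

    mtl_path = os.path.splitext(str(path))[0] + ".mtl"
    used = []
    for m in meshes:
        if m.type_label not in used:
            used.append(m.type_label)
    with open(mtl_path, "w") as fh:
        for t in used:
            r, g, b = (c / 255.0 for c in TYPE_COLORS.get(t, TYPE_COLORS["unknown"]))
            fh.write(f"newmtl {t}\nKd {r:.4f} {g:.4f} {b:.4f}\n")
    with open(path, "w") as fh:
        fh.write(f"mtllib {os.path.basename(mtl_path)}\n")
        offset = 1
        for mi, m in enumerate(meshes):
            fh.write(f"o fascicle_{mi}\nusemtl {m.type_label}\n")
            for v in m.vertices:
                fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            for f in m.faces:
                fh.write(f"f {f[0]+offset} {f[1]+offset} {f[2]+offset}\n")
            offset += len(m.vertices)


def write_labelmap(contours_by_section: list, shape, path,
                   track_of_contour: dict | None = None) -> np.ndarray:
    """Multi-page TIFF labelmap: one page per section, contour rasterizations
    carrying stable integer ids (per-section contour index + 1 by default,
    or the track id + 1 when a mapping is given).  Returns the volume."""
    import tifffile

    n_sections = len(contours_by_section)
    vol = np.zeros((n_sections,) + tuple(shape), dtype=np.uint16)
    for s, sec in enumerate(contours_by_section):
        for ci, contour in enumerate(sec):
            verts = np.asarray(getattr(contour, "vertices", contour), dtype=float)
            mask = rasterize_contour(verts, shape)
            lab = (track_of_contour or {}).get((s, ci), ci) + 1
            vol[s][mask] = lab
    tifffile.imwrite(path, vol, photometric="minisblack")
    return vol


SUPPORTED_FORMATS = ("ply", "obj")


def export_model(meshes: list, out_path, fmt: str = "ply",
                 labelmap: dict | None = None) -> list:
    """Write the surface model (and optionally a voxel labelmap).

    Parameters
    ----------
    fmt
        One of ``ply`` or ``obj``.
    labelmap
        Optional dict with keys ``contours_by_section``, ``shape``, ``path``
        (and optionally ``track_of_contour``) to also emit the multi-page
        TIFF labelmap.

    Returns the list of files written.
    """
    if fmt not in SUPPORTED_FORMATS:
        raise ValueError(f"unsupported format {fmt!r}; supported: {SUPPORTED_FORMATS}")
    written = [str(out_path)]
    if fmt == "ply":
        write_ply(meshes, out_path)
    else:
        write_obj(meshes, out_path)
    if labelmap is not None:
        write_labelmap(labelmap["contours_by_section"], labelmap["shape"],
                       labelmap["path"], labelmap.get("track_of_contour"))
        written.append(str(labelmap["path"]))
    return written
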