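"""On-disk artifact formats.

All per-stage artifacts are plain text: landmarks and transforms as CSV,
contours and types as JSON, stacks as numbered PNGs, ground truth as
CSV/JSON plus per-section label-mask TIFFs.
"""

from __future__ import annotations

import json
import os
import re

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .position_lines import LANDMARK_LABELS, LandmarkSet
from .registration import BilinearTransform

__all__ = [
    "write_stack", "read_stack",
    "write_landmarks_csv", "read_landmarks_csv",
    "write_transforms_csv", "read_transforms_csv",
    "write_contours_json", "read_contours_json",
    "write_types_json", "read_types_json",
    "write_ground_truth",
]


def write_stack(sections, out_dir) -> list:
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for s in sections:
        p = os.path.join(out_dir, f"section_{s.index:04d}.png")
        iio.imwrite(p, s.pixels)
        paths.append(p)
    return paths


def read_stack(stack_dir) -> list:
    from .synthetic_histology import SectionImage, Z_SPACING_MM

    names = sorted(
        f for f in os.listdir(stack_dir)
        if re.fullmatch(r".*\.(png|tif|tiff|jpg|jpeg)", f, re.IGNORECASE)
    )
    if not names:
        raise FileNotFoundError(f"no section images found in {stack_dir}")
    out = []
    for i, name in enumerate(names):
        px = iio.imread(os.path.join(stack_dir, name))
        if px.ndim == 2:
            px = np.stack([px] * 3, axis=-1)
        out.append(SectionImage(pixels=px[..., :3], index=i, z_mm=i * Z_SPACING_MM))
    return out


def write_landmarks_csv(landmark_sets, path) -> None:
    """Columns: section,label,row,col (0-based); sections with no landmarks
    are simply absent."""
    rows = []
    for ls in landmark_sets:
        if ls is None:
            continue
        for lab in LANDMARK_LABELS:
            r, c = ls.centers[lab]
            rows.append({"section": ls.section_index, "label": lab, "row": r, "col": c})
    pd.DataFrame(rows, columns=["section", "label", "row", "col"]).to_csv(path, index=False)


def read_landmarks_csv(path, n_sections: int | None = None) -> list:
    df = pd.read_csv(path)
    n = (int(df["section"].max()) + 1) if n_sections is None else n_sections
    out: list = [None] * n
    for sec, grp in df.groupby("section"):
        centers = {row["label"]: (float(row["row"]), float(row["col"]))
                   for _, row in grp.iterrows()}
        pts = np.array([centers[lab] for lab in LANDMARK_LABELS])
        out[int(sec)] = LandmarkSet(
            section_index=int(sec), centers=centers,
            section_center=tuple(pts.mean(axis=0)),
        )
    return out


def write_transforms_csv(transforms, path) -> None:
    cols = ["section", "a0", "a1", "a2", "a3", "b0", "b1", "b2", "b3"]
    rows = []
    for i, t in enumerate(transforms):
        if t is None:
            continue
        rows.append([i] + list(t.as_row()))
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_transforms_csv(path, n_sections: int | None = None) -> list:
    df = pd.read_csv(path)
    n = (int(df["section"].max()) + 1) if n_sections is None else n_sections
    out: list = [None] * n
    for _, row in df.iterrows():
        out[int(row["section"])] = BilinearTransform(
            a=row[["a0", "a1", "a2", "a3"]].to_numpy(dtype=float),
            b=row[["b0", "b1", "b2", "b3"]].to_numpy(dtype=float),
        )
    return out


def write_contours_json(segmentations, path) -> None:
    """Per section: closed vertex lists (row, col, sub-pixel) + cluster centers."""
    doc = []
    for seg in segmentations:
        doc.append({
            "contours": [np.asarray(c.vertices).tolist() for c in seg.contours],
            "cluster_centers": (
                np.asarray(seg.clusters.centers).tolist() if seg.clusters is not None else []
            ),
            "failed_clusters": list(seg.failed_clusters),
        })
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_contours_json(path) -> list:
    with open(path) as fh:
        doc = json.load(fh)
    return [
        {
            "contours": [np.asarray(c, dtype=float) for c in sec["contours"]],
            "cluster_centers": np.asarray(sec["cluster_centers"], dtype=float),
            "failed_clusters": sec.get("failed_clusters", []),
        }
        for sec in doc
    ]


def write_types_json(types_by_section, path) -> None:
    with open(path, "w") as fh:
        json.dump([list(t) for t in types_by_section], fh)


def read_types_json(path) -> list:
    with open(path) as fh:
        return json.load(fh)


def write_ground_truth(truth, out_dir) -> None:
    """Ground truth export: landmark CSV, lineage/transform JSON, and one
    label-mask TIFF per section."""
    import tifffile

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for sec, lm in enumerate(truth.landmarks):
        for lab, (r, c) in lm.items():
            rows.append({"section": sec, "label": lab, "row": r, "col": c})
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "landmarks.csv"), index=False)
    doc = {
        "types": {str(k): v for k, v in truth.types.items()},
        "lineage_edges": [[int(u), int(v)] for u, v in truth.lineage.edges],
        "transforms": [t.as_row().tolist() for t in truth.transforms],
        "z_spacing_mm": 0.5,
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(doc, fh)
    for sec, masks in enumerate(truth.masks):
        lbl = np.zeros(truth.config.image_size, dtype=np.uint16)
        for fid, m in masks.items():
            lbl[m] = fid + 1
        tifffile.imwrite(os.path.join(out_dir, f"labels_{sec:04d}.tif"), lbl)
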