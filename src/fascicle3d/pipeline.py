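"""One-command orchestration: detect -> register -> segment -> classify ->
reconstruct, with per-stage artifacts, logging, and a checksummed manifest.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np

from . import io as f3dio
from . import position_lines as pl
from . import reconstruction as recon
from . import segmentation as seg
from . import typing as typ

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "default_config", "config_to_text"]


DEFAULTS = {
    "detector": {"sigma2": 2.0, "gamma": 100.0, "n_train_pos": 150, "n_train_neg": 150},
    "ga": {"enabled": False, "population": 30, "generations": 50,
           "sigma2_lo": 0.1, "sigma2_hi": 50.0, "gamma_lo": 1.0, "gamma_hi": 1000.0},
    "registration": {"reference_index": 0},
    "snake": {"alpha": 0.1, "beta": 0.5, "step": 1.0, "max_iter": 300,
              "n_vertices": 100, "mode": "improved", "gvf_mu": 0.2, "gvf_iter": 80,
              "split_sigma": 22.0, "merge_dist": 30.0},
    "typing": {"r": 11, "n_pixels": 4000, "eps": 1.15, "w_lower": 0.7, "w_upper": 0.3},
    "reconstruction": {"ring_vertices": 64, "z_spacing_mm": 0.5, "format": "ply",
                       "labelmap": True},
}


@dataclass
class PipelineConfig:
    stack_dir: str
    out_dir: str
    seed: int = 0
    model_path: str | None = None  # pre-trained detector archive; else train on synthetics
    params: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULTS.items()})

    def validate(self) -> None:
        if not os.path.isdir(self.stack_dir):
            raise FileNotFoundError(f"stack directory not found: {self.stack_dir}")
        if self.model_path is not None and not os.path.isfile(self.model_path):
            raise FileNotFoundError(f"model archive not found: {self.model_path}")


def default_config(stack_dir: str = "", out_dir: str = "") -> PipelineConfig:
    return PipelineConfig(stack_dir=stack_dir, out_dir=out_dir)


def config_to_text(config: PipelineConfig) -> str:
    """Flat key = value text, sectioned per stage."""
    cp = configparser.ConfigParser()
    cp["pipeline"] = {
        "stack_dir": config.stack_dir, "out_dir": config.out_dir,
        "seed": str(config.seed), "model_path": str(config.model_path or ""),
    }
    for stage, block in config.params.items():
        cp[stage] = {k: str(v) for k, v in block.items()}
    import io as _io

    buf = _io.StringIO()
    cp.write(buf)
    return buf.getvalue()


def config_from_file(path) -> PipelineConfig:
    cp = configparser.ConfigParser()
    cp.read(path)
    cfg = default_config(cp["pipeline"]["stack_dir"], cp["pipeline"]["out_dir"])
    cfg.seed = cp["pipeline"].getint("seed", 0)
    mp = cp["pipeline"].get("model_path", "")
    cfg.model_path = mp or None
    for stage in cfg.params:
        if stage in cp:
            for k, default_v in cfg.params[stage].items():
                if k in cp[stage]:
                    conv = type(default_v)
                    cfg.params[stage][k] = (
                        cp[stage].getboolean(k) if isinstance(default_v, bool)
                        else conv(cp[stage][k])
                    )
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _train_default_detector(cfg: PipelineConfig) -> pl.LSSVMModel:
    from .synthetic_histology import generate_template_windows

    d = cfg.params["detector"]
    wins, labels = generate_template_windows(
        int(d["n_train_pos"]), int(d["n_train_neg"]), seed=cfg.seed
    )
    return pl.train_detector(wins, labels, sigma2=float(d["sigma2"]), gamma=float(d["gamma"]))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order and return the artifact manifest.

    Any stage failure halts the run with the stage name attached; artifacts
    from completed stages are preserved in ``out_dir``.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = {"stages": [], "artifacts": {}}

    def record(stage, t0, **counts):
        entry = {"stage": stage, "wall_s": round(time.time() - t0, 3), **counts}
        manifest["stages"].append(entry)
        logger.info("stage=%s %s", stage, counts)

    def artifact(name, path):
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "load"
    try:
        t0 = time.time()
        sections = f3dio.read_stack(config.stack_dir)
        record(stage, t0, n_sections=len(sections))

        stage = "detect"
        t0 = time.time()
        model = (pl.load_model(config.model_path) if config.model_path
                 else _train_default_detector(config))
        landmark_sets = []
        for s in sections:
            try:
                landmark_sets.append(pl.detect_position_lines(s, model, s.index))
            except pl.DetectionCountError as exc:
                logger.warning("section %d: %s", s.index, exc)
                landmark_sets.append(None)
        lm_path = os.path.join(config.out_dir, "landmarks.csv")
        f3dio.write_landmarks_csv(landmark_sets, lm_path)
        artifact("landmarks.csv", lm_path)
        record(stage, t0, n_detected=sum(ls is not None for ls in landmark_sets))

        stage = "register"
        t0 = time.time()
        from .registration import register_stack

        ref_idx = int(config.params["registration"]["reference_index"])
        lm_arrays = [ls.as_array() if ls is not None else None for ls in landmark_sets]
        reg = register_stack([s.pixels for s in sections], lm_arrays, ref_idx)
        tr_path = os.path.join(config.out_dir, "transforms.csv")
        f3dio.write_transforms_csv(reg.transforms, tr_path)
        artifact("transforms.csv", tr_path)
        record(stage, t0, n_registered=len(reg.images) - len(reg.gaps), gaps=reg.gaps)

        stage = "segment"
        t0 = time.time()
        sp = config.params["snake"]
        params = seg.SnakeParams(
            alpha=float(sp["alpha"]), beta=float(sp["beta"]), step=float(sp["step"]),
            max_iter=int(sp["max_iter"]), n_vertices=int(sp["n_vertices"]),
            mode=str(sp["mode"]),
        )
        segs, fgs = [], []
        for img in reg.images:
            fg = seg.preprocess_section(img)
            fgs.append(fg)
            pts = np.argwhere(fg).astype(float)
            clusters = seg.cluster_fascicle_pixels(
                pts, split_sigma=float(sp["split_sigma"]), merge_dist=float(sp["merge_dist"])
            )
            segs.append(seg.extract_fascicle_contours(
                img, clusters, params,
                gvf_mu=float(sp["gvf_mu"]), gvf_iter=int(sp["gvf_iter"]),
            ))
        ct_path = os.path.join(config.out_dir, "contours.json")
        f3dio.write_contours_json(segs, ct_path)
        artifact("contours.json", ct_path)
        record(stage, t0, n_contours=sum(len(s.contours) for s in segs))

        stage = "classify"
        t0 = time.time()
        tp = config.params["typing"]
        spec = typ.NeighborhoodSpec(r=int(tp["r"]))
        types_by_section = []
        for img, fg, s in zip(reg.images, fgs, segs):
            n_px = min(int(tp["n_pixels"]), int(fg.sum()))
            feats, coords = typ.build_feature_matrix(
                img, n_px, spec, seed=config.seed, mask=fg
            )
            clustering = typ.rough_kmeans(
                feats, k=3, w_lower=float(tp["w_lower"]), w_upper=float(tp["w_upper"]),
                eps=float(tp["eps"]), seed=config.seed,
            )
            types_by_section.append(typ.label_fascicles(s.contours, clustering, coords, img))
        ty_path = os.path.join(config.out_dir, "types.json")
        f3dio.write_types_json(types_by_section, ty_path)
        artifact("types.json", ty_path)
        record(stage, t0, n_typed=sum(len(t) for t in types_by_section))

        stage = "reconstruct"
        t0 = time.time()
        rp = config.params["reconstruction"]
        shape = sections[0].pixels.shape[:2]
        contours = [[c.vertices for c in s.contours] for s in segs]
        tracks, lineage = recon.link_contours(contours, types_by_section, shape)
        meshes = recon.build_meshes(tracks, contours,
                                    z_spacing_mm=float(rp["z_spacing_mm"]),
                                    ring_vertices=int(rp["ring_vertices"]))
        model_path = os.path.join(config.out_dir, "model." + str(rp["format"]))
        labelmap_req = None
        if rp.get("labelmap"):
            labelmap_req = {
                "contours_by_section": contours, "shape": shape,
                "path": os.path.join(config.out_dir, "labelmap.tif"),
            }
        written = recon.export_model(meshes, model_path, fmt=str(rp["format"]),
                                     labelmap=labelmap_req)
        for p in written:
            artifact(os.path.basename(p), p)
        record(stage, t0, n_tracks=len(tracks), n_meshes=len(meshes))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    man_path = os.path.join(config.out_dir, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
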