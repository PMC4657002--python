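# fascicle3d

Reconstruction of the 3D topology of peripheral-nerve internal fascicular
groups from serial 2D histological section images.

The pipeline runs in five stages over an ordered stack of RGB section
images, each carrying four dark circular fiducial dots ("position lines"):

1. **Position-line detection** (`fascicle3d.position_lines`) — a 15×15
   template window around each dark-blob candidate is classified as
   circle-like or non-circular by a least-squares SVM with an RBF kernel;
   hyperparameters (σ², γ) can be tuned by a real-coded genetic algorithm on
   a held-out template set.  Detected centers are labeled `S_a..S_d`
   canonically by angle.
2. **Registration** (`fascicle3d.registration`) — the four labeled centers
   are control points for an exactly determined bilinear coordinate
   transform (terms `1, x, y, xy`); every section is warped into the
   reference section's frame by backward mapping with bilinear
   interpolation.
3. **Edge extraction** (`fascicle3d.segmentation`) — preprocessing isolates
   fascicle-texture pixels; an ISODATA-style dynamic clustering with
   unknown cluster count finds how many fascicles there are and where; a
   gradient-vector-flow (GVF) snake pulls a smooth closed contour onto each
   fascicle edge.  The *improved* snake mode applies only the component of
   the external force along the contour normal (the tangential part is
   negligible at the edge) and converges in fewer iterations.
4. **Functional typing** (`fascicle3d.typing`) — per-pixel 72-dimensional
   texture descriptors (4 directions × first/second-order gradient curves ×
   3 descriptors × 3 RGB channels, neighborhood scale `r`, default 11) are
   grouped by rough K-means (k = 3, lower/upper approximations); fascicle
   contours are labeled sensory / motor / mixed by majority vote, with the
   darkest cluster named sensory and the lightest motor.
5. **3D reconstruction** (`fascicle3d.reconstruction`) — contours are linked
   across sections by polygon overlap (splits and merges recorded), lofted
   into triangulated tubes (z = section index × 0.5 mm), and exported as
   PLY/OBJ with per-type colors plus an optional multi-page TIFF voxel
   labelmap.

Because no real specimen data are distributed, `fascicle3d.synthetic_histology`
generates full stacks with known ground truth — granular fascicle textures in
three separable classes, fiducial dots of 12–15 px diameter, per-section
misalignment from the bilinear family, and scripted split/merge events —
against which every stage is tested.

## Command line

```bash
# make a synthetic stack with ground truth
fascicle3d simulate --out stack/ --sections 16 --fascicles 3 --seed 7 \
    --events '5:split:2,11:merge:1'

# individual stages
fascicle3d train-detector --out model.zip --tune
fascicle3d detect-landmarks --stack stack/ --model model.zip --out landmarks.csv
fascicle3d register --stack stack/ --landmarks landmarks.csv --ref 0 --out reg/
fascicle3d segment --stack reg/ --out contours.json
fascicle3d classify --stack reg/ --contours contours.json --r 11 --out types.json
fascicle3d reconstruct --contours contours.json --types types.json \
    --shape 768x1024 --out model.ply --labelmap volume.tif

# or everything at once
fascicle3d run --stack stack/ --out results/ --seed 7
fascicle3d config --print-defaults
```

`fascicle3d run` writes per-stage artifacts (`landmarks.csv`,
`transforms.csv`, `contours.json`, `types.json`, `model.ply`,
`labelmap.tif`) and a `manifest.json` with SHA-256 checksums; reruns with
the same config and seed reproduce the deterministic artifacts bit for bit.

## Conventions

- Coordinates are 0-based `(row, col)`, row increasing downward, throughout.
- Mesh vertices are `(x=col px, y=row px, z=mm)`; sections are 0.5 mm apart.
- Mesh colors: purple = mixed, green = motor, yellow = sensory.
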