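# vesselgraph

Extraction of annotated centerline graphs from binary 3D segmentations of
vessel networks.

The pipeline runs four stages that are iterated until a fixed point:

1. **Thinning** — topology-preserving erosion of the foreground to a
   unit-wide voxel skeleton, with anisotropy-aware dynamic axis selection,
   optional fixed voxels, and a switchable line-end preservation rule.
2. **Topology extraction** — slice-streamed classification of skeleton
   voxels (end / regular / branch), streaming connected components, node
   barycenters, node-edge matching, and Bezier-style centerline smoothing.
3. **Voxel-branch assignment & feature annotation** — every foreground
   voxel is mapped to a graph edge (Voronoi mapping, component remapping,
   cut-off region flooding); per-point surface distances and volumes are
   accumulated and aggregated into per-edge features (length, distance,
   straightness, volume, average cross-section, radius statistics,
   roundness).
4. **Refinement** — spurious branches are pruned with a single
   dimensionless parameter, the *bulge size*
   `(length − inner_length + tip_radius) / mean average radius`,
   then degree-2 nodes are merged.  Leaf-node voxels of the refined graph
   are fixed for the next skeletonization round; iteration stops when the
   edge count no longer changes.

A synthetic phantom generator (cylinder, Y-junction, torus, surface bumps,
thick-beside-thin vessels) with known ground-truth graphs, a
topology-preserving surface-noise operator, resample/mirror volume scaling,
and a DICE-style edge match ratio make the whole pipeline testable without
external data.

## Usage

Extract a graph from a volume (NIfTI, TIFF stack, HDF5, or raw blocked
format with JSON sidecar; nonzero voxels are foreground):

```sh
vesselgraph extract --input vessels.nii --bulge-size 1.5 \
    --out-csv edges.csv --out-json graph.json --out-obj centerlines.obj
```

Use `--bulge-size 1.5` for irregular (e.g. lymphatic) vessels and `3.0` or
higher for smooth vasculature.  `--max-iterations 0` (default) iterates to
the fixed point.

Generate a phantom with ground truth:

```sh
vesselgraph phantom y --out y.h5 --ground-truth y_gt.json --noise-level 0.5 --seed 1
```

From Python:

```python
from vesselgraph import (PipelineConfig, rasterize, run_pipeline, y_phantom)

grid, ground_truth = rasterize(y_phantom())
graph, reports = run_pipeline(grid, PipelineConfig(bulge_threshold=1.5))
for edge in graph.edges.values():
    print(edge.id, edge.features.length, edge.features.avg_radius_mean)
```

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the property-based acceptance suite
(topology preservation against brute-force oracles, clean-phantom ground
truth recovery, bulge-size behaviour, noise robustness, resolution and
anisotropy invariance, assignment oracles).

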