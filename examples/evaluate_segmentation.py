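"""Score a segmentation and a picking-point prediction.

Degrades a ground-truth label map with random flips, scores it with the
macro metrics (mPA, mIoU, MP, MR), then evaluates a picking point against
a 30x10 px best-region and converts it to camera coordinates.
"""

import numpy as np

from saffpick.geometry import Point2D
from saffpick.metrics import (
    MP, MR, BestRegion, CameraIntrinsics, confusion, mIoU, mPA,
    pixel_error, pixel_to_camera,
)
from saffpick.synth import SceneSpec, generate_scene

scene = generate_scene(SceneSpec(seed=3, depth_mm=480.0))
truth = scene.label_map.astype(int)

rng = np.random.default_rng(0)
pred = truth.copy()
flip = rng.random(truth.shape) < 0.02  # 2% label noise
pred[flip] = rng.integers(0, 4, int(flip.sum()))

cm = confusion(pred, truth, 4)
print(f"mPA  = {mPA(cm):6.2f} %   (macro pixel accuracy)")
print(f"mIoU = {mIoU(cm):6.2f} %   (macro intersection over union)")
print(f"MP   = {MP(cm):6.2f} %   (macro precision)")
print(f"MR   = {MR(cm):6.2f} %   (macro recall)")

best = BestRegion.around(scene.gt_necking, width=10, height=30)
predicted = Point2D(scene.gt_necking.x + 3.0, scene.gt_necking.y - 20.0)
pe = pixel_error(best, predicted)
print(f"picking-point pixel error: e_x={pe.e_x:.1f} e_y={pe.e_y:.1f} e={pe.e:.2f} px")

intr = CameraIntrinsics(f_x=600.0, f_y=600.0, c_x=320.0, c_y=240.0)
depth = scene.depth[int(predicted.y), int(predicted.x)]
xyz = pixel_to_camera(predicted.x, predicted.y, depth, intr)
print(f"camera-frame coordinates at {depth:.0f} mm depth: "
      f"X={xyz[0]:.1f} Y={xyz[1]:.1f} Z={xyz[2]:.1f} mm")
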