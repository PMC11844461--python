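"""Precision experiment in silico: static lips, moving head.

A rigid head rotating at 18 deg/s must register no lip-aperture change
(rigid motion preserves distances); any measured SD then comes from pixel
jitter alone.  The empirical SD under iid jitter is compared with the
first-order (delta-method) noise propagation through projection,
triangulation and the aperture distance.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "tests"))
from oracles import predict_la_sd  # noqa: E402

from lipstereo import (
    HeadMotionParams,
    JitterModel,
    build_scene,
    compute_precision,
    render_tracks,
)
from lipstereo.synth import default_rig, static_lips

rig = default_rig()

rotating = build_scene(
    static_lips(8.0),
    HeadMotionParams(mode="constant-rotation", angular_rate_deg_s=18.0),
    rig=rig, duration=1.0, seed=0,
)
left, right = render_tracks(rotating)  # zero jitter
sd, _ = compute_precision(left, right, rig)
print(f"18 deg/s rotating head, zero jitter: LA SD = {sd:.2e} mm "
      f"(isometry -> numerical noise only)")

static = build_scene(static_lips(8.0), rig=rig, duration=1.0, seed=0)
up = static.trajectories["upper_mid"][0]
lo = static.trajectories["lower_mid"][0]
print(f"\n{'sigma_px':>8} {'empirical SD':>14} {'predicted SD':>14}   (mm, 50 replicates)")
for sigma in (0.25, 0.5, 1.0):
    j = JitterModel(kind="iid", sigma_px=sigma)
    var = [
        np.var(compute_precision(*render_tracks(static, j, j, seed=r), rig)[1].values,
               ddof=1)
        for r in range(50)
    ]
    emp = float(np.sqrt(np.mean(var)))
    pred = predict_la_sd(rig, up, lo, sigma)
    print(f"{sigma:8.2f} {emp:14.4f} {pred:14.4f}")
print("-> at this rig geometry 1 px of tracker noise maps to ~0.25 mm of "
      "lip-aperture SD.")
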