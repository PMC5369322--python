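"""Write and read back a miniature fixation dataset.

Runs the full acquisition protocol at reduced scale (one vantage point,
3 x 3 gaze grid, 240 x 135 px) and shows the on-disk layout: one folder
per head position, with stereo/cyclopic PNGs, 16-bit depth PNGs, raw
float32 disparity binaries, occlusion/edge masks and a geometry info file
per fixation.
"""

from pathlib import Path

import numpy as np

from stereofix import ProtocolConfig, make_synthetic_scene, run_protocol
from stereofix import dataset_io

out = Path("example_output/mini_dataset")
scene = make_synthetic_scene(seed=1, n_objects=6)
config = ProtocolConfig(azimuths_deg=(0.0,), elevations_deg=(30.0,),
                        grid_rows=3, grid_cols=3, width=240, height=135)
manifest = run_protocol([("K", scene)], config, out)
print(f"wrote {len(manifest['records'])} records "
      f"({sum(not r['mirrored'] for r in manifest['records'])} rendered "
      "+ mirrored disparity twins)")

paths = dataset_io.record_paths("K", 0, 1, 0, 0)
folder = out / paths.folder
print(f"record folder: {paths.folder}")
info = dataset_io.read_info(folder / paths.files["info"])
print(f"  vergence {info.gaze_vergence:.3f} deg, "
      f"version {info.gaze_version:.3f} deg")
lam = dataset_io.read_depth_png(folder / paths.files["cycdepth"],
                                info.cyc_depth_norm)
print(f"  cyclopic depth {np.nanmin(lam):.0f}-{np.nanmax(lam):.0f} mm "
      f"(PNG normalization {info.cyc_depth_norm.dmin:.1f}.."
      f"{info.cyc_depth_norm.dmax:.1f})")
dx = dataset_io.read_disparity_bin(folder / paths.files["cycdispx"],
                                   (config.height, config.width))
print(f"  cyclopic d_x range [{np.nanmin(dx):+.2f}, {np.nanmax(dx):+.2f}] px")
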