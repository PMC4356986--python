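"""Optical-stability tracking of a levitated cell.

Simulates a microscope image series (0.1 s/frame) of a cell jittering
around its trap by 0.23 um horizontally and 0.84 um vertically, then
tracks four points of interest (two on the cell, the capillary wall and
the laser spot) by normalized cross-correlation.
"""

from cellxrf.optics import ROISpec, track_stability
from cellxrf.phantom import generate_image_series

series = generate_image_series(n_frames=1500, jitter_sd_um=(0.23, 0.84),
                               seed=5)
rois = [ROISpec(name, tuple(series.truth_px[name][0]))
        for name in ("cell", "cell_edge", "wall", "laser")]
result = track_stability(series.frames, rois, series.um_per_px)

print(f"{'POI':10s} {'sd Y (um)':>10s} {'sd Z (um)':>10s}")
for name, (sd_z, sd_y) in result.sd_um.items():
    print(f"{name:10s} {sd_y:10.3f} {sd_z:10.3f}")
print("\ncell deviation relative to the capillary wall (um):",
      tuple(round(v, 3) for v in result.relative_to_wall_sd_um["cell"]))
# The cell POIs reproduce the injected sub-micron jitter while the wall
# and laser references stay quiet -- sufficient stability for 1-2 um
# raster scanning of a 30 um organism.
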