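"""Recovering 3D transmurality from a thick-slice acquisition.

Slices an ellipsoidal LV phantom into an 8 mm stack (the worst clinical
slice thickness), upsamples it back to isotropic resolution with
shape-based interpolation and compares wall overlap and per-vertex
transmurality against the isotropic reference.
"""

import numpy as np

from scarmap import (
    PhantomSpec,
    classify_boundaries,
    dice,
    downsample_throughplane,
    extract_surface,
    icc_2_1,
    make_phantom,
    match_grid,
    match_vertices,
    solve_laplace,
    trace_correspondences,
    transmurality_map,
    upsample_topologic,
)

spec = PhantomSpec(
    shape="ellipsoid", wall_thickness=8.0, transmural_extent=0.6,
    spacing=(1.0, 1.0, 1.0), noise_sigma=0.0,
)
ref, _, truth = make_phantom(spec)

thick = downsample_throughplane(ref, 8.0)
print(f"thick-slice stack: {thick.shape[2]} slices of {thick.spacing[2]:.1f} mm")
up = match_grid(upsample_topologic(thick, 1.0), ref)
print(f"wall Dice after 8 mm round trip: {dice(up.wall_mask, ref.wall_mask):.3f}")


def tsm(seg):
    fld = solve_laplace(seg, classify_boundaries(seg))
    mesh = extract_surface(seg, "epi")
    return mesh, transmurality_map(trace_correspondences(fld, mesh))


mesh_ref, map_ref = tsm(ref)
mesh_up, map_up = tsm(up)
idx = match_vertices(mesh_ref, mesh_up)
ok = map_ref.valid & map_up.valid[idx]
icc = icc_2_1(np.column_stack([map_ref.tsm[ok], map_up.tsm[idx][ok]]))
print(f"transmurality ICC(2,1), upsampled vs reference: {icc:.3f} over {ok.sum()} matched vertices")
# ICC near 1 means the thick-slice route reproduces the per-vertex
# transmurality of the isotropic reference, not just its average
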