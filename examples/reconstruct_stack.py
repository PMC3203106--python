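"""Align a misaligned stack and reconstruct BrdU+ nuclei in 3D.

Perturbs a phantom stack with known similarity misalignments, re-registers
it from three control points per section, extracts labelled nuclei in 3D,
splits touching ones, and meshes the rudiment iso-surface.
"""

import numpy as np

from mamrud import phantom, reconstruct

spec = phantom.PhantomSpec(
    rng_seed=9,
    n_sections=7,
    brdu_fraction={"ectoderm": 0.0, "core": 0.0, "periphery": 0.0, "mesenchyme": 0.05},
)
sections, truth = phantom.generate_stack(spec)
moved, applied = phantom.perturb_stack(sections, max_shift_px=4, max_rot_rad=0.05, max_scale_dev=0.02, seed=11)

landmarks = np.array([[40.0, 60.0], [40.0, 200.0], [80.0, 128.0]])  # two ectoderm points + centre
points = {s.index: applied[k].apply(landmarks) for k, s in enumerate(sections)}
aligned, recovered = reconstruct.align_stack(moved, points)
residual = reconstruct.control_point_residual(points, recovered, [s.index for s in aligned])
print(f"registration residual after alignment: {residual:.2e} px")

nuclei = reconstruct.extract_label_voxels(aligned, threshold=0.65, size_window=(5, 400))
split = reconstruct.split_touching(nuclei, min_separation_um=3.5)
print(f"BrdU+ nuclei: {nuclei.count} raw components -> {split.count} after splitting "
      f"(ground truth: {int(truth.nuclei['brdu'].sum())})")

mr_voxels = np.stack([truth.mr_mask(i) for i in range(spec.n_sections)])
mesh = reconstruct.isosurface(mr_voxels, (spec.section_thickness_um, 1.0, 1.0), "MR")
voxel_volume = mr_voxels.sum() * spec.section_thickness_um
print(f"rudiment mesh: {len(mesh.vertices)} vertices, enclosed volume "
      f"{mesh.enclosed_volume_um3():,.0f} um^3 (voxelized: {voxel_volume:,.0f})")

# Raw 3D components undercount nuclei wherever two nuclei of consecutive
# sections overlap in-plane; the distance-transform-seeded split restores
# the count up to interpolation blur from the re-registration.  The mesh
# volume agrees with the voxelized volume of the imaged part of the
# rudiment (this short 7-section stack covers only its central slab).
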