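"""Reconstruct a leg cross section and extract the bone permittivities.

Runs the full chain for one scene — forward simulation on a fine mesh,
FEM-CSI inversion on a coarser mesh (inverse-crime guard), rasterization
of the reconstruction, and the expert-eye extraction for both bones —
and prints the extracted values next to the ground truth.

Takes ~20 s.
"""

from legtomo import bvf_to_permittivity
from legtomo.pipeline import ExperimentConfig, build_setup, extract_bones, reconstruct_scene

BVF = 0.35  # moderately demineralized bone

config = ExperimentConfig(scenario="thin_fat")
setup = build_setup(config)
print(f"forward mesh {setup.fwd_mesh.num_nodes} nodes / "
      f"inversion mesh {setup.inv_mesh.num_nodes} nodes "
      f"({setup.domain.size} contrast unknowns in the leg)")

recon, model = reconstruct_scene(setup, BVF)
f_csi, f_s, f_d = recon.cost_history[-1]
print(f"CSI converged in {len(recon.cost_history)} iterations, "
      f"F_CSI = {f_csi:.2e} (data {f_s:.2e} + state {f_d:.2e})")

actual = bvf_to_permittivity(BVF).real
for bone, est in extract_bones(recon, model, BVF).items():
    shown = "not detected" if not est.detected else \
        f"extracted eps' = {est.mean_real_permittivity:.2f}"
    print(f"  {bone:>6}: {shown}   (actual {actual:.1f}, muscle 55.0)")
print("\nThe tibia estimate should sit within a few permittivity units "
      "of the actual value; the small, deeper fibula is extracted less "
      "accurately — the same asymmetry the imaging study reports.")
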