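"""Design a modulated bolus for a wedge PTV over bone and air slabs.

Builds the water-cube phantom with a wedge-shaped PTV and two inhomogeneity
slabs distal to it, runs the iterative design with the built-in broad-beam
dose engine (12 MeV, 10x10 cm applicator), and writes the printable STL.
"""

import numpy as np

import mertbolus as mb

spec = mb.PhantomSpec(
    size_mm=(200, 200, 200), spacing_mm=2.5,
    ptv_half_x_mm=30, ptv_half_y_mm=30,
    ptv_proximal_mm=5, ptv_distal_min_mm=20, ptv_distal_max_mm=40,
    inserts=[mb.Insert(lo=(-30, -25, 140), hi=(-5, 25, 150), material="bone"),
             mb.Insert(lo=(5, -25, 140), hi=(30, 25, 150), material="air")])
ct, structures = mb.make_wedge_phantom(spec)
beam = mb.beam_for_phantom(ct, structures["BODY"], energy=12.0,
                           applicator_cm=10.0)

result = mb.run_design(ct, structures, mb.DesignConfig(beam=beam))

print("iter  V90[%]  Dmax[%]  conformity   bone max[%]  air max[%]")
for m in result.history:
    bone = m.oar_doses["INSERT_BONE_0"][1]
    air = m.oar_doses["INSERT_AIR_1"][1]
    print(f"{m.iteration:4d}  {m.v90:6.1f}  {m.dmax:7.1f}  {m.conformity:10.3f}"
          f"  {bone:11.1f}  {air:9.1f}")
print(f"stopped: {result.stop_reason} after "
      f"{len(result.iteration_log)} design pass(es)")
print(f"thickness range: {result.thickness.min():.1f} - "
      f"{result.thickness.max():.1f} mm")

path = mb.write_stl(result.solid.mesh, "wedge_bolus.stl")
print(f"wrote {path} ({path.stat().st_size} bytes, "
      f"{len(result.solid.mesh.faces)} triangles, "
      f"watertight={result.solid.is_watertight})")

# V90 is the fraction of the PTV covered by the 90% isodose; the bolus pulls
# that surface up to the distal PTV, which is why the bone/air maximum doses
# collapse between iteration 0 (no bolus) and the final plan.
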