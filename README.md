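# mertbolus

Iterative design of 3D-printable modulated bolus for electron radiation
therapy.

Electron beams treat superficial tumours, but a flat bolus makes the
prescription isodose surface follow the patient surface instead of the
planning target volume (PTV), so tissue distal to the target is irradiated
unnecessarily. A bolus whose thickness is *modulated* point by point can shape
the distal 90% isodose surface to conform to the distal PTV surface — a form
of modulated electron radiation therapy (MERT). This package designs such a
bolus from a CT, a structure set, a dose distribution and a beam description,
and exports it as a watertight STL solid ready for a 3D printer.

It is written for medical physicists and planning researchers: the library
API is the main interface, `examples/` holds short narrative scripts, and a
thin `bolus` command line covers the clinic-style file workflow (DICOM
CT/RTSTRUCT/RTDOSE in, STL + report out).

## The algorithm

For every point *p* of a 2.5 mm grid on the plane through the isocenter and
perpendicular to the central axis, a ray is traced from the virtual source
through *p*. Along that ray the distal PTV depth *T₂* and the distal 90%
isodose depth *T₁* are found, and the thickness shift is the water-equivalent
gap converted into bolus material:

```
SBT_p = (1 / CET_bolus) ∫_{T₂}^{T₁} CET(z) dz
```

where CET(z), the coefficient of equivalent thickness, is the density of the
tissue at depth z relative to water (from the CT's HU→density table) and
CET_bolus ≈ 1.119 for solid printed PLA. A positive shift thickens the bolus
(pulls the 90% surface up), a negative one thins it.

The raw shift map is then refined by five regional modulation operators,
applied in fixed order:

1. **Hot-spot smoothing** — if any dose exceeds 110% of prescription, its ray
   projection is smoothed with a Gaussian regional kernel (mode 1, which
   shrinks unreliable values toward their surroundings).
2. **Coverage smoothing** — negative shifts in under-covered regions are kept
   and bled outward over an annulus (mode 2, a proper weighted average).
3. **Irregularity smoothing** — cells whose thickness gradient exceeds twice
   the mean gradient magnitude are relaxed.
4. **PTV-margin adjustment** — a 10 mm border inside the PTV projection is
   thinned with the kernel `Ker(x) = exp(−x²/2σ²)`, `K1 = σ√(−2 ln 0.01)`,
   compensating the reduced scatter near the field edge.
5. **Outside-PTV extrusion** — boundary values are extruded radially out to
   1 cm beyond the applicator edge.

New dose is then computed (built-in broad-beam engine, or a planning-system
RTDOSE dropped in per iteration), and the loop repeats until the plan is
acceptable (default V90 ≥ 98%, Dmax ≤ 110%); one or two iterations usually
suffice. The final map becomes a watertight solid whose inner surface sits on
the patient skin and whose outer surface is displaced along the diverging
rays.

## Worked example

`python examples/design_wedge_bolus.py` designs a bolus for a wedge-shaped
PTV in a 20×20×20 cm³ water phantom with a bone slab and an air slab distal
to the target (12 MeV, 10×10 cm applicator). It prints:

```
iter  V90[%]  Dmax[%]  conformity   bone max[%]  air max[%]
   0   100.0    100.0       0.248         45.6       66.7
   1   100.0    100.0       0.321          2.0       13.6
stopped: acceptable after 1 design pass(es)
thickness range: 5.0 - 21.2 mm
wrote wedge_bolus.stl (480084 bytes, 9600 triangles, watertight=True)
```

Iteration 0 is the no-bolus plan: the PTV is covered, but the 90% surface
overshoots and the slabs behind it receive up to 67% of prescription. One
design pass conforms the 90% surface to the distal PTV (conformity rises) and
collapses the maximum bone/air doses to 2% and 14% while keeping V90 at 100%.

The other examples calibrate the bolus CET from slab depth-dose curves
(`calibrate_cet.py`, recovering 1.130 ± 0.000 from forward-simulated
measurements) and run a 3%/5 mm gamma comparison between planned and
as-built dose (`gamma_check.py`).

Command-line equivalents:

```
bolus phantom --spec spec.yaml --out ct_dir/
bolus design --ct ct_dir/ --structures rs.dcm --config design.yaml \
      --out-stl bolus.stl --out-report report.yaml
bolus calibrate-cet --ref ref.csv --slab slab10.csv:10 --slab slab20.csv:20
bolus gamma --eval d_built.dcm --ref d_plan.dcm --ct ct_dir/
```

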