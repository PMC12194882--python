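# capforge

Mesh-driven design of perfusable, porous 3D microcapillary scaffolds for
two-photon lithography (TPL), plus the quantitative QC used to validate the
prints: design-vs-print registration maps, bead velocimetry and live/dead
viability counting.

Engineered microvasculature for brain-on-chip and organoid work needs
capillary-scale (tens of µm) perfusable tubes routed along tortuous 3D
paths, with open pores in the wall for diffusion, and enough mechanical
support to survive printing and solvent development. `capforge` generates
those scaffolds as watertight triangle meshes ready for slicing, and gives
the image-analysis side of the loop for checking what actually printed.

## The design model

A capillary is a cylindrical membrane of lumen diameter `l_d` swept along a
centerline of arc length `P_l` (imported from CSV or generated: Hilbert
space-filling curves, single/double helices). The membrane surface is
subdivided parametrically into `u × v` cells,

```
u = ⌊P_l / (p_d + p_s)⌋        s_l = P_l / u
v = ⌊π·l_d / (p_d + p_s)⌋      s_r = π·l_d / v
```

with `p_d` the pore diameter and `p_s` the edge-to-edge pore spacing. Each
cell becomes a picture frame — a border of width `p_s/2` with a rectangular
through-opening ≈ `p_d` across. Openings facing sideways are widened 1.5×
circumferentially (the anisotropic TPL voxel tends to seal them). The shell
is thickened outward into a watertight solid (χ = −2P for P pores), then
optionally Catmull-Clark smoothed. Three support families anchor the tube:
polygonal collar rings (placed evenly or at the printer's field-of-view
stitching seams), truncated-octahedron strut lattices with capillary-
clearance culling, and ≥15°-taper cone supports whose geometry keeps clear
of the capillary envelope so the chip stays perfusable. A flat base,
heat-shrink-tubing nozzle ports (508 µm OD) and retaining walls complete a
chip, exported as binary STL (µm).

## Worked example

```python
import capforge as cf

spec = cf.CapillarySpec(lumen_diameter=40, pore_diameter=5,
                        pore_spacing=8, membrane_thickness=10)
path = cf.hilbert_path(order=2, dims=2, step=100, layers=2, layer_gap=120,
                       corner_fillet_radius=spec.lumen_radius)
grid = cf.subdivision_grid(path.path_length, spec)
print(grid.u, grid.v, grid.n_pores)
shell = cf.sweep_shell(path, grid, spec)
membrane = cf.thicken(cf.elongate_side_pores(cf.cut_pores(shell, grid, spec),
                                             spec),
                      on_self_intersection="warn")
print(membrane.is_watertight(), membrane.euler_characteristic())
```

prints

```
221 9 1989
True -3978
```

— a stacked two-layer Hilbert capillary with 221 axial × 9 circumferential
cells, hence 1989 pores, and a closed membrane whose Euler characteristic
−2·1989 confirms every pore is a genuine through-channel. The same chip can
be produced end to end (supports, base, nozzles, STL set, JSON manifest)
from one config file:

```
forge generate examples/reference_chip.toml
```

The QC commands mirror the analyses run on printed chips:
`forge register <design.png> <print.png>` (overlap map and fractions),
`forge piv <stack.tiff> --pixel-size 1.0 --frame-interval 0.005`
(mean ± SD bead velocity in mm/s), `forge viability <green.png> <red.png>`
(live/dead counts), and `forge synth` writes seeded synthetic fixtures for
all three.

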