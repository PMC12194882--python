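# Stacked two-layer Hilbert-curve capillary chip with lattice and cone
# supports: 40 µm lumen, 5 µm pores at 8 µm spacing, 10 µm wall,
# 10 µm lattice beams.

seed = 1

[path]
source = "hilbert"
order = 2
step = 100.0
layers = 2
layer_gap = 120.0

[capillary]
ld = 40.0
pd = 5.0
ps = 8.0
membrane_thickness = 10.0
side_pore_elongation = 1.5
smoothing_iterations = 0

[fov]
fov_width = 400.0
overlap = 5.0
stitch_angle = 15.0

[supports]
strategies = ["lattice", "cone"]

[supports.lattice]
cell_size = 150.0
beam_diameter = 10.0
clearance = 2.0

[supports.cone]
taper_angle = 15.0
tip_radius = 6.0
spacing = 300.0

[chip]
base_margin = 100.0

[output]
dir = "forge_out/reference_chip"
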