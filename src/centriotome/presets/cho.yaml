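# CHO (Chinese hamster ovary) triplet centriole preset.
# Radii are axis -> A-tubule-centre distances; tilts are blade long-axis
# angles from the local tangent (outward positive).  The radius/tilt pairs
# are calibrated so the outer density envelope (20% threshold convention)
# of the symmetrized ensemble measures ~235 nm proximally and ~220 nm
# distally, the distal change being a 15-degree inward blade rotation.
name: cho
n_blades: 9
length: 440.0
domain_boundary: 200.0
radius_proximal: 67.0
radius_distal: 63.0
blade_tilt_proximal: 50.0
blade_tilt_distal: 35.0
segment_step: 24.0
center_offset: 22.0
a11_mip_domain: proximal
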