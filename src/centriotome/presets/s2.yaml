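# Drosophila S2 doublet centriole preset.  Single (fly) domain, length
# 176 nm (nearest multiple of the 8 nm dimer repeat to the ~175 nm average
# length); radius/tilt calibrated for a ~210 nm outer-envelope diameter.
name: s2
n_blades: 9
length: 176.0
domain_boundary: null
radius_proximal: 74.0
radius_distal: 74.0
blade_tilt_proximal: 50.0
blade_tilt_distal: 50.0
segment_step: 24.0
center_offset: 14.0
a11_mip_domain: proximal
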