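# Default wear-study configuration: a synthetic lower second premolar
# fitted at one representative wear depth per ordinal wear stage.
# All lengths mm, forces N, moduli GPa. Unknown keys are rejected.

geometry:
  crown_height: 8.0
  buccal_cusp_height: 8.0
  lingual_cusp_height: 6.5
  buccal_cusp_slope: 50.0     # degrees from the occlusal plane
  cervix_radius: 3.5
  root_length: 10.0
  enamel_thickness: 1.2
  pulp_radius: 1.0
  pdl_thickness: 0.25
  bone_block: [10.5, 11.5, 16.0]
  mesh_size: 1.0              # target edge length; coarser is much faster
  seed: 0

contact:
  epsilon: 0.05               # proximity tolerance, mm
  direction: [0.0, -1.0, 0.0] # antagonist approach direction

loads:
  total_force: 100.0          # prescribed resultant magnitude, N

# materials:                  # optional overrides, GPa / Poisson
#   enamel: {E: 84.1, nu: 0.3}

analysis:
  n_cervical: 10              # homologous buccal-cervical sampling nodes

# wear_depths: [0.4, 1.3, 2.4]  # omit to use one depth per wear stage

output_dir: runs
seed: 0
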