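# Full pipeline configuration. Every value shown equals the shipped default
# (the design constants); delete anything you do not want to override.
geometry:
  cell_size_mm: 1.0

pores:
  d_lo_um: 100.0       # capillary diameter floor
  d_hi_um: 400.0       # oxygen-diffusion ceiling (2 x 200 um)
  resolution: 60       # voxels per unit cell for the 3x3x3 pore model

stiffness:
  E_Pa: 1.8e9          # laser-sintered Nylon
  D_mm: 30.0           # femoral diameter
  L_mm: 30.0           # critical fracture length
  k_lo_N_mm: 1000.0    # interfragmentary-movement floor
  k_hi_N_mm: 2700.0    # stress-shielding ceiling

growth:
  dt: 1.0e-4           # advection step in curvature time (mm^2)
  lambda_mm2_day: 1.5588e-3   # calibrated on the Split P anchor rate
  max_days: 21.0
  fill_threshold: 0.005
  resolution: 64       # voxels per unit cell for the level-set model

optimise:
  vf_sweep: [0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5, 0.55, 0.6, 0.65, 0.7,
             0.75, 0.8, 0.85, 0.9]
  stiffness_mode: report       # "strict" to intersect with the GA window
  use_published_windows: false # true = reproduction run over the published limits
  growth_sweep_points: 3
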